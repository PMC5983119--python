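import numpy as np
import pandas as pd
import pytest

from skiptic.core_io import SampleSheet
from skiptic.expression import (
    diff_expression,
    long_intron_trend,
    se_expression_enrichment,
    size_factors,
    stability_vs_downregulation,
)
from oracles import binomial_tail_oracle, chi2_2x2_oracle


def _sheet(n=4):
    return SampleSheet(
        [(f"WT_{i}", "WT") for i in range(n)] + [(f"MUT_{i}", "MUT") for i in range(n)]
    )


def _nb_counts(rng, mu, alpha, size):
    lam = rng.gamma(1.0 / alpha, mu * alpha, size)
    return rng.poisson(lam)


class TestDiffExpression:
    def test_null_calibration(self, rng):
        sheet = _sheet()
        mu = np.exp(rng.normal(np.log(400), 0.5, 2000))
        counts = pd.DataFrame(
            {s: _nb_counts(rng, mu, 0.05, len(mu)) for s in sheet.sample_ids},
            index=[f"g{i}" for i in range(len(mu))],
        )
        de = diff_expression(counts, sheet)
        frac = (de.loc[de.tested, "p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.10
        assert np.abs(de.loc[de.tested, "log2fc"].median()) < 0.05

    def test_planted_fold_change_recovery(self, rng):
        """200 planted genes at mean 500, dispersion 0.05, fold change 0.5,
        n=4 per group (amid 800 unchanged genes, so median-of-ratios
        normalization has a stable reference): the median estimated log2FC
        of the planted set lands within +/-0.15 of -1."""
        sheet = _sheet()
        n_genes, n_planted = 1000, 200
        mu = np.full(n_genes, 500.0)
        fc = np.where(np.arange(n_genes) < n_planted, 0.5, 1.0)
        data = {}
        for s, cond in sheet.samples:
            m = mu * (fc if cond == "MUT" else 1.0)
            data[s] = _nb_counts(rng, m, 0.05, n_genes)
        counts = pd.DataFrame(data, index=[f"g{i}" for i in range(n_genes)])
        de = diff_expression(counts, sheet)
        assert de["log2fc"][:n_planted].median() == pytest.approx(-1.0, abs=0.15)
        assert ((de["fdr"][:n_planted] < 0.1).mean()) > 0.9

    def test_constant_counts_give_p_one(self):
        sheet = _sheet(2)
        counts = pd.DataFrame(
            {s: [100, 50] for s in sheet.sample_ids}, index=["g0", "g1"]
        )
        de = diff_expression(counts, sheet)
        assert (de["p"] == 1.0).all()

    def test_all_zero_gene_untested(self):
        sheet = _sheet(2)
        counts = pd.DataFrame(
            {s: [100, 0] for s in sheet.sample_ids}, index=["g0", "g1"]
        )
        de = diff_expression(counts, sheet)
        assert not de.loc["g1", "tested"]
        assert np.isnan(de.loc["g1", "p"])

    def test_size_factors_correct_library_scale(self, rng):
        sheet = _sheet(2)
        base = rng.poisson(300, 500).astype(float) + 1
        counts = pd.DataFrame(
            {
                "WT_0": base,
                "WT_1": base * 2,
                "MUT_0": base,
                "MUT_1": base * 4,
            },
            index=[f"g{i}" for i in range(500)],
        )
        sf = size_factors(counts)
        assert sf["WT_1"] / sf["WT_0"] == pytest.approx(2.0, rel=0.02)
        de = diff_expression(counts, sheet)
        assert np.abs(de["log2fc"]).max() < 0.35


class TestSeEnrichment:
    def _calls(self, se_genes, cassette_genes=()):
        rows = [
            {"event_id": f"se{i}", "gene_id": g, "event_class": "cassette", "category": "skiptic"}
            for i, g in enumerate(se_genes)
        ] + [
            {"event_id": f"c{i}", "gene_id": g, "event_class": "cassette", "category": "alt_shift"}
            for i, g in enumerate(cassette_genes)
        ]
        return pd.DataFrame(rows).set_index("event_id", drop=False)

    def _de(self, n, down_genes, rng):
        gene_ids = [f"g{i}" for i in range(n)]
        df = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "mean_ref": rng.uniform(100, 1000, n),
                "mean_mut": rng.uniform(100, 1000, n),
                "log2fc": np.where(np.isin(gene_ids, down_genes), -1.0, 0.0),
                "fdr": np.where(np.isin(gene_ids, down_genes), 0.001, 0.9),
                "tested": True,
            },
            index=gene_ids,
        )
        return df

    def test_binomial_tail_matches_oracle(self, rng):
        down = [f"g{i}" for i in range(50)]
        se = down[:10] + [f"g{i}" for i in range(900, 940)]
        de = self._de(1000, down, rng)
        out = se_expression_enrichment(self._calls(se), de)
        row = out.loc[("down", "skiptic")]
        assert row["k"] == 10 and row["n"] == 50
        assert row["p"] == pytest.approx(
            binomial_tail_oracle(10, 50, row["background_rate"]), abs=1e-12
        )

    def test_k_zero_gives_p_one(self, rng):
        down = [f"g{i}" for i in range(30)]
        se = [f"g{i}" for i in range(500, 520)]
        de = self._de(1000, down, rng)
        out = se_expression_enrichment(self._calls(se), de)
        assert out.loc[("down", "skiptic"), "p"] == 1.0

    def test_empty_downregulated_set(self, rng):
        de = self._de(100, [], rng)
        out = se_expression_enrichment(self._calls(["g5"]), de)
        assert out.loc[("down", "skiptic"), "n"] == 0
        assert np.isnan(out.loc[("down", "skiptic"), "p"])

    def test_null_coupling_p_uniform(self, rng):
        """SE membership independent of DE status: enrichment p-values over
        repeated draws are uniform (KS test not rejected at alpha 0.01)."""
        from scipy import stats as sps

        pvals = []
        for _ in range(200):
            genes = [f"g{i}" for i in range(400)]
            down = list(rng.choice(genes, 40, replace=False))
            se = list(rng.choice(genes, 60, replace=False))
            de = self._de(400, down, rng)
            out = se_expression_enrichment(self._calls(se), de)
            pvals.append(out.loc[("down", "skiptic"), "p"])
        # discrete p-values stack at 1; compare against the null CDF loosely
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01 or np.mean(np.array(pvals) < 0.05) < 0.09


class TestStabilityChi2:
    def _inputs(self, down_damaging, down_ok, other_damaging, other_ok):
        rows, cons_rows, gid = [], [], 0

        def add(n, down, damaging):
            nonlocal gid
            for _ in range(n):
                g = f"g{gid}"
                eid = f"e{gid}"
                gid += 1
                rows.append(
                    {
                        "event_id": eid,
                        "gene_id": g,
                        "event_class": "cassette",
                        "category": "skiptic",
                        "_down": down,
                    }
                )
                cons_rows.append(
                    {
                        "event_id": eid,
                        "stability_class": "damaging_unstable" if damaging else "other",
                    }
                )

        add(down_damaging, True, True)
        add(down_ok, True, False)
        add(other_damaging, False, True)
        add(other_ok, False, False)
        calls = pd.DataFrame(rows).set_index("event_id", drop=False)
        cons = pd.DataFrame(cons_rows).set_index("event_id", drop=False)
        down_genes = calls.loc[calls["_down"], "gene_id"]
        de = pd.DataFrame(
            {
                "gene_id": calls["gene_id"].tolist(),
                "fdr": [0.01 if d else 0.9 for d in calls["_down"]],
                "log2fc": [-1.0 if d else 0.0 for d in calls["_down"]],
                "tested": True,
            },
            index=calls["gene_id"].tolist(),
        )
        return calls.drop(columns="_down"), cons, de

    def test_diagonal_table_matches_oracle(self):
        calls, cons, de = self._inputs(10, 0, 0, 10)
        out = stability_vs_downregulation(calls, cons, de)
        stat, p = chi2_2x2_oracle([[10, 0], [0, 10]])
        assert out["chi2"] == pytest.approx(stat, abs=1e-12)
        assert out["p"] == pytest.approx(p, abs=1e-12)
        assert out["chi2"] == pytest.approx(20.0)

    def test_independent_table(self):
        calls, cons, de = self._inputs(5, 5, 5, 5)
        out = stability_vs_downregulation(calls, cons, de)
        assert out["chi2"] == 0.0 and out["p"] == 1.0

    def test_zero_column_reports_proportions_only(self):
        calls, cons, de = self._inputs(0, 10, 0, 10)
        with pytest.warns(UserWarning):
            out = stability_vs_downregulation(calls, cons, de)
        assert np.isnan(out["p"])
        assert out["prop_damaging_downregulated"] == 0.0


class TestLongIntronTrend:
    def _models(self, intron_lens):
        from skiptic.core_io import GenomicInterval, TranscriptModel

        models = []
        pos = 0
        for i, L in enumerate(intron_lens):
            e1 = GenomicInterval("chr1", pos, pos + 100)
            e2 = GenomicInterval("chr1", pos + 100 + int(L), pos + 200 + int(L))
            models.append(TranscriptModel(f"t{i}", f"g{i}", (e1, e2)))
            pos += 300 + int(L)
        return models

    def test_bin_count(self, rng):
        n = 1000
        models = self._models(rng.integers(100, 1000, n))
        de = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "z": rng.normal(size=n),
                "tested": True,
            },
            index=[f"g{i}" for i in range(n)],
        )
        out = long_intron_trend(de, models, bin_size=200)
        assert len(out["bins"]) == 5
        assert out["bins"]["n"].sum() == n

    def test_coupled_trend_is_monotone(self, rng):
        """Downregulated genes with 10x longer introns: strong negative
        Spearman between bin order (most downregulated first) and mean
        intron length... i.e. |rho| -> 1 with length decreasing."""
        n = 1000
        z = np.sort(rng.normal(size=n))  # ascending
        intron = 10000.0 / (1 + np.exp(z * 2)) + rng.normal(0, 100, n) + 500
        models = self._models(np.clip(intron, 100, None))
        de = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "z": z, "tested": True},
            index=[f"g{i}" for i in range(n)],
        )
        out = long_intron_trend(de, models, bin_size=200)
        assert out["spearman_rho"] < -0.8

    def test_intronless_genes_excluded(self, rng):
        from skiptic.core_io import GenomicInterval, TranscriptModel

        models = self._models([500, 600])
        models.append(
            TranscriptModel("t9", "g9", (GenomicInterval("chr1", 10**6, 10**6 + 100),))
        )
        de = pd.DataFrame(
            {"gene_id": ["g0", "g1", "g9"], "z": [0.0, 1.0, 2.0], "tested": True},
            index=["g0", "g1", "g9"],
        )
        out = long_intron_trend(de, models, bin_size=2)
        assert out["n_intronless_excluded"] == 1
        assert out["bins"]["n"].sum() == 2
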