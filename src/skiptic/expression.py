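"""Gene-level differential expression and splicing-expression coupling.

Differential expression is a negative-binomial Wald test on median-of-ratios
normalized counts, with per-gene method-of-moments dispersions shrunk toward
a fitted mean-dispersion trend (alpha(mu) = a0 + a1/mu); it is a defined,
auditable statistic, not a reimplementation of any published tool's
internals.

Coupling analyses:

* binomial enrichment of skiptic exons among significantly downregulated
  (or upregulated) genes against an expression-matched background rate
  (quantile bins of mean normalized count);
* a 2x2 Pearson chi-squared test of damaging/unstable consequence calls vs
  downregulation among skiptic-exon genes;
* the long-intron trend: genes ranked by signed expression z-score, binned,
  and the per-bin mean intron length correlated with bin order.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import DataError, SampleSheet
from .stats import bh_adjust, binomial_tail_p, pearson_chi2, signed_z, DataErrorZeroMargin
from .consequence import STABILITY_DAMAGING


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors (genes with any zero count are
    excluded from the reference geometric mean)."""
    logs = np.log(counts.replace(0, np.nan))
    ref = logs.mean(axis=1)
    usable = np.isfinite(ref)
    if not usable.any():
        raise DataError("no gene has non-zero counts in every sample")
    ratios = logs.loc[usable].sub(ref[usable], axis=0)
    return np.exp(ratios.median(axis=0))


def diff_expression(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    ref_condition: Optional[str] = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test of mutant vs reference mean expression.

    Returns mean normalized counts per condition, log2 fold change
    (mutant/reference), Wald p, BH FDR over tested genes and signed z.
    Genes with zero counts everywhere are untested.
    """
    conds = sheet.conditions
    if len(conds) != 2:
        raise DataError("diff_expression needs exactly 2 conditions")
    if ref_condition is None:
        ref_condition = "WT" if "WT" in conds else conds[0]
    mut_condition = [c for c in conds if c != ref_condition][0]

    counts = counts.loc[:, sheet.sample_ids]
    sf = size_factors(counts)
    norm = counts / sf

    ref_cols = sheet.condition_samples(ref_condition)
    mut_cols = sheet.condition_samples(mut_condition)
    a = norm[ref_cols].to_numpy(dtype=float)
    b = norm[mut_cols].to_numpy(dtype=float)

    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    tested = (mu_a + mu_b) > 0
    mu = (a.sum(axis=1) + b.sum(axis=1)) / (a.shape[1] + b.shape[1])

    # method-of-moments dispersion from pooled within-condition variance
    var_w = np.zeros(len(counts))
    df = 0
    for block in (a, b):
        if block.shape[1] >= 2:
            var_w += block.var(axis=1, ddof=1) * (block.shape[1] - 1)
            df += block.shape[1] - 1
    if df > 0:
        var_w = var_w / df
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.clip((var_w - mu) / np.maximum(mu, 1e-9) ** 2, 1e-8, 10.0)

    # mean-dispersion trend alpha(mu) = a0 + a1/mu (least squares on 1/mu)
    fit_mask = tested & (mu > 0) & np.isfinite(alpha_mom)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[fit_mask], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = np.nanmedian(alpha_mom[fit_mask]) if fit_mask.any() else 0.01, 0.0
    with np.errstate(divide="ignore"):
        alpha_trend = a0 + a1 / np.maximum(mu, 1e-9)
    # geometric-mean shrinkage toward the trend
    alpha = np.exp(0.5 * (np.log(alpha_mom) + np.log(np.maximum(alpha_trend, 1e-8))))

    pc = 0.5
    lfc = np.log2((mu_b + pc) / (mu_a + pc))
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log_a = (1.0 / np.maximum(mu_a, pc) + alpha) / a.shape[1]
        var_log_b = (1.0 / np.maximum(mu_b, pc) + alpha) / b.shape[1]
    se = np.sqrt(var_log_a + var_log_b)
    wald = np.log((mu_b + pc) / (mu_a + pc)) / np.maximum(se, 1e-12)
    p = 2.0 * sps.norm.sf(np.abs(wald))
    p = np.where(tested, p, np.nan)
    # degenerate case: identical counts in every sample -> no evidence
    novar = tested & (var_w == 0) & (mu_a == mu_b)
    p = np.where(novar, 1.0, p)

    fdr = bh_adjust(p)
    z = signed_z(np.where(np.isnan(lfc), 0.0, lfc), p)
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "mean_ref": mu_a,
            "mean_mut": mu_b,
            "log2fc": lfc,
            "p": p,
            "fdr": fdr,
            "z": z,
            "tested": tested,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# SE / expression coupling
# ---------------------------------------------------------------------------

def se_expression_enrichment(
    calls: pd.DataFrame,
    de: pd.DataFrame,
    fdr_cut: float = 0.1,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Binomial enrichment of splicing categories among differentially
    expressed genes.

    For each direction (down: FDR < cut and log2FC < 0; up: FDR < cut and
    log2FC > 0) and each exon category (skiptic; non-skiptic cassette), k is
    the number of DE genes containing such an event and the background rate
    is the category frequency among non-significant genes from the same
    expression deciles, weighted by the DE set's decile composition;
    p is the one-sided upper binomial tail.
    """
    de = de[de["tested"]].copy()
    se_genes = set(calls.loc[calls["category"] == "skiptic", "gene_id"])
    cassette_genes = set(
        calls.loc[
            (calls["event_class"] == "cassette") & (calls["category"] != "skiptic")
            & (calls["category"] != "none"),
            "gene_id",
        ]
    )
    mean_expr = (de["mean_ref"] + de["mean_mut"]) / 2
    try:
        bins = pd.qcut(mean_expr, n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=de.index)
    de = de.assign(_bin=bins)

    nonsig = de[de["fdr"] >= fdr_cut]
    rows = []
    for direction, mask in [
        ("down", (de["fdr"] < fdr_cut) & (de["log2fc"] < 0)),
        ("up", (de["fdr"] < fdr_cut) & (de["log2fc"] > 0)),
    ]:
        sel = de[mask]
        for cat_name, members in [("skiptic", se_genes), ("cassette", cassette_genes)]:
            n = len(sel)
            k = int(sel["gene_id"].isin(members).sum())
            if n == 0:
                rows.append(
                    {
                        "direction": direction,
                        "category": cat_name,
                        "k": 0,
                        "n": 0,
                        "background_rate": np.nan,
                        "p": np.nan,
                    }
                )
                continue
            weights = sel["_bin"].value_counts(normalize=True)
            rate = 0.0
            for bin_id, w in weights.items():
                bg = nonsig[nonsig["_bin"] == bin_id]
                r = bg["gene_id"].isin(members).mean() if len(bg) else 0.0
                rate += w * r
            rate = float(min(max(rate, 1e-12), 1.0))
            rows.append(
                {
                    "direction": direction,
                    "category": cat_name,
                    "k": k,
                    "n": n,
                    "background_rate": rate,
                    "p": binomial_tail_p(k, n, rate),
                }
            )
    return pd.DataFrame(rows).set_index(["direction", "category"])


def stability_vs_downregulation(
    calls: pd.DataFrame,
    consequences: pd.DataFrame,
    de: pd.DataFrame,
    fdr_cut: float = 0.1,
) -> dict:
    """2x2 chi-squared of {downregulated SE gene vs other SE gene} x
    {damaging_unstable vs other} over genes with a skiptic call."""
    se = calls[calls["category"] == "skiptic"]
    if "stability_class" not in consequences.columns:
        raise DataError("consequences table lacks stability_class")
    merged = se.join(consequences["stability_class"], how="inner")
    down_genes = set(de.loc[(de["fdr"] < fdr_cut) & (de["log2fc"] < 0), "gene_id"])
    is_down = merged["gene_id"].isin(down_genes)
    damaging = merged["stability_class"] == STABILITY_DAMAGING
    table = np.array(
        [
            [int((is_down & damaging).sum()), int((is_down & ~damaging).sum())],
            [int((~is_down & damaging).sum()), int((~is_down & ~damaging).sum())],
        ]
    )
    prop_down = table[0, 0] / table[0].sum() if table[0].sum() else np.nan
    prop_other = table[1, 0] / table[1].sum() if table[1].sum() else np.nan
    out = {
        "table": table,
        "prop_damaging_downregulated": prop_down,
        "prop_damaging_other": prop_other,
        "chi2": np.nan,
        "p": np.nan,
    }
    try:
        out["chi2"], out["p"] = pearson_chi2(table)
    except DataErrorZeroMargin:
        warnings.warn("chi-squared undefined (zero margin); proportions reported only")
    return out


def long_intron_trend(
    de: pd.DataFrame,
    models,
    bin_size: int = 200,
) -> dict:
    """Rank genes by signed expression z (ascending: most downregulated
    first), bin into disjoint groups, and report per-bin mean and s.e.m. of
    per-gene mean intron length with the Spearman correlation between bin
    index and bin mean.

    The per-gene intron length is the mean intron length of the gene's
    longest isoform; intronless genes are excluded.
    """
    longest: dict = {}
    for m in models:
        span = sum(e.length for e in m.exons)
        if m.gene_id not in longest or span > longest[m.gene_id][0]:
            longest[m.gene_id] = (span, m)
    intron_len = {}
    n_intronless = 0
    for gid, (_span, m) in longest.items():
        introns = m.introns()
        if not introns:
            n_intronless += 1
            continue
        intron_len[gid] = float(np.mean([i.length for i in introns]))

    df = de[de["tested"]].copy()
    df["mean_intron_length"] = df["gene_id"].map(intron_len)
    df = df.dropna(subset=["mean_intron_length"]).sort_values("z")

    rows = []
    for b, start in enumerate(range(0, len(df), bin_size)):
        chunk = df.iloc[start : start + bin_size]
        vals = chunk["mean_intron_length"].to_numpy()
        rows.append(
            {
                "bin": b,
                "n": len(chunk),
                "mean_z": float(chunk["z"].mean()),
                "mean_intron_length": float(vals.mean()),
                "sem_intron_length": float(vals.std(ddof=1) / np.sqrt(len(vals)))
                if len(vals) > 1
                else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    if len(bins) >= 3:
        rho, rho_p = sps.spearmanr(bins["bin"], bins["mean_intron_length"])
    else:
        rho, rho_p = np.nan, np.nan
    return {
        "bins": bins,
        "spearman_rho": float(rho) if np.isfinite(rho) else np.nan,
        "spearman_p": float(rho_p) if np.isfinite(rho_p) else np.nan,
        "n_intronless_excluded": n_intronless,
    }
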