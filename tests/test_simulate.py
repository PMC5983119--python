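import numpy as np
import pytest

from skiptic.core_io import (
    FastaReader,
    SampleSheet,
    read_bedgraph,
    read_crosslinks,
    read_gtf,
    read_junction_counts,
)
from skiptic.core_io import ConfigurationError
from skiptic.simulate import SimulationConfig, build_genome_and_annotation, simulate_study
from skiptic.splicing import extract_splice_events

TINY = dict(
    n_genes=60,
    n_skiptic=5,
    n_cryptic=5,
    n_shared_alt=3,
    n_null_cassette=20,
    n_retained_intron=3,
    n_alt5=3,
    n_alt3=3,
    n_alt_first=3,
    n_alt_last=3,
    n_mutually_exclusive=3,
)


class TestConfig:
    def test_too_many_events_is_error(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_genes=10, n_skiptic=20)

    def test_bad_regime(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(regime="bananas")


class TestDeterminism:
    def test_same_seed_same_files(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_study(SimulationConfig(seed=9, **TINY), outdir=d1)
        simulate_study(SimulationConfig(seed=9, **TINY), outdir=d2)
        for name in [
            "genome.fa",
            "annotation.gtf",
            "crosslinks.bed",
            "conservation.bedGraph",
            "gene_counts.tsv",
            "truth_events.tsv",
            "sj/WT_1.SJ.out.tab",
            "sj/MUT_4.SJ.out.tab",
        ]:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name

    def test_regimes_share_annotation_but_not_counts(self):
        g = simulate_study(SimulationConfig(seed=9, regime="GOF", **TINY))
        l = simulate_study(SimulationConfig(seed=9, regime="LOF", **TINY))
        assert g.genome == l.genome
        assert [m.transcript_id for m in g.models] == [m.transcript_id for m in l.models]
        gc = {j.key: j.counts for j in g.junctions}
        lc = {j.key: j.counts for j in l.junctions}
        assert gc != lc


class TestTruthTable:
    def test_planted_counts_and_cds_placement(self):
        sim = build_genome_and_annotation(SimulationConfig(seed=3, **TINY))
        vc = sim.truth_events["event_type"].value_counts()
        assert vc["skiptic"] == 5 and vc["cryptic"] == 5 and vc["null_cassette"] == 20
        models_by_gene = {}
        for m in sim.models:
            models_by_gene.setdefault(m.gene_id, []).append(m)
        for _, row in sim.truth_events[sim.truth_events.event_type == "skiptic"].iterrows():
            for m in models_by_gene[row.gene_id]:
                # constitutive: the skiptic exon is in every isoform, inside the CDS
                assert any(e.start == row.start and e.end == row.end for e in m.exons)
                cs, ce = m.cds
                assert cs <= row.start and row.end <= ce

    def test_frameshift_fraction_controls_exon_length(self):
        cfg = SimulationConfig(seed=3, frac_frameshift=1.0, **TINY)
        sim = build_genome_and_annotation(cfg)
        sk = sim.truth_events[sim.truth_events.event_type == "skiptic"]
        lengths = (sk.end - sk.start).to_numpy()
        assert np.all(lengths % 3 != 0)
        assert (sk.frame_status == "frameshift").all()

    def test_true_psi_in_unit_interval(self):
        sim = build_genome_and_annotation(SimulationConfig(seed=3, **TINY))
        assert sim.truth_events.psi_wt.between(0, 1).all()
        assert sim.truth_events.psi_mut.between(0, 1).all()


class TestClosedLoop:
    """Generated files parse cleanly through core_io and feed extraction."""

    def test_outputs_parse_and_match_memory(self, tmp_path):
        cfg = SimulationConfig(seed=5, **TINY)
        sim = simulate_study(cfg, outdir=tmp_path)
        models = read_gtf(tmp_path / "annotation.gtf")
        assert len(models) == len(sim.models)
        sheet = SampleSheet.from_tsv(tmp_path / "samples.tsv")
        sj = {s: tmp_path / "sj" / f"{s}.SJ.out.tab" for s in sheet.sample_ids}
        junctions = read_junction_counts(sj, sheet)
        mem = {j.key: {k: v for k, v in j.counts.items() if v > 0} for j in sim.junctions}
        mem = {k: v for k, v in mem.items() if v}
        disk = {j.key: j.counts for j in junctions}
        disk = {k: {s: c for s, c in v.items() if c > 0} for k, v in disk.items()}
        disk = {k: v for k, v in disk.items() if v}
        assert disk == mem
        read_crosslinks(tmp_path / "crosslinks.bed")
        read_bedgraph(tmp_path / "conservation.bedGraph")
        genome = FastaReader(tmp_path / "genome.fa")
        assert genome.fetch("chr1", 0, 50) == sim.genome["chr1"][:50]

    def test_every_truth_event_extractable(self, small_gof_sim):
        sim = small_gof_sim
        events = {e.event_id for e in extract_splice_events(sim.models, sim.junctions)}
        missing = set(sim.truth_events.event_id) - events
        assert not missing


class TestJunctionModel:
    def test_noiseless_psi_expectation(self):
        """PSI 0.75 with no dispersion: inclusion-junction mean ~ 3x the
        exclusion count (30 vs 10 at n=40)."""
        cfg = SimulationConfig(
            seed=2,
            regime="null",
            psi_logit_sd=0.0,
            coverage_dispersion=0.0,
            mean_coverage=4000.0,
            n_genes=30,
            n_skiptic=0,
            n_cryptic=0,
            n_shared_alt=0,
            n_null_cassette=20,
            n_retained_intron=0,
            n_alt5=0,
            n_alt3=0,
            n_alt_first=0,
            n_alt_last=0,
            n_mutually_exclusive=0,
            null_psi_range=(0.75, 0.75),
        )
        sim = simulate_study(cfg)
        jc = {j.key: j for j in sim.junctions}
        for g in sim.genes:
            if g.event is None:
                continue
            ev = g.event
            for s in sim.sheet.sample_ids:
                inc = np.mean([jc[k].count(s) for k in ev.inclusion_keys])
                exc = jc[ev.exclusion_keys[0]].count(s)
                psi = inc / (inc + exc)
                assert psi == pytest.approx(0.75, abs=0.03)

    def test_null_event_pooled_psi_near_truth(self):
        """Pooled PSI over samples at high coverage recovers the planted
        value within ~3 binomial standard errors."""
        cfg = SimulationConfig(
            seed=7,
            regime="null",
            psi_logit_sd=0.0,
            mean_coverage=500.0,
            n_genes=40,
            n_skiptic=0,
            n_cryptic=0,
            n_shared_alt=0,
            n_null_cassette=30,
            n_retained_intron=0,
            n_alt5=0,
            n_alt3=0,
            n_alt_first=0,
            n_alt_last=0,
            n_mutually_exclusive=0,
        )
        sim = simulate_study(cfg)
        jc = {j.key: j for j in sim.junctions}
        for g in sim.genes:
            if g.event is None:
                continue
            ev = g.event
            inc = np.mean(
                [
                    sum(jc[k].count(s) for s in sim.sheet.sample_ids)
                    for k in ev.inclusion_keys
                ]
            )
            exc = sum(jc[ev.exclusion_keys[0]].count(s) for s in sim.sheet.sample_ids)
            pooled = inc / (inc + exc)
            assert pooled == pytest.approx(ev.psi_wt, abs=0.03)


class TestCrosslinkPlacement:
    def test_background_zero_puts_all_sites_near_motifs(self):
        cfg = SimulationConfig(seed=5, crosslink_rate_background=0.0, **TINY)
        sim = simulate_study(cfg)
        motif_pos = []
        width = len(cfg.motif_seq)
        for g in sim.genes:
            if g.event is not None:
                motif_pos.extend(g.event.motif_positions)
        motif_pos = np.array(sorted(motif_pos))
        assert len(sim.crosslinks) > 0
        for s in sim.crosslinks:
            d = np.min(np.abs(motif_pos - s.pos))
            assert d <= cfg.crosslink_halfwidth + width

    def test_pentamer_census_around_sites(self):
        """UGUGU and GUGUG are the two most frequent pentamers around the
        emitted crosslink sites (direct census on the generated genome)."""
        from collections import Counter

        cfg = SimulationConfig(seed=5, crosslink_rate_background=0.0, **TINY)
        sim = simulate_study(cfg)
        fa = FastaReader(sim.genome)
        census = Counter()
        for s in sim.crosslinks:
            win = fa.fetch(s.chrom, s.pos - 10, s.pos + 11, s.strand).replace("T", "U")
            for i in range(len(win) - 4):
                census[win[i : i + 5]] += 1
        top2 = {k for k, _ in census.most_common(2)}
        assert top2 == {"UGUGU", "GUGUG"}


class TestConservationAndExpression:
    def test_noiseless_conservation_levels(self):
        cfg = SimulationConfig(seed=6, cons_sd=0.0, **TINY)
        sim = simulate_study(cfg)
        track_records = sim.conservation
        from skiptic.core_io import ScoreTrack

        track = ScoreTrack(track_records)
        for _, row in sim.truth_events.iterrows():
            if row.event_type not in ("skiptic", "cryptic"):
                continue
            mean, n = track.mean_scored(row.chrom, row.start, row.end)
            expected = cfg.cons_high if row.event_type == "skiptic" else cfg.cons_low
            assert n == row.end - row.start
            assert mean == pytest.approx(expected)

    def test_fold_change_reflected_in_counts(self):
        cfg = SimulationConfig(
            seed=8, expr_dispersion=1e-4, expr_mean=5000, frac_frameshift=1.0, **TINY
        )
        sim = simulate_study(cfg)
        counts = sim.gene_counts
        wt = counts[[s for s, c in sim.sheet.samples if c == "WT"]].mean(axis=1)
        mut = counts[[s for s, c in sim.sheet.samples if c == "MUT"]].mean(axis=1)
        down = sim.truth_genes[sim.truth_genes.true_fold_change < 1].gene_id
        assert len(down) == 5
        ratio = (mut[down] / wt[down]).mean()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_uncoupled_intron_length_uncorrelated_with_fold_change(self):
        sim = build_genome_and_annotation(SimulationConfig(seed=8, **TINY))
        tg = sim.truth_genes
        other = tg[tg.true_fold_change == 1.0]
        assert len(other) > 0  # fold change 1 by construction off coupling
        assert tg.true_fold_change.isin([1.0, 0.5]).all()
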