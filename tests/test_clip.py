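import numpy as np
import pytest

from skiptic.clip import (
    annotate_regions,
    binding_overlap_enrichment,
    call_clusters,
    flank_motif_enrichment,
    pentamer_enrichment,
    rna_map,
)
from skiptic.core_io import CrosslinkSite, FastaReader, GenomicInterval, TranscriptModel
from oracles import merge_clusters_oracle


def _site(pos, count=1, chrom="chr1", strand="+"):
    return CrosslinkSite(chrom, pos, strand, count)


class TestClusterCalling:
    def test_merge_rule(self):
        sites = [_site(10), _site(12), _site(40)]
        clusters = call_clusters(sites, max_gap=15, min_total=1)
        spans = [(c.interval.start, c.interval.end) for c in clusters]
        assert spans == [(10, 13), (40, 41)]
        assert call_clusters(sites, max_gap=15, min_total=3) == []

    def test_single_high_count_site(self):
        (c,) = call_clusters([_site(10, count=5)], max_gap=15, min_total=3)
        assert c.total == 5 and c.n_sites == 1

    def test_strands_never_merge(self):
        clusters = call_clusters(
            [_site(10, 3), _site(12, 3, strand="-")], max_gap=15, min_total=3
        )
        assert len(clusters) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equals_brute_force_oracle_on_random_sites(self, seed):
        rng = np.random.default_rng(seed)
        positions = sorted(set(rng.integers(0, 2500, 400).tolist()))
        sites = [
            _site(int(p), int(rng.integers(1, 4)), strand=("+" if rng.random() < 0.7 else "-"))
            for p in positions
        ]
        ours = {
            (c.interval.chrom, c.interval.strand, c.interval.start, c.interval.end, c.total, c.n_sites)
            for c in call_clusters(sites, max_gap=15, min_total=3)
        }
        oracle = set(merge_clusters_oracle(sites, 15, 3))
        assert ours == oracle


def _annotated_model():
    exons = (
        GenomicInterval("chr1", 0, 100, "+"),
        GenomicInterval("chr1", 500, 700, "+"),
        GenomicInterval("chr1", 1000, 1200, "+"),
    )
    return TranscriptModel("t1", "g1", exons, (50, 1100))


class TestRegionAnnotation:
    def test_intron_assignment(self):
        model = _annotated_model()
        from skiptic.clip import ClipCluster

        cl = ClipCluster(GenomicInterval("chr1", 300, 310, "+"), 5, 2)
        dist = annotate_regions([cl], [model])
        assert dist["intron"] == 1.0

    def test_precedence_cds_over_intron(self):
        model = _annotated_model()
        # second isoform where 550..650 is intronic
        iso2 = TranscriptModel(
            "t2",
            "g1",
            (
                GenomicInterval("chr1", 0, 100, "+"),
                GenomicInterval("chr1", 500, 540, "+"),
                GenomicInterval("chr1", 660, 700, "+"),
                GenomicInterval("chr1", 1000, 1200, "+"),
            ),
            (50, 1100),
        )
        from skiptic.clip import ClipCluster

        cl = ClipCluster(GenomicInterval("chr1", 598, 604, "+"), 5, 2)
        dist = annotate_regions([cl], [model, iso2])
        assert dist["cds_exon"] == 1.0

    def test_utr_split_by_strand(self):
        model = _annotated_model()
        from skiptic.clip import ClipCluster

        five = ClipCluster(GenomicInterval("chr1", 10, 20, "+"), 3, 1)
        three = ClipCluster(GenomicInterval("chr1", 1150, 1160, "+"), 3, 1)
        dist = annotate_regions([five, three], [model])
        assert dist["utr5"] == 0.5 and dist["utr3"] == 0.5

    def test_fractions_sum_to_one(self, small_gof_sim):
        sim = small_gof_sim
        clusters = call_clusters(sim.crosslinks)
        dist = annotate_regions(clusters, sim.models)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestPentamers:
    def test_pure_ug_windows_rank_ug_pentamers_top(self):
        genome = {"chr1": "TG" * 300 + "A" * 600}
        models = [
            TranscriptModel("t", "g", (GenomicInterval("chr1", 0, 1200, "+"),))
        ]
        sites = [_site(int(p)) for p in range(100, 400, 10)]
        scores = pentamer_enrichment(
            sites, FastaReader(genome), models, window=10, n_shuffle=20, seed=0
        )
        top2 = set(scores.top(2).index)
        assert top2 == {"UGUGU", "GUGUG"}

    def test_self_null_is_centred(self, small_gof_sim):
        """Foreground drawn from the null placement itself: mean pentamer z
        over all 1024 pentamers stays within +/-0.1."""
        sim = small_gof_sim
        rng = np.random.default_rng(0)
        fa = FastaReader(sim.genome)
        sites = []
        for g in sim.genes[:120]:
            for p in rng.integers(g.start, g.end, 4):
                sites.append(CrosslinkSite(g.chrom, int(p), g.strand, 1))
        scores = pentamer_enrichment(sites, fa, sim.models, window=20, n_shuffle=100, seed=1)
        assert abs(scores.z.mean()) <= 0.1

    def test_planted_motif_recovery(self, small_gof_sim):
        sim = small_gof_sim
        fa = FastaReader(sim.genome)
        scores = pentamer_enrichment(
            sim.crosslinks, fa, sim.models, window=20, n_shuffle=50, seed=0
        )
        assert scores.rank_of("UGUGU") <= 5


class TestFlankMotif:
    def _genome_and_exons(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("AC"), 20000))  # no TG motifs possible
        genome = {"chr1": seq}
        exons = [GenomicInterval("chr1", 1000 * i + 400, 1000 * i + 520, "+") for i in range(12)]
        return genome, exons

    def test_identity_set_gives_null(self):
        genome, exons = self._genome_and_exons()
        out = flank_motif_enrichment({"a": exons}, FastaReader(genome), exons)
        assert out.loc["a", "odds_ratio"] == pytest.approx(1.0)
        assert out.loc["a", "p"] == pytest.approx(1.0)

    def test_no_motif_anywhere_degenerate(self):
        genome, exons = self._genome_and_exons()
        out = flank_motif_enrichment({"a": exons[:6]}, FastaReader(genome), exons[6:])
        assert out.loc["a", "odds_ratio"] == 1.0 and out.loc["a", "p"] == 1.0

    def test_planted_downstream_motif_enriched(self):
        genome, exons = self._genome_and_exons()
        seq = list(genome["chr1"])
        fg = exons[:6]
        for e in fg:  # motif within 100 nt downstream of the exon end
            seq[e.end + 20 : e.end + 26] = list("TGTGTG")
        fa = FastaReader({"chr1": "".join(seq)})
        out = flank_motif_enrichment({"fg": fg}, fa, exons[6:])
        assert out.loc["fg", "fraction_with_motif"] == 1.0
        assert out.loc["fg", "p"] < 0.01
        assert np.isinf(out.loc["fg", "odds_ratio"])


class TestRnaMap:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        exons = [
            GenomicInterval("chr1", int(s), int(s) + 150, "+")
            for s in np.arange(60, 600_000, 1500)[:300]
        ]
        return exons, rng

    def test_coverage_bounded(self, small_gof_sim):
        sim = small_gof_sim
        clusters = call_clusters(sim.crosslinks)
        truth = sim.truth_events
        reg = [
            GenomicInterval(r.chrom, r.start, r.end, r.strand)
            for r in truth[truth.event_type == "skiptic"].itertuples()
        ]
        bg = [
            GenomicInterval(r.chrom, r.start, r.end, r.strand)
            for r in truth[truth.event_type == "null_cassette"].itertuples()
        ]
        prof = rna_map(clusters, reg, bg, n_boot=200, seed=0)
        finite = prof.regulated[np.isfinite(prof.regulated)]
        assert np.all((finite >= 0) & (finite <= 1))
        assert len(prof.positions) == 2 * (100 + 300)

    def test_self_background_mask_calibrated(self):
        """Using the regulated set as its own background keeps the
        significance mask at or below the ~5% bootstrap false-positive rate."""
        from skiptic.clip import ClipCluster

        exons, rng = self._setup()
        clusters = [
            ClipCluster(GenomicInterval("chr1", int(p), int(p) + 20, "+"), 5, 3)
            for p in rng.integers(0, 600_000, 400)
        ]
        prof = rna_map(clusters, exons, exons, n_boot=300, seed=1)
        assert prof.significant.mean() <= 0.08

    def test_planted_cluster_positions_localised(self):
        """Clusters at +20..+40 of the downstream intron of every regulated
        exon produce a mask concentrated there (within the smoothing span)."""
        from skiptic.clip import ClipCluster

        exons, _ = self._setup()
        reg, bg = exons[:40], exons[40:]
        clusters = [
            ClipCluster(GenomicInterval("chr1", e.end + 20, e.end + 40, "+"), 9, 3)
            for e in reg
        ]
        smooth = 15
        prof = rna_map(clusters, reg, bg, smooth=smooth, n_boot=300, seed=2)
        sig_idx = np.where(prof.significant)[0]
        assert len(sig_idx) > 0
        donor = prof.window_labels == "donor"
        offsets = prof.positions[prof.significant & donor]
        assert len(offsets) > 0
        assert offsets.min() >= 20 - smooth and offsets.max() <= 40 + smooth
        # nothing outside the donor window
        assert not np.any(prof.significant & ~donor)


class TestBindingOverlap:
    def test_full_and_empty_overlap(self):
        from skiptic.clip import ClipCluster

        exons = [GenomicInterval("chr1", 1000 * i, 1000 * i + 100, "+") for i in range(10)]
        clusters = [
            ClipCluster(GenomicInterval("chr1", e.start + 10, e.start + 30, "+"), 5, 2)
            for e in exons[:5]
        ]
        out = binding_overlap_enrichment(
            {"bound": exons[:5], "unbound": exons[5:]}, clusters, reference="unbound"
        )
        assert out.loc["bound", "fraction_bound"] == 1.0
        assert out.loc["unbound", "fraction_bound"] == 0.0
        out2 = binding_overlap_enrichment({"a": exons}, [], reference="a")
        assert out2.loc["a", "fraction_bound"] == 0.0

    def test_downstream_flank_counts_as_bound(self):
        from skiptic.clip import ClipCluster

        exon = GenomicInterval("chr1", 1000, 1100, "+")
        cl = ClipCluster(GenomicInterval("chr1", 1150, 1160, "+"), 5, 2)
        out = binding_overlap_enrichment({"a": [exon]}, [cl], flank=100, reference="a")
        assert out.loc["a", "fraction_bound"] == 1.0
        out = binding_overlap_enrichment({"a": [exon]}, [cl], flank=10, reference="a")
        assert out.loc["a", "fraction_bound"] == 0.0

    def test_minus_strand_flank_is_genomically_upstream(self):
        from skiptic.clip import ClipCluster

        exon = GenomicInterval("chr1", 1000, 1100, "-")
        cl = ClipCluster(GenomicInterval("chr1", 950, 960, "-"), 5, 2)
        out = binding_overlap_enrichment({"a": [exon]}, [cl], flank=100, reference="a")
        assert out.loc["a", "fraction_bound"] == 1.0
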