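"""Synthetic study generator.

Emits a complete, fully seeded synthetic experiment -- genome FASTA,
transcript annotation, per-sample splice-junction counts, iCLIP-style
crosslink sites, gene-level counts and a conservation track -- with planted
gain-of-function (GOF) and loss-of-function (LOF) splicing regimes and a
machine-readable truth table, so every downstream stage of the pipeline is
testable without external data.

The planted structures mirror the biology being modelled:

* *skiptic* exons: internal coding exons present in every annotated isoform
  (constitutive, WT PSI ~0.98) that are skipped under the GOF regime, with
  UG-repeat motifs written into the exon body and the first 100 nt of the
  downstream intron, where crosslink pileups are placed;
* *cryptic* exons: intronic segments absent from every annotated isoform
  (WT PSI ~0.01) that gain inclusion junctions under the LOF regime;
* shared alternative cassette exons (WT PSI 0.5) shifted in opposite
  directions by the two regimes;
* null cassettes and the remaining event classes (retained intron, alt
  5'/3' splice sites, alternative first/last exons, mutually exclusive
  exons) for taxonomy and calibration;
* negative-binomial gene counts, with frame-disrupting skips coupled to
  downregulation, and an optional long-intron expression-coupling mode;
* conservation high over skiptic exons, low over cryptic exons.

Replicate variability is modelled as logit-normal jitter of the per-sample
inclusion probability.  Everything derives from one seed through independent
substreams per output file, so regenerating any single output is
byte-deterministic.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core_io import (
    ConfigurationError,
    CrosslinkSite,
    GenomicInterval,
    SampleSheet,
    SpliceJunction,
    TranscriptModel,
    reverse_complement,
    write_bedgraph,
    write_crosslinks,
    write_fasta,
    write_gtf,
    write_junction_counts,
)
from .splicing import _event_id

REGIMES = ("GOF", "LOF", "null")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = np.array(
    [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]
)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults encode the simulated design used throughout: 4 replicates per
    condition, ~100x junction coverage, logit-scale biological PSI s.d. 0.3,
    planted |dPSI| 0.15, constitutive (skiptic) exons at WT PSI 0.98 and
    cryptic exons at WT PSI 0.01, a 0.5 expression fold change for genes
    whose skip disrupts the reading frame, and roughly one third of skips
    frame-disrupting.
    """

    seed: int = 0
    regime: str = "GOF"
    n_genes: int = 1700
    n_replicates: int = 4
    mean_coverage: float = 100.0
    coverage_dispersion: float = 0.1
    psi_logit_sd: float = 0.3
    # planted event counts
    n_skiptic: int = 30
    n_cryptic: int = 30
    n_shared_alt: int = 20
    n_null_cassette: int = 1500
    n_retained_intron: int = 10
    n_alt5: int = 10
    n_alt3: int = 10
    n_alt_first: int = 10
    n_alt_last: int = 10
    n_mutually_exclusive: int = 10
    # effect sizes
    dpsi_skiptic: float = 0.15
    dpsi_cryptic: float = 0.15
    dpsi_shared_alt: float = 0.15
    dpsi_retained_intron: float = 0.15
    psi_wt_skiptic: float = 0.98
    psi_wt_cryptic: float = 0.01
    psi_wt_shared_alt: float = 0.5
    retention_wt: float = 0.10
    null_psi_range: tuple = (0.05, 0.95)
    # consequence / expression coupling
    frac_frameshift: float = 15.0 / 48.0
    unstable_fold_change: float = 0.5
    expr_mean: float = 500.0
    expr_log_sd: float = 0.5
    expr_dispersion: float = 0.05
    long_intron_coupling: bool = False
    long_intron_beta: float = 0.75
    # motifs / crosslinks
    motif_seq: str = "TGTGTG"
    motif_copies_exon: int = 2
    motif_copies_intron: int = 3
    motif_intron_window: int = 100
    crosslink_rate_motif: float = 2.0
    crosslink_rate_background: float = 0.005
    crosslink_halfwidth: int = 10
    # conservation
    cons_high: float = 2.0
    cons_low: float = 0.0
    cons_mid: float = 0.5
    cons_sd: float = 0.5
    cons_bounds: tuple = (-2.0, 10.0)
    cons_segment: int = 25
    # geometry
    n_chroms: int = 2
    exon_len_range: tuple = (120, 200)
    internal_exon_codons: tuple = (33, 50)
    intron_len_range: tuple = (500, 900)
    intergenic_gap: tuple = (200, 400)
    utr5: int = 30

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ConfigurationError(f"regime must be one of {REGIMES}")
        if self.mean_coverage <= 0:
            raise ConfigurationError("mean_coverage must be positive")
        if self.psi_logit_sd < 0:
            raise ConfigurationError("psi_logit_sd must be non-negative")
        if self.n_planted > self.n_genes:
            raise ConfigurationError(
                f"{self.n_planted} planted events exceed {self.n_genes} genes"
            )

    @property
    def n_planted(self) -> int:
        return (
            self.n_skiptic
            + self.n_cryptic
            + self.n_shared_alt
            + self.n_null_cassette
            + self.n_retained_intron
            + self.n_alt5
            + self.n_alt3
            + self.n_alt_first
            + self.n_alt_last
            + self.n_mutually_exclusive
        )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class EventDesign:
    gene_id: str
    event_type: str  # skiptic, cryptic, shared_alt, null_cassette, ...
    event_id: str
    target: GenomicInterval
    inclusion_keys: tuple
    exclusion_keys: tuple
    psi_wt: float
    psi_mut: float
    frame_status: Optional[str] = None  # skiptic only
    motif_positions: tuple = ()


@dataclass
class GeneDesign:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    models: list
    constitutive_keys: list
    event: Optional[EventDesign]
    mean_intron_length: float
    base_expression: float = 0.0
    true_fold_change: float = 1.0


@dataclass
class Simulation:
    """The full synthetic study: design, truth tables and generated data."""

    config: SimulationConfig
    genome: dict
    genes: list
    models: list
    truth_events: pd.DataFrame
    truth_genes: pd.DataFrame = field(default=None)
    sheet: SampleSheet = field(default=None)
    junctions: list = field(default=None)
    intron_body: pd.DataFrame = field(default=None)
    gene_counts: pd.DataFrame = field(default=None)
    crosslinks: list = field(default=None)
    conservation: list = field(default=None)


def _rand_seq(rng, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, int(n))]


def _coding_seq(rng, n_codons: int) -> str:
    return "".join(rng.choice(_CODONS, int(n_codons)))


def _nb_draw(rng, mean, dispersion, size):
    """Negative binomial with var = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _psi_pair(cfg: SimulationConfig, event_type: str, psi_wt: float) -> tuple:
    """(psi_wt, psi_mut) for the configured regime."""
    if cfg.regime == "null":
        return psi_wt, psi_wt
    if event_type == "skiptic":
        return psi_wt, psi_wt - (cfg.dpsi_skiptic if cfg.regime == "GOF" else 0.0)
    if event_type == "cryptic":
        return psi_wt, psi_wt + (cfg.dpsi_cryptic if cfg.regime == "LOF" else 0.0)
    if event_type == "shared_alt":
        delta = -cfg.dpsi_shared_alt if cfg.regime == "GOF" else cfg.dpsi_shared_alt
        return psi_wt, psi_wt + delta
    if event_type == "retained_intron":
        return psi_wt, psi_wt + (cfg.dpsi_retained_intron if cfg.regime == "GOF" else 0.0)
    return psi_wt, psi_wt


# ---------------------------------------------------------------------------
# Genome + annotation
# ---------------------------------------------------------------------------

def build_genome_and_annotation(config: SimulationConfig) -> Simulation:
    """Construct the genome, transcript models and the truth table.

    Genes are laid out in transcript orientation and reverse-complemented
    onto the genome for minus-strand genes, so all sequence-level features
    (motifs, reading frames) are strand-aware by construction.  Internal CDS
    exon lengths are multiples of 3 (except frame-disrupting skiptic exons),
    which keeps codons within exons and makes in-frame skips PTC-free by
    design.
    """
    cfg = config
    root = np.random.SeedSequence([cfg.seed, 101])
    rng = np.random.default_rng(root)

    roles = (
        ["skiptic"] * cfg.n_skiptic
        + ["cryptic"] * cfg.n_cryptic
        + ["shared_alt"] * cfg.n_shared_alt
        + ["null_cassette"] * cfg.n_null_cassette
        + ["retained_intron"] * cfg.n_retained_intron
        + ["alt5"] * cfg.n_alt5
        + ["alt3"] * cfg.n_alt3
        + ["alt_first"] * cfg.n_alt_first
        + ["alt_last"] * cfg.n_alt_last
        + ["mutually_exclusive"] * cfg.n_mutually_exclusive
        + ["plain"] * (cfg.n_genes - cfg.n_planted)
    )
    roles = list(rng.permutation(roles))

    n_frameshift = int(round(cfg.frac_frameshift * cfg.n_skiptic))
    skiptic_frames = ["frameshift"] * n_frameshift + ["in_frame"] * (
        cfg.n_skiptic - n_frameshift
    )
    skiptic_frames = list(rng.permutation(skiptic_frames))

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_parts = {c: [] for c in chrom_names}
    chrom_len = {c: 0 for c in chrom_names}

    genes, models_all, truth_rows = [], [], []
    e_lo, e_hi = cfg.exon_len_range
    c_lo, c_hi = cfg.internal_exon_codons
    i_lo, i_hi = cfg.intron_len_range
    ski = 0

    for gi, role in enumerate(roles):
        gene_id = f"g{gi:05d}"
        chrom = chrom_names[gi % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"

        n_ex = int(rng.integers(4, 9))
        exon_lens = [int(rng.integers(e_lo, e_hi + 1))] + [
            3 * int(rng.integers(c_lo, c_hi + 1)) for _ in range(n_ex - 2)
        ] + [int(rng.integers(e_lo, e_hi + 1))]
        intron_lens = [int(rng.integers(i_lo, i_hi + 1)) for _ in range(n_ex - 1)]
        # internal target exon with internal flanks where a role needs one
        t = int(rng.integers(1, n_ex - 1))

        frame = None
        if role == "skiptic":
            frame = skiptic_frames[ski]
            ski += 1
            if frame == "frameshift":
                exon_lens[t] += int(rng.integers(1, 3))

        cds_first_exon = 0
        utr5_target = cfg.utr5
        if role == "alt_first":
            # CDS must start downstream of the alternative first exons so the
            # CDS anchors live in exons shared by both isoforms
            cds_first_exon = 1
            utr5_target = exon_lens[0] + cfg.utr5
        # align CDS start so internal exon boundaries are codon boundaries
        lead = sum(exon_lens[: cds_first_exon + 1])
        utr5 = lead - ((lead - utr5_target) // 3) * 3
        mrna_len = sum(exon_lens)
        utr3_target = 33 + (exon_lens[-1] if role == "alt_last" else 0)
        cds_len = mrna_len - utr5 - utr3_target
        cds_len -= cds_len % 3
        utr3 = mrna_len - utr5 - cds_len

        mrna = (
            "".join(chr(b) for b in _rand_seq(rng, utr5))
            + "ATG"
            + _coding_seq(rng, cds_len // 3 - 2)
            + "TAA"
            + "".join(chr(b) for b in _rand_seq(rng, utr3))
        )
        assert len(mrna) == mrna_len

        # exon tx coordinates within the gene
        exon_tx, pos = [], 0
        mrna_off = []
        off = 0
        for k in range(n_ex):
            exon_tx.append((pos, pos + exon_lens[k]))
            mrna_off.append(off)
            off += exon_lens[k]
            pos += exon_lens[k]
            if k < n_ex - 1:
                pos += intron_lens[k]
        gene_len = pos

        seq = _rand_seq(rng, gene_len)
        for k in range(n_ex):
            s, e = exon_tx[k]
            seq[s:e] = np.frombuffer(
                mrna[mrna_off[k] : mrna_off[k] + exon_lens[k]].encode(), dtype=np.uint8
            )

        def _intron_tx(k):
            return exon_tx[k][1], exon_tx[k + 1][0]

        # ------------------------------------------------------------------
        # role-specific extra features (tx coordinates)
        extra = {}
        motif_tx = []

        def _plant_motifs(lo, hi, copies):
            """Write UG-repeat copies into tx window [lo, hi)."""
            m = cfg.motif_seq
            width = len(m)
            if hi - lo < width or copies <= 0:
                return
            starts = np.sort(rng.choice(max(1, (hi - lo) - width), size=copies)) + lo
            for s in starts:
                seq[s : s + width] = np.frombuffer(m.encode(), dtype=np.uint8)
                motif_tx.append((int(s), width))

        if role == "skiptic":
            s, e = exon_tx[t]
            _plant_motifs(s, e, cfg.motif_copies_exon)
            ds, de = _intron_tx(t)
            _plant_motifs(ds, min(ds + cfg.motif_intron_window, de), cfg.motif_copies_intron)
        elif role == "cryptic":
            ds, de = _intron_tx(t - 1) if t >= 1 else _intron_tx(0)
            ce_len = 3 * int(rng.integers(c_lo, c_hi + 1)) + 1
            ce_s = ds + (de - ds - ce_len) // 2
            extra["cryptic"] = (ce_s, ce_s + ce_len)
            _plant_motifs(ce_s, ce_s + ce_len, cfg.motif_copies_exon)
            _plant_motifs(
                ce_s + ce_len,
                min(ce_s + ce_len + cfg.motif_intron_window, de),
                cfg.motif_copies_intron,
            )
        elif role == "alt5":
            # donor of exon t extended 30 nt into the downstream intron
            extra["ext"] = 30
        elif role == "alt3":
            # acceptor of exon t+1... modelled as exon t start moved 30 nt up
            extra["ext"] = 30
        elif role == "alt_first":
            ds, de = _intron_tx(0)
            alt_len = int(rng.integers(e_lo, e_hi + 1))
            a_s = ds + 150
            extra["alt_exon"] = (a_s, a_s + alt_len)
        elif role == "alt_last":
            ds, de = _intron_tx(n_ex - 2)
            alt_len = int(rng.integers(e_lo, e_hi + 1))
            a_s = ds + 150
            extra["alt_exon"] = (a_s, a_s + alt_len)
        elif role == "mutually_exclusive":
            ds, de = _intron_tx(t)
            alt_len = 3 * int(rng.integers(c_lo, c_hi + 1))
            a_s = ds + (de - ds - alt_len) // 2
            extra["alt_exon"] = (a_s, a_s + alt_len)

        # ------------------------------------------------------------------
        # genomic placement
        g0 = chrom_len[chrom]
        gseq = seq if strand == "+" else np.frombuffer(
            reverse_complement(bytes(seq).decode()).encode(), dtype=np.uint8
        )
        chrom_parts[chrom].append(gseq)
        gap = int(rng.integers(*cfg.intergenic_gap))
        chrom_parts[chrom].append(_rand_seq(rng, gap))
        chrom_len[chrom] += gene_len + gap

        def g_iv(ts, te):
            if strand == "+":
                return g0 + ts, g0 + te
            return g0 + gene_len - te, g0 + gene_len - ts

        def g_pos(tp):  # single base
            return g0 + tp if strand == "+" else g0 + gene_len - 1 - tp

        def jkey(ts, te):
            lo, hi = g_iv(ts, te)
            return (chrom, lo, hi, strand)

        exons_g = [GenomicInterval(chrom, *g_iv(s, e), strand) for s, e in exon_tx]
        cds_a = g_pos(_tx_of_mrna(utr5, exon_tx, mrna_off, exon_lens))
        cds_b = g_pos(_tx_of_mrna(utr5 + cds_len - 1, exon_tx, mrna_off, exon_lens))
        cds_span = (min(cds_a, cds_b), max(cds_a, cds_b) + 1)

        iso1 = TranscriptModel(f"{gene_id}.t1", gene_id, tuple(exons_g), cds_span)
        models = [iso1]
        chain_juncs = [jkey(*_intron_tx(k)) for k in range(n_ex - 1)]
        constitutive = list(chain_juncs)
        event = None
        target_g = None

        if role in ("skiptic", "cryptic", "shared_alt", "null_cassette"):
            if role == "cryptic":
                ce_s, ce_e = extra["cryptic"]
                d_tx = _intron_tx(t - 1)
                inc = (jkey(d_tx[0], ce_s), jkey(ce_e, d_tx[1]))
                exc = (jkey(*d_tx),)
                target_g = GenomicInterval(chrom, *g_iv(ce_s, ce_e), strand)
                psi_wt = cfg.psi_wt_cryptic
            else:
                s, e = exon_tx[t]
                inc = (jkey(_intron_tx(t - 1)[0], s), jkey(e, _intron_tx(t)[1]))
                exc = (jkey(_intron_tx(t - 1)[0], _intron_tx(t)[1]),)
                target_g = GenomicInterval(chrom, *g_iv(s, e), strand)
                psi_wt = {
                    "skiptic": cfg.psi_wt_skiptic,
                    "shared_alt": cfg.psi_wt_shared_alt,
                }.get(role)
                if psi_wt is None:
                    psi_wt = float(rng.uniform(*cfg.null_psi_range))
            if role in ("shared_alt", "null_cassette"):
                exons2 = tuple(x for k, x in enumerate(exons_g) if k != t)
                models.append(TranscriptModel(f"{gene_id}.t2", gene_id, exons2, cds_span))
            w, m = _psi_pair(cfg, role, psi_wt)
            # event-driven junctions must not also draw constitutive counts
            constitutive = [k for k in chain_juncs if k not in inc and k not in exc]
            motif_g = tuple(
                sorted(min(g_pos(p), g_pos(p + width - 1)) for p, width in motif_tx)
            )
            event = EventDesign(
                gene_id, role, _event_id("cassette", target_g), target_g, inc, exc,
                w, m, frame, motif_g,
            )
        elif role == "retained_intron":
            it = _intron_tx(t)
            key = jkey(*it)
            target_g = GenomicInterval(chrom, key[1], key[2], strand)
            merged = []
            for k, x in enumerate(exons_g):
                merged.append((exon_tx[k], x))
            lo_t = min(exon_tx[t][0], exon_tx[t + 1][0])
            hi_t = max(exon_tx[t][1], exon_tx[t + 1][1])
            exons2 = [x for (txc, x) in merged if txc not in (exon_tx[t], exon_tx[t + 1])]
            exons2.append(GenomicInterval(chrom, *g_iv(lo_t, hi_t), strand))
            models.append(TranscriptModel(f"{gene_id}.t2", gene_id, tuple(exons2), cds_span))
            constitutive = [k for k in chain_juncs if k != key]
            w, m = _psi_pair(cfg, role, cfg.retention_wt)
            event = EventDesign(
                gene_id, role, _event_id("retained_intron", target_g), target_g,
                (), (key,), w, m,
            )
        elif role in ("alt5", "alt3"):
            ext = extra["ext"]
            if role == "alt5":
                s, e = exon_tx[t]
                d0, d1 = _intron_tx(t)
                exons2 = list(exons_g)
                exons2[t] = GenomicInterval(chrom, *g_iv(s, e + ext), strand)
                j_short = jkey(e + ext, d1)
                j_long = jkey(d0, d1)
                var = (e, e + ext)
            else:
                s, e = exon_tx[t]
                d0, d1 = _intron_tx(t - 1)
                exons2 = list(exons_g)
                exons2[t] = GenomicInterval(chrom, *g_iv(s - ext, e), strand)
                j_short = jkey(d0, s - ext)
                j_long = jkey(d0, d1)
                var = (s - ext, s)
            models.append(TranscriptModel(f"{gene_id}.t2", gene_id, tuple(exons2), cds_span))
            lo, hi = g_iv(*var)
            target_g = GenomicInterval(chrom, lo, hi, strand)
            # donor/acceptor identity is intrinsic to the transcript, so the
            # class label is strand-independent
            cls = role
            constitutive = [k for k in chain_juncs if k != j_long]
            w, m = _psi_pair(cfg, role, 0.5)
            event = EventDesign(
                gene_id, role, _event_id(cls, target_g), target_g,
                (j_short,), (j_long,), w, m,
            )
        elif role in ("alt_first", "alt_last"):
            a_s, a_e = extra["alt_exon"]
            alt_g = GenomicInterval(chrom, *g_iv(a_s, a_e), strand)
            if role == "alt_first":
                anchor = _intron_tx(0)[1]
                j_main = jkey(_intron_tx(0)[0], anchor)
                j_alt = jkey(a_e, anchor)
                exons2 = [alt_g] + list(exons_g[1:])
            else:
                anchor = _intron_tx(n_ex - 2)[0]
                j_main = jkey(anchor, _intron_tx(n_ex - 2)[1])
                j_alt = jkey(anchor, a_s)
                exons2 = list(exons_g[:-1]) + [alt_g]
            models.append(
                TranscriptModel(
                    f"{gene_id}.t2", gene_id, tuple(sorted(exons2, key=lambda x: x.start)),
                    cds_span,
                )
            )
            term_main = exons_g[0] if role == "alt_first" else exons_g[-1]
            first, second = sorted((term_main, alt_g), key=lambda x: x.start)
            target_g = first
            inc, exc = (
                ((j_main,), (j_alt,))
                if first is term_main
                else ((j_alt,), (j_main,))
            )
            cls = role
            constitutive = [k for k in chain_juncs if k != j_main]
            w, m = _psi_pair(cfg, role, 0.5)
            event = EventDesign(
                gene_id, role, _event_id(cls, target_g), target_g,
                inc, exc, w, m,
            )
        elif role == "mutually_exclusive":
            a_s, a_e = extra["alt_exon"]
            alt_g = GenomicInterval(chrom, *g_iv(a_s, a_e), strand)
            s, e = exon_tx[t]
            p_end = _intron_tx(t - 1)[0]
            n_start = _intron_tx(t)[1]
            jA = (jkey(p_end, s), jkey(e, n_start))
            jB = (jkey(p_end, a_s), jkey(a_e, n_start))
            exons2 = [x for k, x in enumerate(exons_g) if exon_tx[k] != exon_tx[t]]
            exons2.append(alt_g)
            models.append(
                TranscriptModel(
                    f"{gene_id}.t2", gene_id,
                    tuple(sorted(exons2, key=lambda x: x.start)), cds_span,
                )
            )
            x_g = GenomicInterval(chrom, *g_iv(s, e), strand)
            first, second = sorted((x_g, alt_g), key=lambda z: z.start)
            target_g = first
            inc, exc = (jA, jB) if first is x_g else (jB, jA)
            constitutive = [
                k for k in chain_juncs if k not in jA
            ]
            w, m = _psi_pair(cfg, role, 0.5)
            event = EventDesign(
                gene_id, role, _event_id("mutually_exclusive", target_g), target_g,
                inc, exc, w, m,
            )

        gs, ge = g0, g0 + gene_len
        genes.append(
            GeneDesign(
                gene_id, chrom, strand, gs, ge, models, constitutive, event,
                float(np.mean(intron_lens)),
            )
        )
        models_all.extend(models)
        if event is not None:
            truth_rows.append(
                {
                    "event_id": event.event_id,
                    "gene_id": gene_id,
                    "event_type": event.event_type,
                    "chrom": event.target.chrom,
                    "start": event.target.start,
                    "end": event.target.end,
                    "strand": strand,
                    "psi_wt": event.psi_wt,
                    "psi_mut": event.psi_mut,
                    "frame_status": event.frame_status or "",
                    "motif_positions": ",".join(map(str, event.motif_positions)),
                }
            )

    genome = {
        c: bytes(np.concatenate(chrom_parts[c])).decode() if chrom_parts[c] else ""
        for c in chrom_names
    }
    truth_events = pd.DataFrame(truth_rows).set_index("event_id", drop=False)
    sim = Simulation(cfg, genome, genes, models_all, truth_events)
    _assign_expression_truth(sim, rng)
    return sim


def _tx_of_mrna(mpos: int, exon_tx, mrna_off, exon_lens) -> int:
    """Map an mRNA coordinate to the gene-local (tx-orientation) coordinate."""
    for k in range(len(exon_tx)):
        if mrna_off[k] <= mpos < mrna_off[k] + exon_lens[k]:
            return exon_tx[k][0] + (mpos - mrna_off[k])
    raise ValueError(f"mRNA position {mpos} outside exons")


def _assign_expression_truth(sim: Simulation, rng) -> None:
    cfg = sim.config
    base = np.exp(rng.normal(np.log(cfg.expr_mean), cfg.expr_log_sd, len(sim.genes)))
    lens = np.array([g.mean_intron_length for g in sim.genes])
    fc = np.ones(len(sim.genes))
    if cfg.long_intron_coupling:
        z = (np.log(lens) - np.log(lens).mean()) / max(np.log(lens).std(), 1e-9)
        fc = np.clip(2.0 ** (-cfg.long_intron_beta * z), 0.25, 4.0)
    for i, g in enumerate(sim.genes):
        g.base_expression = float(base[i])
        ev = g.event
        if (
            not cfg.long_intron_coupling
            and cfg.regime == "GOF"
            and ev is not None
            and ev.event_type == "skiptic"
            and ev.frame_status == "frameshift"
        ):
            g.true_fold_change = cfg.unstable_fold_change
        else:
            g.true_fold_change = float(fc[i])
    sim.truth_genes = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in sim.genes],
            "chrom": [g.chrom for g in sim.genes],
            "start": [g.start for g in sim.genes],
            "end": [g.end for g in sim.genes],
            "strand": [g.strand for g in sim.genes],
            "base_expression": [g.base_expression for g in sim.genes],
            "mean_intron_length": [g.mean_intron_length for g in sim.genes],
            "true_fold_change": [g.true_fold_change for g in sim.genes],
        }
    ).set_index("gene_id", drop=False)


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------

def default_sheet(cfg: SimulationConfig) -> SampleSheet:
    return SampleSheet(
        [(f"WT_{i + 1}", "WT") for i in range(cfg.n_replicates)]
        + [(f"MUT_{i + 1}", "MUT") for i in range(cfg.n_replicates)]
    )


def simulate_junction_counts(sim: Simulation) -> list:
    """Simulate per-sample junction counts for every gene.

    Per event and sample, total informative reads n ~ NB(coverage,
    dispersion); the sample's inclusion probability is a logit-normal draw
    around its condition's true PSI; inclusion reads ~ Binomial(n, PSI) are
    evidenced equally at each inclusion junction, the remainder at the
    exclusion junction.  Constitutive junctions draw independent NB counts.
    """
    cfg = sim.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 202, REGIMES.index(cfg.regime)])
    )
    sheet = default_sheet(cfg)
    sim.sheet = sheet
    samples = sheet.sample_ids
    is_mut = np.array([sheet.condition_of(s) == "MUT" for s in samples])
    S = len(samples)

    counts: dict = {}
    body_rows: dict = {}

    def _add(key, arr):
        if key in counts:
            counts[key] = counts[key] + arr
        else:
            counts[key] = arr

    def _jitter(psi_true):
        mu = np.where(is_mut, psi_true[1], psi_true[0])
        if cfg.psi_logit_sd <= 0:
            return mu
        interior = (mu > 0) & (mu < 1)
        out = np.array(mu, dtype=float)
        out[interior] = expit(
            logit(mu[interior]) + rng.normal(0, cfg.psi_logit_sd, interior.sum())
        )
        return out

    for g in sim.genes:
        for key in g.constitutive_keys:
            _add(key, _nb_draw(rng, cfg.mean_coverage, cfg.coverage_dispersion, S))
        ev = g.event
        if ev is None:
            continue
        n = _nb_draw(rng, cfg.mean_coverage, cfg.coverage_dispersion, S)
        psi = _jitter((ev.psi_wt, ev.psi_mut))
        inc = rng.binomial(n, psi)
        exc = n - inc
        if ev.event_type == "retained_intron":
            body = inc
            key = ev.exclusion_keys[0]
            _add(key, exc)
            body_rows[f"{key[0]}:{key[1]}-{key[2]}:{key[3]}"] = body
            continue
        n_inc = len(ev.inclusion_keys)
        if n_inc == 2:
            j1 = rng.binomial(2 * inc, 0.5)
            _add(ev.inclusion_keys[0], j1)
            _add(ev.inclusion_keys[1], 2 * inc - j1)
        elif n_inc == 1:
            _add(ev.inclusion_keys[0], inc)
        n_exc = len(ev.exclusion_keys)
        if n_exc == 2:
            j1 = rng.binomial(2 * exc, 0.5)
            _add(ev.exclusion_keys[0], j1)
            _add(ev.exclusion_keys[1], 2 * exc - j1)
        elif n_exc == 1:
            _add(ev.exclusion_keys[0], exc)

    junctions = []
    for key in sorted(counts):
        arr = counts[key]
        cmap = {s: int(arr[i]) for i, s in enumerate(samples) if arr[i] > 0}
        junctions.append(SpliceJunction(GenomicInterval(key[0], key[1], key[2], key[3]), cmap))
    sim.junctions = junctions
    sim.intron_body = pd.DataFrame.from_dict(
        body_rows, orient="index", columns=samples, dtype=float
    )
    sim.intron_body.index.name = "intron"
    return junctions


# ---------------------------------------------------------------------------
# Crosslinks
# ---------------------------------------------------------------------------

def simulate_crosslinks(sim: Simulation) -> list:
    """Poisson crosslink pileups around planted motifs plus a uniform
    background over expressed gene bodies; strand follows the gene."""
    cfg = sim.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 303, REGIMES.index(cfg.regime)])
    )
    per_strand: dict = {}

    for g in sim.genes:
        ev = g.event
        if ev is None or not ev.motif_positions:
            continue
        width = len(cfg.motif_seq)
        for mp in ev.motif_positions:
            lo = mp - cfg.crosslink_halfwidth
            hi = mp + width + cfg.crosslink_halfwidth
            k = rng.poisson(cfg.crosslink_rate_motif, hi - lo)
            pos = np.arange(lo, hi)[k > 0]
            cnt = k[k > 0]
            d = per_strand.setdefault((g.chrom, g.strand), {})
            for p, c in zip(pos, cnt):
                d[int(p)] = d.get(int(p), 0) + int(c)

    if cfg.crosslink_rate_background > 0:
        for g in sim.genes:
            span = g.end - g.start
            nbg = rng.poisson(cfg.crosslink_rate_background * span)
            if nbg == 0:
                continue
            pos = rng.integers(g.start, g.end, nbg)
            d = per_strand.setdefault((g.chrom, g.strand), {})
            for p in pos:
                d[int(p)] = d.get(int(p), 0) + 1

    sites = []
    for (chrom, strand), d in per_strand.items():
        for p, c in d.items():
            sites.append(CrosslinkSite(chrom, p, strand, c))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    sim.crosslinks = sites
    return sites


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(sim: Simulation) -> pd.DataFrame:
    """Negative-binomial gene counts; mutant means scaled by the gene's true
    fold change."""
    cfg = sim.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 404, REGIMES.index(cfg.regime)])
    )
    sheet = sim.sheet or default_sheet(cfg)
    sim.sheet = sheet
    samples = sheet.sample_ids
    is_mut = np.array([sheet.condition_of(s) == "MUT" for s in samples])
    rows = {}
    for g in sim.genes:
        mu = g.base_expression * np.where(is_mut, g.true_fold_change, 1.0)
        rows[g.gene_id] = _nb_draw(rng, mu, cfg.expr_dispersion, len(samples))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df.index.name = "gene_id"
    sim.gene_counts = df
    return df


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def simulate_conservation(sim: Simulation) -> list:
    """Piecewise-constant per-base conservation: high over skiptic exons,
    low over cryptic exons, intermediate over all other exonic sequence."""
    cfg = sim.config
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 505, REGIMES.index(cfg.regime)])
    )
    lo_b, hi_b = cfg.cons_bounds
    records = []

    def _emit(chrom, start, end, mean):
        seg = max(1, cfg.cons_segment)
        edges = list(range(start, end, seg)) + [end]
        for a, b in zip(edges, edges[1:]):
            v = mean if cfg.cons_sd == 0 else float(
                np.clip(rng.normal(mean, cfg.cons_sd), lo_b, hi_b)
            )
            records.append((chrom, a, b, v))

    for g in sim.genes:
        ev = g.event
        special = None
        if ev is not None and ev.event_type == "skiptic":
            special = (ev.target, cfg.cons_high)
        elif ev is not None and ev.event_type == "cryptic":
            special = (ev.target, cfg.cons_low)
        ivs = sorted({(e.start, e.end) for m in g.models for e in m.exons})
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        sp_s, sp_e = (special[0].start, special[0].end) if special else (None, None)
        for s, e in merged:
            if special is not None and s < sp_e and sp_s < e:
                if s < sp_s:
                    _emit(g.chrom, s, sp_s, cfg.cons_mid)
                if sp_e < e:
                    _emit(g.chrom, sp_e, e, cfg.cons_mid)
            else:
                _emit(g.chrom, s, e, cfg.cons_mid)
        if special is not None:
            _emit(g.chrom, sp_s, sp_e, special[1])

    records.sort(key=lambda r: (r[0], r[1]))
    sim.conservation = records
    return records


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, outdir=None) -> Simulation:
    """Run all five generators from one seed; optionally write every output
    file (FASTA, GTF, SJ.out.tab per sample, sample sheet, crosslink BED,
    gene counts, intron-body counts, conservation bedGraph, truth tables)."""
    sim = build_genome_and_annotation(config)
    simulate_junction_counts(sim)
    simulate_crosslinks(sim)
    simulate_expression(sim)
    simulate_conservation(sim)
    if outdir is not None:
        write_outputs(sim, outdir)
    return sim


def write_outputs(sim: Simulation, outdir) -> dict:
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_fasta(sim.genome, _p("genome.fa"))
    write_gtf(sim.models, _p("annotation.gtf"))
    sim.sheet.to_tsv(_p("samples.tsv"))
    sjdir = os.path.join(outdir, "sj")
    os.makedirs(sjdir, exist_ok=True)
    paths["sj"] = {}
    for s in sim.sheet.sample_ids:
        path = os.path.join(sjdir, f"{s}.SJ.out.tab")
        write_junction_counts(sim.junctions, s, path)
        paths["sj"][s] = path
    write_crosslinks(sim.crosslinks, _p("crosslinks.bed"))
    write_bedgraph(sim.conservation, _p("conservation.bedGraph"))
    sim.gene_counts.to_csv(_p("gene_counts.tsv"), sep="\t")
    sim.intron_body.to_csv(_p("intron_body.tsv"), sep="\t")
    sim.truth_events.to_csv(_p("truth_events.tsv"), sep="\t", index=False)
    sim.truth_genes.to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
    return paths
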