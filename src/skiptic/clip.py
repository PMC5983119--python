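"""iCLIP computational analysis.

Single-nucleotide crosslink sites are merged into clusters by single-linkage
on genomic distance; clusters are placed into genomic regions, scored for
pentamer enrichment against a within-gene shuffled null, and summarised as
RNA maps: positional cluster-coverage profiles around the boundaries of a
regulated exon set compared with a non-regulated background set, with a
bootstrap significance mask.

All sequence operations are strand-aware; minus-strand windows are
reverse-complemented before k-mer counting, and strand "." sites are
excluded from sequence-based analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import FastaReader, GenomicInterval, TranscriptModel

DEFAULT_MAX_GAP = 15
DEFAULT_MIN_TOTAL = 3


@dataclass(frozen=True)
class ClipCluster:
    interval: GenomicInterval
    total: int
    n_sites: int

    def __post_init__(self):
        if not (self.total >= self.n_sites >= 1):
            raise ValueError("cluster requires total >= n_sites >= 1")


def call_clusters(
    sites,
    max_gap: int = DEFAULT_MAX_GAP,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> list:
    """Single-linkage merge of same-strand sites with inter-site distance
    <= max_gap; keep clusters whose total crosslink count >= min_total."""
    if max_gap < 0 or min_total < 1:
        raise ValueError("max_gap >= 0 and min_total >= 1 required")
    by_key: dict = {}
    for s in sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s)
    clusters = []
    for (chrom, strand), group in sorted(by_key.items()):
        group.sort(key=lambda s: s.pos)
        run = [group[0]]
        for s in group[1:]:
            if s.pos - run[-1].pos <= max_gap:
                run.append(s)
            else:
                clusters.append(_finish(run, chrom, strand))
                run = [s]
        clusters.append(_finish(run, chrom, strand))
    clusters = [c for c in clusters if c.total >= min_total]
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.strand))
    return clusters


def _finish(run, chrom, strand) -> ClipCluster:
    iv = GenomicInterval(chrom, run[0].pos, run[-1].pos + 1, strand)
    return ClipCluster(iv, sum(s.count for s in run), len(run))


# ---------------------------------------------------------------------------
# Region annotation
# ---------------------------------------------------------------------------

REGIONS = ("cds_exon", "utr3", "utr5", "intron", "intergenic")


def annotate_regions(clusters, models) -> pd.Series:
    """Distribution of cluster midpoints over genomic regions.

    Midpoints are assigned with precedence CDS exon > 3'UTR > 5'UTR >
    intron > intergenic across all overlapping same-strand isoforms;
    fractions sum to 1.
    """
    by_chrom: dict = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for v in by_chrom.values():
        v.sort(key=lambda m: m.start)
    starts = {c: np.array([m.start for m in v]) for c, v in by_chrom.items()}

    rank = {r: i for i, r in enumerate(REGIONS)}
    counts = dict.fromkeys(REGIONS, 0)
    for cl in clusters:
        mid = cl.interval.midpoint
        chrom, strand = cl.interval.chrom, cl.interval.strand
        best = "intergenic"
        if chrom in by_chrom:
            i0 = int(np.searchsorted(starts[chrom], mid, side="right"))
            for m in by_chrom[chrom][max(0, i0 - 50) : i0]:
                if not (m.start <= mid < m.end):
                    continue
                if strand != "." and m.strand != strand:
                    continue
                r = _region_in_model(m, mid)
                if rank[r] < rank[best]:
                    best = r
        counts[best] += 1
    total = max(sum(counts.values()), 1)
    return pd.Series({r: counts[r] / total for r in REGIONS})


def _region_in_model(m: TranscriptModel, pos: int) -> str:
    in_exon = any(e.start <= pos < e.end for e in m.exons)
    if not in_exon:
        return "intron"
    if m.cds is None:
        return "cds_exon"
    cs, ce = m.cds
    if cs <= pos < ce:
        return "cds_exon"
    before = pos < cs
    if m.strand == "+":
        return "utr5" if before else "utr3"
    return "utr3" if before else "utr5"


# ---------------------------------------------------------------------------
# Pentamer enrichment
# ---------------------------------------------------------------------------

PENTAMERS = ["".join(p).replace("T", "U") for p in product("ACGT", repeat=5)]
_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _count_pentamers(seqs) -> np.ndarray:
    """Count all 4^5 pentamers over a list of DNA strings (vectorized)."""
    counts = np.zeros(1024, dtype=np.int64)
    for s in seqs:
        arr = _BASE_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
        if len(arr) < 5:
            continue
        valid = arr >= 0
        code = (
            arr[:-4] * 256 + arr[1:-3] * 64 + arr[2:-2] * 16 + arr[3:-1] * 4 + arr[4:]
        )
        ok = valid[:-4] & valid[1:-3] & valid[2:-2] & valid[3:-1] & valid[4:]
        counts += np.bincount(code[ok], minlength=1024)
    return counts


@dataclass
class PentamerScores:
    z: pd.Series  # pentamer -> z-score
    observed: pd.Series
    null_mean: pd.Series
    null_sd: pd.Series

    def top(self, n: int = 10) -> pd.Series:
        return self.z.sort_values(ascending=False).head(n)

    def rank_of(self, pentamer: str) -> int:
        order = self.z.sort_values(ascending=False).index
        return int(order.get_loc(pentamer)) + 1


def pentamer_enrichment(
    sites,
    genome: FastaReader,
    models,
    window: int = 20,
    n_shuffle: int = 100,
    seed: int = 0,
) -> PentamerScores:
    """Pentamer z-scores in +/-window nt around crosslink sites vs a null of
    equally many sites placed uniformly within the same genes.

    The within-gene null controls for gene-level base composition without
    modelling it.  Strand "." sites and sites outside any gene are skipped
    with a warning.
    """
    if window < 5 or n_shuffle < 10:
        raise ValueError("window >= 5 and n_shuffle >= 10 required")
    rng = np.random.default_rng(seed)

    genes: dict = {}
    for m in models:
        key = m.gene_id
        if key not in genes:
            genes[key] = [m.chrom, m.strand, m.start, m.end]
        else:
            genes[key][2] = min(genes[key][2], m.start)
            genes[key][3] = max(genes[key][3], m.end)
    gene_list = sorted(genes.values(), key=lambda g: (g[0], g[2]))
    by_chrom: dict = {}
    for g in gene_list:
        by_chrom.setdefault(g[0], []).append(g)
    gstarts = {c: np.array([g[2] for g in v]) for c, v in by_chrom.items()}

    assigned = []  # (chrom, strand, gene_start, gene_end, pos)
    skipped = 0
    for s in sites:
        if s.strand == ".":
            skipped += 1
            continue
        host = None
        if s.chrom in by_chrom:
            i0 = int(np.searchsorted(gstarts[s.chrom], s.pos, side="right"))
            for g in by_chrom[s.chrom][max(0, i0 - 50) : i0]:
                if g[2] <= s.pos < g[3] and g[1] == s.strand:
                    host = g
                    break
        if host is None:
            skipped += 1
            continue
        assigned.append((s.chrom, s.strand, host[2], host[3], s.pos))
    if skipped:
        warnings.warn(f"{skipped} crosslink sites outside genes or unstranded; skipped")
    if not assigned:
        raise ValueError("no crosslink sites within annotated genes")

    def _windows(positions):
        seqs = []
        for (chrom, strand, _gs, _ge, pos) in positions:
            lo = max(0, pos - window)
            hi = min(genome.length(chrom), pos + window + 1)
            seqs.append(genome.fetch(chrom, lo, hi, strand))
        return seqs

    obs = _count_pentamers(_windows(assigned)).astype(float)

    null_counts = np.zeros((n_shuffle, 1024))
    arr = np.array([(a[2], a[3]) for a in assigned])
    for b in range(n_shuffle):
        pos = rng.integers(arr[:, 0], arr[:, 1])
        shuffled = [
            (a[0], a[1], a[2], a[3], int(p)) for a, p in zip(assigned, pos)
        ]
        null_counts[b] = _count_pentamers(_windows(shuffled))
    mu = null_counts.mean(axis=0)
    sd = null_counts.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mu) / sd, 0.0)
    idx = pd.Index(PENTAMERS, name="pentamer")
    return PentamerScores(
        pd.Series(z, index=idx),
        pd.Series(obs, index=idx),
        pd.Series(mu, index=idx),
        pd.Series(sd, index=idx),
    )


# ---------------------------------------------------------------------------
# Flank motif enrichment
# ---------------------------------------------------------------------------

def _exon_flank_seq(genome: FastaReader, exon: GenomicInterval, flank: int) -> str:
    lo = max(0, exon.start - flank)
    hi = min(genome.length(exon.chrom), exon.end + flank)
    return genome.fetch(exon.chrom, lo, hi, exon.strand)


def flank_motif_enrichment(
    exon_sets: dict,
    genome: FastaReader,
    background,
    motif: str = "UGUGUG",
    flank: int = 100,
) -> pd.DataFrame:
    """Per exon set: fraction of exons whose body +/- flank nt of adjacent
    intron contains the motif, with Fisher's exact test vs the background
    exon set."""
    dna = motif.replace("U", "T").upper()

    def _has(exons):
        return np.array([dna in _exon_flank_seq(genome, e, flank) for e in exons])

    bg = _has(background)
    rows = []
    for name, exons in exon_sets.items():
        fg = _has(exons)
        table = [
            [int(fg.sum()), int((~fg).sum())],
            [int(bg.sum()), int((~bg).sum())],
        ]
        if fg.sum() == 0 and bg.sum() == 0:
            odds, p = 1.0, 1.0
        else:
            odds, p = sps.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "set": name,
                "n": len(exons),
                "fraction_with_motif": float(fg.mean()) if len(exons) else np.nan,
                "background_fraction": float(bg.mean()),
                "odds_ratio": float(odds),
                "p": float(p),
            }
        )
    return pd.DataFrame(rows).set_index("set")


# ---------------------------------------------------------------------------
# RNA map
# ---------------------------------------------------------------------------

@dataclass
class RnaMapProfile:
    """Positional cluster coverage around exon boundaries.

    Positions run over two windows: around the exon start (acceptor, 3'SS in
    transcript orientation) from -intron_pad to +exon_pad, and around the
    exon end (donor, 5'SS) from -exon_pad to +intron_pad; minus-strand exons
    are flipped so "upstream" is always 5' in the transcript.
    """

    positions: np.ndarray  # offsets, concatenated windows
    window_labels: np.ndarray  # "acceptor" / "donor"
    regulated: np.ndarray  # smoothed coverage in [0,1]
    background: np.ndarray
    significant: np.ndarray  # bool mask
    dpsi_sign: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "window": self.window_labels,
                "offset": self.positions,
                "regulated_coverage": self.regulated,
                "background_coverage": self.background,
                "significant": self.significant,
            }
        )


def _coverage_matrix(exons, clusters_by, exon_pad, intron_pad):
    """Per-exon binary coverage over the two boundary windows; positions
    beyond the exon body are NaN-masked."""
    width = exon_pad + intron_pad
    n = len(exons)
    mat = np.zeros((n, 2 * width))
    mask = np.ones((n, 2 * width), dtype=bool)
    for i, e in enumerate(exons):
        length = e.end - e.start
        ivs = clusters_by.get((e.chrom, e.strand), np.empty((0, 2), dtype=np.int64))
        # genomic offsets (acceptor window then donor window, genome-ordered)
        if e.strand == "+":
            acc0, don0 = e.start, e.end
            acc = np.arange(acc0 - intron_pad, acc0 + exon_pad)
            don = np.arange(don0 - exon_pad, don0 + intron_pad)
        else:
            acc0, don0 = e.end, e.start
            acc = np.arange(acc0 + intron_pad, acc0 - exon_pad, -1) - 1
            don = np.arange(don0 + exon_pad, don0 - intron_pad, -1) - 1
        pos = np.concatenate([acc, don])
        if len(ivs):
            covered = np.zeros(len(pos), dtype=bool)
            lo = np.searchsorted(ivs[:, 1], pos, side="right")
            hi = np.searchsorted(ivs[:, 0], pos, side="right")
            covered = hi > lo
            mat[i] = covered.astype(float)
        # mask exon-body positions beyond the actual exon length
        rel = np.concatenate(
            [np.arange(-intron_pad, exon_pad), np.arange(-exon_pad, intron_pad)]
        )
        exonic_acc = (rel[:width] >= 0) & (rel[:width] >= length)
        exonic_don = (rel[width:] < 0) & (rel[width:] < -length)
        mask[i, :width] = ~exonic_acc
        mask[i, width:] = ~exonic_don
    mat[~mask] = np.nan
    return mat


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    out = np.copy(x)
    finite = np.isfinite(x)
    xf = np.where(finite, x, 0.0)
    num = np.convolve(xf, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    return out


def rna_map(
    clusters,
    regulated,
    background,
    exon_pad: int = 100,
    intron_pad: int = 300,
    smooth: int = 15,
    n_boot: int = 1000,
    seed: int = 0,
    dpsi_sign: int = 0,
) -> RnaMapProfile:
    """Cluster-coverage RNA map around regulated exon boundaries vs a
    background exon set, with a bootstrap 95th-percentile significance mask.

    Coverage at a position is the fraction of exons in the set with a
    cluster overlapping that (strand-oriented) position.  The mask marks
    positions where smoothed regulated coverage exceeds the 95th percentile
    of coverage over ``n_boot`` equal-size background resamples.
    """
    if not len(regulated) or not len(background):
        raise ValueError("regulated and background exon sets must be non-empty")
    rng = np.random.default_rng(seed)
    clusters_by: dict = {}
    for c in clusters:
        clusters_by.setdefault((c.interval.chrom, c.interval.strand), []).append(
            (c.interval.start, c.interval.end)
        )
    clusters_by = {
        k: np.array(sorted(v), dtype=np.int64) for k, v in clusters_by.items()
    }

    reg = _coverage_matrix(regulated, clusters_by, exon_pad, intron_pad)
    bg = _coverage_matrix(background, clusters_by, exon_pad, intron_pad)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        reg_cov = _smooth(np.nanmean(reg, axis=0), smooth)
        bg_cov = _smooth(np.nanmean(bg, axis=0), smooth)

        n = len(regulated)
        boot = np.empty((n_boot, reg.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, len(background), n)
            boot[b] = _smooth(np.nanmean(bg[idx], axis=0), smooth)
    q95 = np.nanpercentile(boot, 95, axis=0)
    sig = np.isfinite(reg_cov) & (reg_cov > q95)

    width = exon_pad + intron_pad
    positions = np.concatenate(
        [np.arange(-intron_pad, exon_pad), np.arange(-exon_pad, intron_pad)]
    )
    labels = np.array(["acceptor"] * width + ["donor"] * width)
    return RnaMapProfile(positions, labels, reg_cov, bg_cov, sig, dpsi_sign)


# ---------------------------------------------------------------------------
# Binding overlap
# ---------------------------------------------------------------------------

def binding_overlap_enrichment(
    exon_sets: dict,
    clusters,
    flank: int = 100,
    reference: str = None,
) -> pd.DataFrame:
    """Fraction of exons per set with >= 1 cluster overlapping the exon body
    or its downstream-intron flank, with Fisher's exact test vs a reference
    set (default: the last set)."""
    clusters_by: dict = {}
    for c in clusters:
        clusters_by.setdefault((c.interval.chrom, c.interval.strand), []).append(
            (c.interval.start, c.interval.end)
        )
    clusters_by = {
        k: np.array(sorted(v), dtype=np.int64) for k, v in clusters_by.items()
    }

    def _bound(exon: GenomicInterval) -> bool:
        if exon.strand == "-":
            lo, hi = exon.start - flank, exon.end
        else:
            lo, hi = exon.start, exon.end + flank
        ivs = clusters_by.get((exon.chrom, exon.strand))
        if ivs is None or not len(ivs):
            return False
        i = np.searchsorted(ivs[:, 0], hi, side="left")
        return bool((ivs[:i, 1] > lo).any())

    flags = {}
    for name, exons in list(exon_sets.items()):
        if not len(exons):
            warnings.warn(f"exon set {name!r} is empty; excluded")
            continue
        flags[name] = np.array([_bound(e) for e in exons])
    if reference is None:
        reference = list(flags)[-1]
    ref = flags[reference]
    rows = []
    for name, fg in flags.items():
        table = [
            [int(fg.sum()), int((~fg).sum())],
            [int(ref.sum()), int((~ref).sum())],
        ]
        p = 1.0 if name == reference else float(
            sps.fisher_exact(table, alternative="two-sided")[1]
        )
        rows.append(
            {
                "set": name,
                "n": len(fg),
                "fraction_bound": float(fg.mean()),
                "p_vs_reference": p,
            }
        )
    return pd.DataFrame(rows).set_index("set")
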