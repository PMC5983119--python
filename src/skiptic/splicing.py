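"""Splice-event extraction, PSI quantification and two-group differential
splicing.

Events are derived two ways: by comparing annotated isoforms within a gene
(cassette, retained intron, alternative 5'/3' splice sites, alternative
first/last exons, mutually exclusive exons), and from junction evidence alone
-- an observed junction pair bracketing an unannotated segment yields a
cryptic-exon candidate, and an observed junction skipping an annotated
constitutive exon yields a cassette event even when no skipping isoform is
annotated.

PSI for a cassette exon is mean(inclusion-junction counts) divided by that
mean plus the exclusion-junction count; a sample is informative for an event
only when the denominator reaches ``min_total`` reads.  The differential test
is a beta-binomial likelihood-ratio test (condition-specific vs shared
inclusion probability, shared method-of-moments dispersion, chi-squared(1)
reference), falling back to Fisher's exact test on pooled counts when either
condition has fewer than two informative replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import (
    DataError,
    GenomicInterval,
    SampleSheet,
    SpliceJunction,
    TranscriptModel,
)
from .stats import (
    bh_adjust,
    betabinom_profile_mu,
    betabinom_rho_mom,
    signed_z,
)

EVENT_CLASSES = (
    "cassette",
    "retained_intron",
    "alt5",
    "alt3",
    "alt_first",
    "alt_last",
    "mutually_exclusive",
)


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    gene_id: str
    event_class: str
    target: GenomicInterval
    inclusion_junctions: tuple
    exclusion_junctions: tuple
    annotated: bool = True

    def __post_init__(self):
        if self.event_class not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.event_class == "cassette":
            if len(self.inclusion_junctions) != 2 or len(self.exclusion_junctions) != 1:
                raise ValueError("cassette events need 2 inclusion / 1 exclusion junction")
        if self.event_class == "retained_intron" and len(self.exclusion_junctions) != 1:
            raise ValueError("retained-intron events reference exactly 1 junction")


def _event_id(event_class: str, target: GenomicInterval, extra: str = "") -> str:
    base = f"{event_class}:{target.chrom}:{target.start}-{target.end}:{target.strand}"
    return base + (f":{extra}" if extra else "")


# ---------------------------------------------------------------------------
# Event extraction
# ---------------------------------------------------------------------------

def _pairwise_events(a: TranscriptModel, b: TranscriptModel) -> list:
    """Classify the splice variation between two isoforms of one gene."""
    out = []
    chrom, strand = a.chrom, a.strand
    ja, jb = set(a.junctions()), set(b.junctions())
    bounds_b = {(e.start, e.end) for e in b.exons}

    # cassette: internal exon of a absent from b, with b splicing flank->flank
    for i in range(1, len(a.exons) - 1):
        prev, mid, nxt = a.exons[i - 1 : i + 2]
        if (prev.end, nxt.start) in jb and (mid.start, mid.end) not in bounds_b:
            out.append(
                SpliceEvent(
                    _event_id("cassette", mid),
                    a.gene_id,
                    "cassette",
                    mid,
                    ((chrom, prev.end, mid.start, strand), (chrom, mid.end, nxt.start, strand)),
                    ((chrom, prev.end, nxt.start, strand),),
                )
            )

    # retained intron: junction of a lies strictly inside one exon of b
    for s, e in ja:
        for ex in b.exons:
            if ex.start < s and e < ex.end:
                target = GenomicInterval(chrom, s, e, strand)
                out.append(
                    SpliceEvent(
                        _event_id("retained_intron", target),
                        a.gene_id,
                        "retained_intron",
                        target,
                        (),
                        ((chrom, s, e, strand),),
                    )
                )

    # alternative donor/acceptor: junction pairs sharing one boundary; the
    # variable region must be exonic in the isoform using the inner boundary
    # (this is what separates a genuine splice-site shift from the junction
    # geometry of a skipped exon)
    def _exon_ending_at(model, pos):
        return next((e for e in model.exons if e.end == pos), None)

    def _exon_starting_at(model, pos):
        return next((e for e in model.exons if e.start == pos), None)

    for (s1, e1) in ja - jb:
        for (s2, e2) in jb - ja:
            if e1 == e2 and s1 != s2:
                lo, hi = sorted((s1, s2))
                owner = a if s1 == hi else b
                ex = _exon_ending_at(owner, hi)
                if ex is None or ex.start > lo:
                    continue
                target = GenomicInterval(chrom, lo, hi, strand)
                cls = "alt5" if strand == "+" else "alt3"
                out.append(
                    SpliceEvent(
                        _event_id(cls, target),
                        a.gene_id,
                        cls,
                        target,
                        ((chrom, hi, e1, strand),),
                        ((chrom, lo, e1, strand),),
                    )
                )
            elif s1 == s2 and e1 != e2:
                lo, hi = sorted((e1, e2))
                owner = a if e1 == lo else b
                ex = _exon_starting_at(owner, lo)
                if ex is None or ex.end < hi:
                    continue
                target = GenomicInterval(chrom, lo, hi, strand)
                cls = "alt3" if strand == "+" else "alt5"
                out.append(
                    SpliceEvent(
                        _event_id(cls, target),
                        a.gene_id,
                        cls,
                        target,
                        ((chrom, s1, lo, strand),),
                        ((chrom, s1, hi, strand),),
                    )
                )

    # alternative first/last exons: distinct terminal exons splicing to a
    # shared internal anchor
    fa, fb = a.exons[0], b.exons[0]
    if (
        len(a.exons) > 1
        and len(b.exons) > 1
        and (fa.start, fa.end) != (fb.start, fb.end)
        and not fa.overlaps(fb)
        and a.junctions()[0][1] == b.junctions()[0][1]
        and a.junctions()[0][0] != b.junctions()[0][0]
    ):
        anchor = a.junctions()[0][1]
        first, other = sorted((fa, fb), key=lambda e: e.start)
        cls = "alt_first" if strand == "+" else "alt_last"
        out.append(
            SpliceEvent(
                _event_id(cls, first),
                a.gene_id,
                cls,
                first,
                ((chrom, first.end, anchor, strand),),
                ((chrom, other.end, anchor, strand),),
            )
        )
    la, lb = a.exons[-1], b.exons[-1]
    if (
        len(a.exons) > 1
        and len(b.exons) > 1
        and (la.start, la.end) != (lb.start, lb.end)
        and not la.overlaps(lb)
        and a.junctions()[-1][0] == b.junctions()[-1][0]
        and a.junctions()[-1][1] != b.junctions()[-1][1]
    ):
        anchor = a.junctions()[-1][0]
        first, other = sorted((la, lb), key=lambda e: e.start)
        cls = "alt_last" if strand == "+" else "alt_first"
        out.append(
            SpliceEvent(
                _event_id(cls, first),
                a.gene_id,
                cls,
                first,
                ((chrom, anchor, first.start, strand),),
                ((chrom, anchor, other.start, strand),),
            )
        )

    # mutually exclusive: one internal exon each, same flanking anchors,
    # non-overlapping targets
    for i in range(1, len(a.exons) - 1):
        pa, xa, na = a.exons[i - 1 : i + 2]
        for j in range(1, len(b.exons) - 1):
            pb, xb, nb = b.exons[j - 1 : j + 2]
            if (
                pa.end == pb.end
                and na.start == nb.start
                and not xa.overlaps(xb)
                and (xa.start, xa.end) != (xb.start, xb.end)
                and (pa.end, na.start) not in ja | jb
            ):
                first, other = sorted((xa, xb), key=lambda e: e.start)
                out.append(
                    SpliceEvent(
                        _event_id("mutually_exclusive", first),
                        a.gene_id,
                        "mutually_exclusive",
                        first,
                        (
                            (chrom, pa.end, first.start, strand),
                            (chrom, first.end, na.start, strand),
                        ),
                        (
                            (chrom, pa.end, other.start, strand),
                            (chrom, other.end, na.start, strand),
                        ),
                    )
                )
    return out


def extract_splice_events(
    models: Sequence[TranscriptModel],
    junctions: Sequence[SpliceJunction] = (),
) -> list:
    """Emit splice events per gene from isoform comparison plus junction
    evidence (unannotated skips of constitutive exons and cryptic-exon
    candidates)."""
    by_gene: dict = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)

    # index observed junctions by chrom for gene assignment
    junc_by_chrom: dict = {}
    for j in junctions:
        junc_by_chrom.setdefault(j.intron.chrom, []).append(j)

    events: dict = {}

    def add(ev: SpliceEvent):
        events.setdefault(ev.event_id, ev)

    for gene_id, isoforms in by_gene.items():
        isoforms = sorted(isoforms, key=lambda m: m.transcript_id)
        for i in range(len(isoforms)):
            for j in range(len(isoforms)):
                if i != j:
                    for ev in _pairwise_events(isoforms[i], isoforms[j]):
                        add(ev)

        chrom, strand = isoforms[0].chrom, isoforms[0].strand
        gstart = min(m.start for m in isoforms)
        gend = max(m.end for m in isoforms)
        annotated_j = set()
        for m in isoforms:
            annotated_j.update(m.junctions())
        donors = {}  # exon end -> exon
        acceptors = {}  # exon start -> exon
        exon_ivs = []
        for m in isoforms:
            for e in m.exons:
                donors[e.end] = e
                acceptors[e.start] = e
                exon_ivs.append((e.start, e.end))
        exon_ivs = sorted(set(exon_ivs))

        def overlaps_annot_exon(s, e):
            return any(s < ee and es < e for es, ee in exon_ivs)

        obs = [
            j
            for j in junc_by_chrom.get(chrom, [])
            if gstart <= j.intron.start and j.intron.end <= gend
            and j.intron.strand in (strand, ".")
        ]
        obs_keys = {(j.intron.start, j.intron.end) for j in obs}

        # skip of annotated constitutive exon: unannotated junction whose ends
        # match an annotated donor and acceptor with exactly one annotated
        # exon in between (present in every isoform)
        for (a, d) in obs_keys - annotated_j:
            if a not in donors or d not in acceptors:
                continue
            between = [(es, ee) for es, ee in exon_ivs if a <= es and ee <= d]
            if len(between) != 1:
                continue
            es, ee = between[0]
            constitutive = all(
                any(x.start == es and x.end == ee for x in m.exons)
                for m in isoforms
            )
            if not constitutive:
                continue
            if (a, es) not in annotated_j or (ee, d) not in annotated_j:
                continue
            target = GenomicInterval(chrom, es, ee, strand)
            add(
                SpliceEvent(
                    _event_id("cassette", target),
                    gene_id,
                    "cassette",
                    target,
                    ((chrom, a, es, strand), (chrom, ee, d, strand)),
                    ((chrom, a, d, strand),),
                )
            )

        # cryptic-exon candidate: junction pair implying an exon absent from
        # every isoform, bracketed inside an annotated junction
        for (a, b) in obs_keys:
            if a not in donors:
                continue
            for (c, d) in obs_keys:
                if c <= b or d not in acceptors:
                    continue
                if (a, d) not in annotated_j:
                    continue
                if overlaps_annot_exon(b, c):
                    continue
                target = GenomicInterval(chrom, b, c, strand)
                add(
                    SpliceEvent(
                        _event_id("cassette", target),
                        gene_id,
                        "cassette",
                        target,
                        ((chrom, a, b, strand), (chrom, c, d, strand)),
                        ((chrom, a, d, strand),),
                        annotated=False,
                    )
                )
    return sorted(events.values(), key=lambda e: (e.target.chrom, e.target.start, e.event_id))


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

DEFAULT_MIN_TOTAL = 10


def compute_psi(inclusion_counts, exclusion_counts, min_total: int = DEFAULT_MIN_TOTAL):
    """PSI = mean(inclusion) / (mean(inclusion) + mean(exclusion)); None when
    the denominator is below ``min_total``."""
    inc = float(np.mean(inclusion_counts)) if len(inclusion_counts) else 0.0
    exc = float(np.mean(exclusion_counts)) if len(exclusion_counts) else 0.0
    if inc + exc < min_total:
        return None
    return inc / (inc + exc)


def intron_retention_psi(body_count: float, junction_count: float, min_total: int = 1):
    """Retention fraction body/(body+junction); body counts must already be
    length-normalized to junction-equivalent units.  None below min_total."""
    if body_count < 0 or junction_count < 0:
        raise ValueError("counts must be non-negative")
    total = body_count + junction_count
    if total < max(min_total, 1e-12):
        return None
    return body_count / total


@dataclass
class PsiTable:
    """Per-(event, sample) inclusion/total evidence and PSI estimates.

    ``inc`` and ``tot`` are (n_events, n_samples) float arrays (inclusion
    evidence and inclusion+exclusion); psi is NaN wherever tot < min_total.
    """

    events: list
    samples: list
    inc: np.ndarray
    tot: np.ndarray
    min_total: int = DEFAULT_MIN_TOTAL
    psi: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = self.inc / self.tot
        psi[self.tot < self.min_total] = np.nan
        self.psi = psi

    @property
    def event_ids(self) -> list:
        return [e.event_id for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.event_ids, columns=self.samples)


def build_psi_table(
    events: Sequence[SpliceEvent],
    junctions: Sequence[SpliceJunction],
    sheet: SampleSheet,
    min_total: int = DEFAULT_MIN_TOTAL,
    intron_body: Optional[pd.DataFrame] = None,
) -> PsiTable:
    """Assemble the PSI table from junction counts (and, for retained-intron
    events, a length-normalized intron-body count table indexed by
    ``chrom:start-end:strand``)."""
    lookup = {j.key: j for j in junctions}
    samples = sheet.sample_ids
    inc = np.zeros((len(events), len(samples)))
    tot = np.zeros_like(inc)
    for i, ev in enumerate(events):
        if ev.event_class == "retained_intron":
            key = ev.exclusion_junctions[0]
            jx = lookup.get(key)
            body_key = f"{key[0]}:{key[1]}-{key[2]}:{key[3]}"
            for k, s in enumerate(samples):
                junc = jx.count(s) if jx is not None else 0
                body = 0.0
                if intron_body is not None and body_key in intron_body.index:
                    body = float(intron_body.loc[body_key, s])
                inc[i, k] = body
                tot[i, k] = body + junc
            continue
        inc_j, exc_j = [], []
        for key in ev.inclusion_junctions:
            if key not in lookup:
                lookup[key] = SpliceJunction(GenomicInterval(*key[:3], key[3]), {})
            inc_j.append(lookup[key])
        for key in ev.exclusion_junctions:
            if key not in lookup:
                lookup[key] = SpliceJunction(GenomicInterval(*key[:3], key[3]), {})
            exc_j.append(lookup[key])
        for k, s in enumerate(samples):
            mi = float(np.mean([j.count(s) for j in inc_j])) if inc_j else 0.0
            me = float(np.mean([j.count(s) for j in exc_j])) if exc_j else 0.0
            inc[i, k] = mi
            tot[i, k] = mi + me
    return PsiTable(list(events), samples, inc, tot, min_total)


# ---------------------------------------------------------------------------
# Differential splicing
# ---------------------------------------------------------------------------

def diff_splicing(
    psi_table: PsiTable,
    sheet: SampleSheet,
    ref_condition: Optional[str] = None,
) -> pd.DataFrame:
    """Two-group differential splicing over a PsiTable.

    Returns a DataFrame with per-event mean PSI per condition, dPSI
    (mutant - reference), p, BH FDR over tested events, and signed z.
    """
    conds = sheet.conditions
    if len(conds) != 2:
        raise DataError(f"diff_splicing needs exactly 2 conditions, got {conds}")
    if ref_condition is None:
        ref_condition = "WT" if "WT" in conds else conds[0]
    mut_condition = [c for c in conds if c != ref_condition][0]

    samples = psi_table.samples
    ref_idx = np.array([i for i, s in enumerate(samples) if sheet.condition_of(s) == ref_condition])
    mut_idx = np.array([i for i, s in enumerate(samples) if sheet.condition_of(s) == mut_condition])

    inc, tot, psi = psi_table.inc, psi_table.tot, psi_table.psi
    informative = tot >= psi_table.min_total
    n_ref = informative[:, ref_idx].sum(axis=1)
    n_mut = informative[:, mut_idx].sum(axis=1)
    tested = (n_ref >= 1) & (n_mut >= 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows are untested
        psi_ref = np.nanmean(np.where(informative, psi, np.nan)[:, ref_idx], axis=1)
        psi_mut = np.nanmean(np.where(informative, psi, np.nan)[:, mut_idx], axis=1)
    dpsi = psi_mut - psi_ref

    groups = np.array([sheet.condition_of(s) for s in samples])
    rho = betabinom_rho_mom(inc[tested], tot[tested], groups, informative[tested]) if tested.any() else 1e-6

    pvals = np.full(len(psi_table.events), np.nan)
    method = np.array(["untested"] * len(psi_table.events), dtype=object)

    lrt_rows = np.where(tested & (n_ref >= 2) & (n_mut >= 2))[0]
    fisher_rows = np.where(tested & ~((n_ref >= 2) & (n_mut >= 2)))[0]

    if len(lrt_rows):
        x, n, m = inc[lrt_rows], tot[lrt_rows], informative[lrt_rows]
        _, ll0 = betabinom_profile_mu(x, n, rho, m)
        _, ll_ref = betabinom_profile_mu(x[:, ref_idx], n[:, ref_idx], rho, m[:, ref_idx])
        _, ll_mut = betabinom_profile_mu(x[:, mut_idx], n[:, mut_idx], rho, m[:, mut_idx])
        lrt = np.clip(2.0 * (ll_ref + ll_mut - ll0), 0.0, None)
        pvals[lrt_rows] = sps.chi2.sf(lrt, df=1)
        method[lrt_rows] = "betabinom_lrt"

    for i in fisher_rows:
        m = informative[i]
        a = inc[i, ref_idx][m[ref_idx]].sum()
        b = (tot[i, ref_idx] - inc[i, ref_idx])[m[ref_idx]].sum()
        c = inc[i, mut_idx][m[mut_idx]].sum()
        d = (tot[i, mut_idx] - inc[i, mut_idx])[m[mut_idx]].sum()
        table = np.round([[a, b], [c, d]]).astype(int)
        pvals[i] = sps.fisher_exact(table, alternative="two-sided")[1]
        method[i] = "fisher"

    fdr = bh_adjust(pvals)
    z = signed_z(np.where(np.isnan(dpsi), 0.0, dpsi), pvals)

    evs = psi_table.events
    return pd.DataFrame(
        {
            "event_id": [e.event_id for e in evs],
            "gene_id": [e.gene_id for e in evs],
            "event_class": [e.event_class for e in evs],
            "chrom": [e.target.chrom for e in evs],
            "start": [e.target.start for e in evs],
            "end": [e.target.end for e in evs],
            "strand": [e.target.strand for e in evs],
            "annotated": [e.annotated for e in evs],
            "psi_ref": psi_ref,
            "psi_mut": psi_mut,
            "dpsi": dpsi,
            "p": pvals,
            "fdr": fdr,
            "z": z,
            "n_informative_ref": n_ref,
            "n_informative_mut": n_mut,
            "tested": tested,
            "method": method,
        }
    ).set_index("event_id", drop=False)


def event_class_breakdown(results: pd.DataFrame, fdr_cut: float = 0.01) -> dict:
    """Among FDR-significant events: fraction per event class, and the
    fraction of significant cassettes with dPSI < 0 (skipping)."""
    sig = results[results["fdr"] < fdr_cut]
    if len(sig) == 0:
        warnings.warn("no significant events; empty breakdown")
        return {"class_fractions": {}, "cassette_skipping_fraction": np.nan, "n_significant": 0}
    fractions = (sig["event_class"].value_counts() / len(sig)).to_dict()
    cassettes = sig[sig["event_class"] == "cassette"]
    skip_frac = float((cassettes["dpsi"] < 0).mean()) if len(cassettes) else np.nan
    return {
        "class_fractions": fractions,
        "cassette_skipping_fraction": skip_frac,
        "n_significant": int(len(sig)),
    }
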