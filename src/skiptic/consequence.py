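"""Coding consequence of exon skips and per-exon conservation.

Skipping an internal coding exon removes its CDS overlap from the mature
transcript.  The call is made by rebuilding the post-skip transcript and
scanning codons: a skip whose removed CDS length is not a multiple of 3
shifts the reading frame; a stop codon appearing upstream of where the
original stop maps in the new CDS is a premature termination codon (PTC);
a PTC located 50 nt or more upstream of the final exon-exon junction of the
post-skip transcript is predicted to trigger nonsense-mediated decay (the
canonical last-junction rule; the boundary is configurable).  A transcript
is classed damaging/unstable when the skip causes a frameshift or
introduces a PTC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import FastaReader, GenomicInterval, ScoreTrack, TranscriptModel

NMD_RULE_NT = 50

_STOPS = ("TAA", "TAG", "TGA")

STABILITY_DAMAGING = "damaging_unstable"
STABILITY_OTHER = "other"


@dataclass(frozen=True)
class ConsequenceCall:
    event_id: str
    frame_status: str  # in_frame | frameshift
    ptc_introduced: bool
    ptc_position: Optional[int]  # CDS coordinate of the PTC in the new CDS
    nmd_predicted: bool

    @property
    def stability_class(self) -> str:
        return classify_stability(self)


def classify_stability(call) -> str:
    """Damaging/unstable iff the skip shifts frame or introduces a PTC."""
    if call.frame_status == "frameshift" or call.ptc_introduced:
        return STABILITY_DAMAGING
    return STABILITY_OTHER


def _mrna_layout(model: TranscriptModel, fetch):
    """(mRNA sequence, per-exon (mrna_start, mrna_end) in transcript order,
    exons in transcript order)."""
    from .core_io import reverse_complement

    exons = list(model.exons) if model.strand == "+" else list(model.exons)[::-1]
    seqs = [fetch(model.chrom, e.start, e.end) for e in exons]
    if model.strand == "-":
        seqs = [reverse_complement(s) for s in seqs]
    spans = []
    off = 0
    for s in seqs:
        spans.append((off, off + len(s)))
        off += len(s)
    return "".join(seqs), spans, exons


def splice_consequence(
    model: TranscriptModel,
    skipped_exon: GenomicInterval,
    genome: FastaReader,
    event_id: str = "",
    nmd_rule_nt: int = NMD_RULE_NT,
) -> ConsequenceCall:
    """Predict frame / PTC / NMD status of skipping one exon of a transcript.

    A skip removing part of the CDS shifts frame iff the removed CDS length
    is not a multiple of 3; losing the start codon is classed as frameshift
    (the annotated ORF cannot be made).  Exons entirely in the UTR return an
    in-frame, PTC-free call.
    """
    idx = next(
        (
            i
            for i, e in enumerate(model.exons)
            if e.start == skipped_exon.start and e.end == skipped_exon.end
        ),
        None,
    )
    if idx is None:
        raise ValueError("skipped_exon is not an exon of the transcript")
    if model.cds is None:
        return ConsequenceCall(event_id, "in_frame", False, None, False)
    cs, ce = model.cds
    cds_overlap = max(0, min(skipped_exon.end, ce) - max(skipped_exon.start, cs))
    if cds_overlap == 0:
        return ConsequenceCall(event_id, "in_frame", False, None, False)

    fetch = genome.fetch
    mrna, spans, tx_exons = _mrna_layout(model, fetch)

    def _mpos(gpos: int) -> int:
        # genomic base -> mRNA coordinate
        for (ms, me), e in zip(spans, tx_exons):
            if e.start <= gpos < e.end:
                off = (gpos - e.start) if model.strand == "+" else (e.end - 1 - gpos)
                return ms + off
        raise ValueError(f"position {gpos} not exonic")

    if model.strand == "+":
        cds_m0 = _mpos(cs)
        cds_m1 = _mpos(ce - 1) + 1
    else:
        cds_m0 = _mpos(ce - 1)
        cds_m1 = _mpos(cs) + 1
    tx_idx = tx_exons.index(model.exons[idx])
    sk_s, sk_e = spans[tx_idx]

    if sk_s <= cds_m0 < sk_e:
        # start codon removed: the annotated ORF is lost
        return ConsequenceCall(event_id, "frameshift", False, None, False)

    frameshift = cds_overlap % 3 != 0

    new_mrna = mrna[:sk_s] + mrna[sk_e:]
    new_spans = [
        (s - (sk_e - sk_s) if s >= sk_e else s, e - (sk_e - sk_s) if e > sk_s else e)
        for i, (s, e) in enumerate(spans)
        if i != tx_idx
    ]
    new_cds_start = cds_m0  # upstream of the skipped exon by construction
    # where the original stop codon's last base maps in the new transcript
    orig_end_new = cds_m1 - min(max(0, cds_m1 - sk_s), sk_e - sk_s)

    cds_seq = new_mrna[new_cds_start:]
    stop_at = None
    for i in range(0, len(cds_seq) - 2, 3):
        if cds_seq[i : i + 3] in _STOPS:
            stop_at = i
            break
    expected_rel = orig_end_new - new_cds_start - 3  # codon start of original stop
    ptc = stop_at is not None and stop_at < expected_rel
    ptc_position = stop_at if ptc else None

    nmd = False
    if ptc:
        # last exon-exon junction position in the new transcript
        if len(new_spans) >= 2:
            last_junction = new_spans[-2][1]
            ptc_end_mrna = new_cds_start + stop_at + 3
            nmd = (last_junction - ptc_end_mrna) >= nmd_rule_nt
    return ConsequenceCall(
        event_id,
        "frameshift" if frameshift else "in_frame",
        bool(ptc),
        ptc_position,
        bool(nmd),
    )


def consequence_table(calls) -> pd.DataFrame:
    rows = [
        {
            "event_id": c.event_id,
            "frame_status": c.frame_status,
            "ptc_introduced": c.ptc_introduced,
            "ptc_position": c.ptc_position if c.ptc_position is not None else "",
            "nmd_predicted": c.nmd_predicted,
            "stability_class": c.stability_class,
        }
        for c in calls
    ]
    return pd.DataFrame(rows).set_index("event_id", drop=False)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonConservation:
    exon: GenomicInterval
    mean_score: float
    n_bases: int


def exon_conservation(exons, track: ScoreTrack) -> list:
    """Arithmetic mean of per-base scores over each exon; exons with no
    scored base are excluded with a warning."""
    out = []
    dropped = 0
    for e in exons:
        mean, n = track.mean_scored(e.chrom, e.start, e.end)
        if n == 0:
            dropped += 1
            continue
        out.append(ExonConservation(e, float(mean), n))
    if dropped:
        warnings.warn(f"{dropped} exons had no scored base; excluded")
    return out


def conservation_mannwhitney(exons_a, exons_b, track: ScoreTrack) -> tuple:
    """(median_a, median_b, two-sided Mann-Whitney U p) for two exon sets."""
    a = np.array([c.mean_score for c in exon_conservation(exons_a, track)])
    b = np.array([c.mean_score for c in exon_conservation(exons_b, track)])
    p = float(sps.mannwhitneyu(a, b, alternative="two-sided")[1])
    return float(np.median(a)), float(np.median(b)), p
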