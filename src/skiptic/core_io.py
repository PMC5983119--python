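"""Genomic data model and readers/writers for the formats the pipeline touches.

All internal coordinates are 0-based, half-open intervals; conversion to and
from 1-based inclusive coordinates happens only at the GTF / SJ.out.tab
boundary.  Junction quantification uses the unique-mapper count column only.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

_RC = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class ParseError(ValueError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class TranscriptModel:
    """A transcript as an ordered exon chain with an optional CDS span.

    ``cds`` is the genomic (start, end) span from the first base of the start
    codon to the last base of the stop codon, 0-based half-open; it must lie
    within the exon union.
    """

    transcript_id: str
    gene_id: str
    exons: tuple
    cds: Optional[tuple] = None

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        chrom, strand = exons[0].chrom, exons[0].strand
        for e in exons:
            if e.chrom != chrom or e.strand != strand:
                raise ValueError(
                    f"{self.transcript_id}: exons span multiple chroms/strands"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)
        if self.cds is not None:
            cs, ce = self.cds
            if not (exons[0].start <= cs < ce <= exons[-1].end):
                raise ValueError(f"{self.transcript_id}: CDS outside exon span")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def junctions(self) -> list:
        """Intron (start, end) pairs in genomic order."""
        return [(a.end, b.start) for a, b in zip(self.exons, self.exons[1:])]

    def spliced_sequence(self, fetch) -> str:
        """Concatenate exon sequences 5'->3' given a ``fetch(chrom,s,e)``."""
        seq = "".join(fetch(self.chrom, e.start, e.end) for e in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq


@dataclass(frozen=True)
class SpliceJunction:
    """An intron (first to one-past-last intronic base) with per-sample
    unique-read counts."""

    intron: GenomicInterval
    counts: Mapping[str, int] = field(default_factory=dict)

    def count(self, sample: str) -> int:
        return int(self.counts.get(sample, 0))

    @property
    def key(self):
        i = self.intron
        return (i.chrom, i.start, i.end, i.strand)


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    pos: int
    strand: str
    count: int


@dataclass
class SampleSheet:
    """Sample ids with condition labels (e.g. WT / MUT)."""

    samples: list  # list of (sample_id, condition)

    def __post_init__(self):
        ids = [s for s, _ in self.samples]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate sample ids in sample sheet")
        by_cond = {}
        for s, c in self.samples:
            by_cond.setdefault(c, []).append(s)
        if any(len(v) < 1 for v in by_cond.values()) or not by_cond:
            raise ConfigurationError("each condition needs >= 1 sample")
        self._by_cond = by_cond

    @property
    def sample_ids(self) -> list:
        return [s for s, _ in self.samples]

    @property
    def conditions(self) -> list:
        return list(self._by_cond)

    def condition_samples(self, condition: str) -> list:
        return list(self._by_cond[condition])

    def condition_of(self, sample: str) -> str:
        for s, c in self.samples:
            if s == sample:
                return c
        raise KeyError(sample)

    def relabelled(self, assignment: Mapping[str, str]) -> "SampleSheet":
        return SampleSheet([(s, assignment[s]) for s, _ in self.samples])

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        samples = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if lineno == 1 and parts[0].lower() in ("sample", "sample_id"):
                    continue
                if len(parts) < 2:
                    raise ParseError(path, lineno, "need sample<TAB>condition")
                samples.append((parts[0], parts[1]))
        return cls(samples)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\tcondition\n")
            for s, c in self.samples:
                fh.write(f"{s}\t{c}\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _parse_attributes(field8: str) -> dict:
    attrs = {}
    for part in field8.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def read_gtf(path) -> list:
    """Read exon/CDS features from a GTF into TranscriptModel objects.

    GTF is 1-based inclusive; internal coordinates are 0-based half-open.
    Transcripts are grouped by gene and returned sorted by
    (chrom, start, transcript_id).
    """
    exons: dict = {}
    cds: dict = {}
    meta: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("exon", "CDS"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(path, lineno, "non-integer coordinates") from None
            if end1 < start1:
                raise ParseError(path, lineno, f"end < start ({end1} < {start1})")
            if strand not in STRANDS:
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            if "transcript_id" not in attrs or "gene_id" not in attrs:
                raise ParseError(path, lineno, "missing gene_id/transcript_id")
            tid = attrs["transcript_id"]
            meta[tid] = (attrs["gene_id"], chrom, strand)
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "exon":
                exons.setdefault(tid, []).append(iv)
            else:
                cds.setdefault(tid, []).append(iv)
    models = []
    for tid, ex in exons.items():
        gene_id, _chrom, _strand = meta[tid]
        cspan = None
        if tid in cds:
            cspan = (min(c.start for c in cds[tid]), max(c.end for c in cds[tid]))
        models.append(TranscriptModel(tid, gene_id, tuple(ex), cspan))
    models.sort(key=lambda m: (m.chrom, m.start, m.transcript_id))
    return models


def write_gtf(models: Sequence[TranscriptModel], path) -> None:
    """Emit 1-based inclusive GTF with exon and CDS features, deterministic
    (chrom, start, transcript_id) ordering."""
    models = sorted(models, key=lambda m: (m.chrom, m.start, m.transcript_id))
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\tskiptic\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
                if m.cds is not None:
                    cs, ce = m.cds
                    os_, oe = max(e.start, cs), min(e.end, ce)
                    if os_ < oe:
                        fh.write(
                            f"{m.chrom}\tskiptic\tCDS\t{os_ + 1}\t{oe}\t.\t"
                            f"{m.strand}\t.\t{attrs}\n"
                        )


# ---------------------------------------------------------------------------
# STAR SJ.out.tab junction counts
# ---------------------------------------------------------------------------

_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}


def read_junction_counts(paths: Mapping[str, object], sheet: SampleSheet) -> list:
    """Merge per-sample STAR SJ.out.tab files into SpliceJunction objects.

    ``paths`` maps sample id -> file path.  Columns: chrom, 1-based intron
    start, 1-based intron end, strand code (0/1/2), motif, annotated flag,
    unique count, multimap count.  Only the unique-read count is used.
    """
    for sample in sheet.sample_ids:
        if sample not in paths:
            raise ConfigurationError(f"sample {sample!r} in sheet has no junction file")
    merged: dict = {}
    for sample in sheet.sample_ids:
        path = paths[sample]
        seen = set()
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                f = line.split("\t")
                if len(f) < 7:
                    raise ParseError(path, lineno, f"expected >=7 columns, got {len(f)}")
                try:
                    start1, end1 = int(f[1]), int(f[2])
                    unique = int(f[6])
                except ValueError:
                    raise ParseError(path, lineno, "non-integer field") from None
                if f[3] not in _SJ_STRAND:
                    raise ParseError(path, lineno, f"bad strand code {f[3]!r}")
                key = (f[0], start1 - 1, end1, _SJ_STRAND[f[3]])
                if key in seen:
                    raise ParseError(path, lineno, f"duplicate junction {key}")
                seen.add(key)
                if unique < 0:
                    raise ParseError(path, lineno, "negative count")
                merged.setdefault(key, {})[sample] = unique
    out = []
    for (chrom, s, e, strand), counts in sorted(merged.items()):
        out.append(SpliceJunction(GenomicInterval(chrom, s, e, strand), counts))
    return out


def write_junction_counts(junctions: Iterable[SpliceJunction], sample: str, path) -> None:
    """Write one sample's counts in the SJ.out.tab dialect."""
    code = {".": "0", "+": "1", "-": "2"}
    rows = sorted(junctions, key=lambda j: j.key)
    with open(path, "w") as fh:
        for j in rows:
            i = j.intron
            fh.write(
                f"{i.chrom}\t{i.start + 1}\t{i.end}\t{code[i.strand]}\t0\t0\t"
                f"{j.count(sample)}\t0\n"
            )


# ---------------------------------------------------------------------------
# Crosslink BED
# ---------------------------------------------------------------------------

def read_crosslinks(path) -> list:
    """Read single-nucleotide crosslink sites from BED (>=5 columns; score =
    crosslink count).  Any record wider than 1 nt is a dialect error."""
    sites = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(path, lineno, "need >=5 BED columns")
            start, end = int(f[1]), int(f[2])
            if end - start != 1:
                raise ParseError(
                    path, lineno, f"crosslink sites must be 1 nt wide, got {end - start}"
                )
            strand = f[5] if len(f) > 5 else "."
            if strand not in STRANDS:
                raise ParseError(path, lineno, f"bad strand {strand!r}")
            sites.append(CrosslinkSite(f[0], start, strand, int(float(f[4]))))
    return sites


def write_crosslinks(sites: Iterable[CrosslinkSite], path) -> None:
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos, x.strand)):
            fh.write(f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tx\t{s.count}\t{s.strand}\n")


# ---------------------------------------------------------------------------
# bedGraph conservation track
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Per-base score track from non-overlapping bedGraph records; bases not
    covered by any record score 0 (and count as unscored for means)."""

    def __init__(self, records):
        self._chrom = {}
        by_chrom: dict = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        for chrom, recs in by_chrom.items():
            recs.sort()
            starts = np.array([r[0] for r in recs])
            ends = np.array([r[1] for r in recs])
            vals = np.array([r[2] for r in recs], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise DataError(f"overlapping bedGraph records on {chrom}")
            self._chrom[chrom] = (starts, ends, vals)

    def value(self, chrom: str, pos: int) -> float:
        if chrom not in self._chrom:
            return 0.0
        starts, ends, vals = self._chrom[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < ends[i]:
            return float(vals[i])
        return 0.0

    def mean_scored(self, chrom: str, start: int, end: int):
        """(mean, n_scored) over scored bases in [start, end); mean is None
        when no base is scored."""
        if chrom not in self._chrom:
            return None, 0
        starts, ends, vals = self._chrom[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total, n = 0.0, 0
        for i in range(lo, hi):
            ov = min(end, ends[i]) - max(start, starts[i])
            if ov > 0:
                total += vals[i] * ov
                n += ov
        if n == 0:
            return None, 0
        return total / n, int(n)


def read_bedgraph(path) -> ScoreTrack:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(path, lineno, "need 4 bedGraph columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ParseError(path, lineno, "end <= start")
            records.append((f[0], start, end, float(f[3])))
    return ScoreTrack(records)


def write_bedgraph(records, path) -> None:
    """records: iterable of (chrom, start, end, value)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.4g}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class FastaReader:
    """Strand-aware FASTA access, backed by pyfaidx or an in-memory dict."""

    def __init__(self, source):
        if isinstance(source, (str, os.PathLike)):
            import pyfaidx

            self._fa = pyfaidx.Fasta(str(source))
            self._mem = None
        else:
            self._fa = None
            self._mem = dict(source)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        start = max(start, 0)
        if self._mem is not None:
            seq = self._mem[chrom][start:end]
        else:
            seq = str(self._fa[chrom][start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()

    def length(self, chrom: str) -> int:
        if self._mem is not None:
            return len(self._mem[chrom])
        return len(self._fa[chrom])

    @property
    def chroms(self) -> list:
        if self._mem is not None:
            return list(self._mem)
        return list(self._fa.keys())
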