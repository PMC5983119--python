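"""Independent brute-force oracles used to cross-check the package's
statistics and the splice-and-translate consequence caller.

Everything here is deliberately written the slow, obvious way and shares no
code with the implementation under test.
"""

from __future__ import annotations

import math

GENETIC_STOPS = ("TAA", "TAG", "TGA")


def bh_oracle(pvalues):
    """Benjamini-Hochberg adjusted p-values, textbook definition."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = n - rank_from_end
        val = min(prev, pvalues[i] * n / rank)
        adjusted[i] = val
        prev = val
    return adjusted


def binomial_tail_oracle(k, n, p):
    """P(X >= k) as an explicit sum of binomial pmf terms."""
    if k <= 0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * (p ** j) * ((1 - p) ** (n - j))
    return min(total, 1.0)


def chi2_2x2_oracle(table):
    """Pearson statistic by explicit expected-count arithmetic; p for 1 df
    via the complementary error function."""
    (a, b), (c, d) = table
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    stat = 0.0
    obs = ((a, b), (c, d))
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            stat += (obs[i][j] - e) ** 2 / e
    p = math.erfc(math.sqrt(stat / 2.0))
    return stat, p


def fisher_oracle(table):
    """Two-sided Fisher exact p by enumerating the hypergeometric support
    and summing tables no more probable than the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def hyper(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = hyper(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = hyper(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def merge_clusters_oracle(sites, max_gap, min_total):
    """O(n^2) single-linkage merge of crosslink sites; returns
    (chrom, strand, start, end, total, n_sites) tuples."""
    groups = []
    for s in sites:
        groups.append({"key": (s.chrom, s.strand), "members": [s]})
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi, gj = groups[i], groups[j]
                if gi["key"] != gj["key"]:
                    continue
                close = any(
                    abs(a.pos - b.pos) <= max_gap
                    for a in gi["members"]
                    for b in gj["members"]
                )
                if close:
                    gi["members"].extend(gj["members"])
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    out = []
    for g in groups:
        members = sorted(g["members"], key=lambda s: s.pos)
        total = sum(s.count for s in members)
        if total < min_total:
            continue
        chrom, strand = g["key"]
        out.append(
            (chrom, strand, members[0].pos, members[-1].pos + 1, total, len(members))
        )
    return sorted(out)


# ---------------------------------------------------------------------------
# Splice-and-translate consequence oracle
# ---------------------------------------------------------------------------

def consequence_oracle(exon_seqs, intron_seqs, utr5_len, utr3_len, skip_index, nmd_nt=50):
    """Frame/PTC/NMD of skipping ``exon_seqs[skip_index]`` from a plus-strand
    toy transcript given directly as exon/intron sequences.

    The CDS runs from ``utr5_len`` into the mRNA to ``utr3_len`` before its
    end.  Splices both transcripts, translates codon by codon, and measures
    the last-junction distance explicitly.  Returns a dict with
    frame_status, ptc_introduced and nmd_predicted.
    """
    mrna = "".join(exon_seqs)
    cds_start = utr5_len
    cds_end = len(mrna) - utr3_len

    # exon span of each exon in the mRNA
    spans = []
    off = 0
    for s in exon_seqs:
        spans.append((off, off + len(s)))
        off += len(s)
    sk_s, sk_e = spans[skip_index]

    overlap = max(0, min(sk_e, cds_end) - max(sk_s, cds_start))
    if overlap == 0:
        return {"frame_status": "in_frame", "ptc_introduced": False, "nmd_predicted": False}
    if sk_s <= cds_start < sk_e:
        return {"frame_status": "frameshift", "ptc_introduced": False, "nmd_predicted": False}
    frame_status = "frameshift" if overlap % 3 else "in_frame"

    new_exons = [s for i, s in enumerate(exon_seqs) if i != skip_index]
    new_mrna = "".join(new_exons)

    # translate from the (unchanged) start codon
    first_stop = None
    i = cds_start
    while i + 3 <= len(new_mrna):
        if new_mrna[i : i + 3] in GENETIC_STOPS:
            first_stop = i
            break
        i += 3
    # where the original stop codon begins in the skipped mRNA
    removed_before_end = min(max(0, cds_end - sk_s), sk_e - sk_s)
    orig_stop_new = (cds_end - 3) - removed_before_end

    ptc = first_stop is not None and first_stop < orig_stop_new
    nmd = False
    if ptc and len(new_exons) >= 2:
        last_junction = sum(len(s) for s in new_exons[:-1])
        stop_end = first_stop + 3
        nmd = (last_junction - stop_end) >= nmd_nt
    return {
        "frame_status": frame_status,
        "ptc_introduced": bool(ptc),
        "nmd_predicted": bool(nmd),
    }
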