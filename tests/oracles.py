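"""Independent quadratic/brute-force oracles for the interval algebra.

Deliberately naive reimplementations used only to cross-check the package;
they share no code with primkit.intervals / primkit.enhancers.
"""

from primkit.intervals import GenomicInterval


def brute_extend(intervals, flank, layout=None):
    out = []
    for iv in intervals:
        start = iv.start - flank
        if start < 0:
            start = 0
        end = iv.end + flank
        if layout is not None and iv.chrom in layout and end > layout[iv.chrom]:
            end = layout[iv.chrom]
        out.append(GenomicInterval(iv.chrom, start, end, iv.strand, iv.score))
    return sorted(out, key=lambda i: (i.chrom, i.start, i.end))


def brute_merge(intervals, gap=0):
    """Repeated pairwise merging until a fixed point."""
    spans = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(spans)):
            for j in range(i + 1, len(spans)):
                ci, si, ei = spans[i]
                cj, sj, ej = spans[j]
                if ci != cj:
                    continue
                sep = max(si, sj) - min(ei, ej)
                if sep <= gap:
                    spans[i] = (ci, min(si, sj), max(ei, ej))
                    spans.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(GenomicInterval(c, s, e) for c, s, e in spans)


def brute_overlap_query(intervals_a, intervals_b):
    out = []
    for a in intervals_a:
        hits = [
            b
            for b in intervals_b
            if b.chrom == a.chrom and a.start < b.end and b.start < a.end
        ]
        out.append(sorted(hits, key=lambda i: (i.chrom, i.start, i.end)))
    return out


def brute_call_enhancers(k27ac, k4me3, annotation, k4_extension, merge_gap):
    """Per-cell-type filter + merge, then pooled merge — all quadratic scans.

    Returns the sorted (chrom, start, end) tuples of the catalog.
    """
    exclusion_extra = []
    for tx in annotation:
        exclusion_extra.append((tx.chrom, tx.tx_start, tx.tx_end))
        exclusion_extra.append((tx.chrom, tx.tx_end, tx.tx_end + 1))
    pooled = []
    for ct, peaks in k27ac.items():
        zones = [
            (iv.chrom, max(0, iv.start - k4_extension), iv.end + k4_extension)
            for iv in k4me3[ct]
        ] + exclusion_extra
        survivors = []
        for iv in peaks:
            hit = any(
                iv.chrom == c and iv.start < e and s < iv.end for c, s, e in zones
            )
            if not hit:
                survivors.append(iv)
        pooled.extend(brute_merge(survivors, merge_gap))
    return [
        (iv.chrom, iv.start, iv.end) for iv in brute_merge(pooled, merge_gap)
    ]


def brute_fisher_greater(a_up, a_down, b_up, b_down):
    """One-sided hypergeometric tail by direct enumeration."""
    from math import comb

    row_a = a_up + a_down
    total_up = a_up + b_up
    n = row_a + b_up + b_down
    denom = comb(n, row_a)
    p = 0.0
    for x in range(a_up, min(row_a, total_up) + 1):
        if row_a - x <= n - total_up:
            p += comb(total_up, x) * comb(n - total_up, row_a - x) / denom
    return p
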