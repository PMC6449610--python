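"""Independent brute-force oracles used to cross-check the interval
primitives.  Deliberately naive (O(n^2)) and structurally unrelated to
the sweep-based implementations they verify."""

from __future__ import annotations

from histofold import GenomicInterval


def brute_merge(
    intervals: list[GenomicInterval], max_gap: int
) -> list[tuple[str, int, int]]:
    """Transitive-closure merge: repeatedly fuse any two intervals on the
    same chromosome whose gap is <= max_gap, until a fixed point."""
    items = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        out: list[tuple[str, int, int]] = []
        for item in items:
            for i, other in enumerate(out):
                if item[0] == other[0] and (
                    item[1] - other[2] <= max_gap and other[1] - item[2] <= max_gap
                ):
                    out[i] = (
                        other[0],
                        min(other[1], item[1]),
                        max(other[2], item[2]),
                    )
                    changed = True
                    break
            else:
                out.append(item)
        items = out
    return sorted(items)


def brute_count(
    regions: list[GenomicInterval], fragments: list[GenomicInterval]
) -> list[int]:
    """All-pairs >= 1 bp overlap count."""
    counts = []
    for r in regions:
        n = 0
        for f in fragments:
            if f.chrom == r.chrom and f.start < r.end and r.start < f.end:
                n += 1
        counts.append(n)
    return counts


def brute_nearest_tss(region, genes):
    """Min over all same-chromosome TSSs with the orientation sign rule."""
    mid = (region.start + region.end) // 2
    best = None
    for g in sorted(genes, key=lambda g: g.gene_id):
        if g.chrom != region.chrom:
            continue
        tss = g.interval.start if g.strand == "+" else g.interval.end - 1
        dist = abs(mid - tss)
        if best is None or dist < best[0]:
            signed = (mid - tss) if g.strand == "+" else (tss - mid)
            best = (dist, g.gene_id, signed)
    if best is None:
        return None, None
    return best[1], best[2]
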