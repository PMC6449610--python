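"""Differential histone-modification regions between two conditions.

The procedure: pool the peak calls of both conditions for one mark,
merge peaks within a gap tolerance (default 1 kb) into a common region
set, quantify each region in each condition as input-subtracted RPKM
(IP RPKM minus INPUT RPKM, floored at 0), and call regions whose signal
changes more than ``fold_threshold``-fold (default 2, strict) between
the conditions "increased" or "decreased".  A pseudocount (default 1 on
the RPKM scale) keeps the fold change defined when a signal is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_io import FragmentSet, GenomicInterval
from .interval_core import MergedRegion, count_overlapping, merge_with_gap

INCREASED = "increased"
DECREASED = "decreased"
UNCHANGED = "unchanged"
CHANGE_CLASSES = (INCREASED, DECREASED, UNCHANGED)


@dataclass
class RegionSignal:
    """A merged region with per-condition quantification and change call.

    ``conditions`` orders the two condition labels; the fold change is
    condition2 over condition1 on the pseudocounted signal scale.
    """

    region: GenomicInterval
    mark: str
    conditions: tuple[str, str]
    ip_count: dict[str, int]
    input_count: dict[str, int]
    ip_rpkm: dict[str, float]
    input_rpkm: dict[str, float]
    signal: dict[str, float]
    fold_change: float
    change_class: str
    n_sources: int = 1


def rpkm(count: int, region_length: int, library_size: int) -> float:
    """Reads per kilobase of region per million mapped reads."""
    if region_length <= 0:
        raise ValueError(f"region_length must be > 0, got {region_length}")
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return count * 1e9 / (region_length * library_size)


def region_signal(ip_rpkm: float, input_rpkm: float) -> float:
    """Input-subtracted signal: max(IP RPKM - INPUT RPKM, 0)."""
    return max(ip_rpkm - input_rpkm, 0.0)


def classify_change(
    signal_c1: float,
    signal_c2: float,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> tuple[float, str]:
    """Classify a region's change from condition 1 to condition 2.

    ``fold = (signal_c2 + pseudocount) / (signal_c1 + pseudocount)``;
    "more than fold_threshold-fold" is strict, so exactly 2-fold is
    unchanged.  Returns ``(fold_change, change_class)``.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if signal_c1 < 0 or signal_c2 < 0:
        raise ValueError("signals must be >= 0")
    fold = (signal_c2 + pseudocount) / (signal_c1 + pseudocount)
    if fold > fold_threshold:
        return fold, INCREASED
    if fold < 1.0 / fold_threshold:
        return fold, DECREASED
    return fold, UNCHANGED


def _pool(fragment_sets: FragmentSet | Sequence[FragmentSet]) -> FragmentSet:
    """Concatenate replicate libraries: fragments and library sizes sum."""
    if isinstance(fragment_sets, FragmentSet):
        return fragment_sets
    if not fragment_sets:
        raise ValueError("no fragment sets given")
    first = fragment_sets[0]
    fragments: list[GenomicInterval] = []
    for fs in fragment_sets:
        if fs.role != first.role:
            raise ValueError("cannot pool IP with INPUT libraries")
        fragments.extend(fs.fragments)
    return FragmentSet(
        library_id="+".join(fs.library_id for fs in fragment_sets),
        role=first.role,
        mark=first.mark,
        condition=first.condition,
        fragments=fragments,
    )


def call_differential_regions(
    peaks_c1: Sequence[GenomicInterval],
    peaks_c2: Sequence[GenomicInterval],
    ip_c1: FragmentSet | Sequence[FragmentSet],
    input_c1: FragmentSet | Sequence[FragmentSet],
    ip_c2: FragmentSet | Sequence[FragmentSet],
    input_c2: FragmentSet | Sequence[FragmentSet],
    mark: str = "",
    conditions: tuple[str, str] = ("c1", "c2"),
    max_gap: int = 1000,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> list[RegionSignal]:
    """Run the full differential-region procedure for one mark.

    Peaks from both conditions are pooled and merged with ``max_gap`` so
    both conditions are quantified on one shared region set.  Replicate
    fragment libraries passed as sequences are concatenated before
    counting.  Every merged region receives a change class; the
    increased/decreased/unchanged sets partition the regions.
    """
    merged: list[MergedRegion] = merge_with_gap(
        list(peaks_c1) + list(peaks_c2), max_gap=max_gap
    )
    if not merged:
        return []
    ip1, in1 = _pool(ip_c1), _pool(input_c1)
    ip2, in2 = _pool(ip_c2), _pool(input_c2)
    for fs in (ip1, in1, ip2, in2):
        if fs.total_mapped == 0:
            raise ValueError(f"empty fragment library {fs.library_id!r}")
    region_ivs = [m.interval for m in merged]
    counts = {
        (conditions[0], "IP"): count_overlapping(region_ivs, ip1),
        (conditions[0], "INPUT"): count_overlapping(region_ivs, in1),
        (conditions[1], "IP"): count_overlapping(region_ivs, ip2),
        (conditions[1], "INPUT"): count_overlapping(region_ivs, in2),
    }
    libsize = {
        (conditions[0], "IP"): ip1.total_mapped,
        (conditions[0], "INPUT"): in1.total_mapped,
        (conditions[1], "IP"): ip2.total_mapped,
        (conditions[1], "INPUT"): in2.total_mapped,
    }

    out: list[RegionSignal] = []
    for i, m in enumerate(merged):
        length = m.interval.length
        ip_count, input_count, ip_r, input_r, sig = {}, {}, {}, {}, {}
        for cond in conditions:
            c_ip = int(counts[(cond, "IP")][i])
            c_in = int(counts[(cond, "INPUT")][i])
            ip_count[cond] = c_ip
            input_count[cond] = c_in
            ip_r[cond] = rpkm(c_ip, length, libsize[(cond, "IP")])
            input_r[cond] = rpkm(c_in, length, libsize[(cond, "INPUT")])
            sig[cond] = region_signal(ip_r[cond], input_r[cond])
        fold, change = classify_change(
            sig[conditions[0]],
            sig[conditions[1]],
            fold_threshold=fold_threshold,
            pseudocount=pseudocount,
        )
        out.append(
            RegionSignal(
                region=m.interval,
                mark=mark,
                conditions=conditions,
                ip_count=ip_count,
                input_count=input_count,
                ip_rpkm=ip_r,
                input_rpkm=input_r,
                signal=sig,
                fold_change=fold,
                change_class=change,
                n_sources=m.n_sources,
            )
        )
    return out


def class_counts(regions: Sequence[RegionSignal]) -> dict[str, int]:
    """Count regions per change class (all three keys always present)."""
    counts = {cls: 0 for cls in CHANGE_CLASSES}
    for r in regions:
        counts[r.change_class] += 1
    return counts
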