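"""Genomic-feature annotation of regions and TSS metaprofiles.

A region is assigned to exactly one of six genomic categories by the
location of its midpoint, with precedence Promoter > 5'UTR > 3'UTR >
Exon > Intron > Downstream > DistalIntergenic (the ChIPseeker-style
priority).  The promoter is the +/- 3 kb window around the TSS, reported
with distance bins (<=1 kb, 1-2 kb, 2-3 kb); Downstream is the 3 kb
window past the TTS in transcriptional orientation.  The midpoint rule
makes the categories a partition of the region set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import FragmentSet, GeneModel, GenomicInterval
from .interval_core import nearest_tss, tss_signed_distance

logger = logging.getLogger(__name__)

PROMOTER = "Promoter"
UTR5 = "5'UTR"
UTR3 = "3'UTR"
EXON = "Exon"
INTRON = "Intron"
DOWNSTREAM = "Downstream"
DISTAL = "DistalIntergenic"
UTR = "UTR"  # collapsed class used in the six-way report

TOP_LEVELS = (PROMOTER, UTR5, UTR3, EXON, INTRON, DOWNSTREAM, DISTAL)
SIX_WAY = (PROMOTER, UTR, EXON, INTRON, DOWNSTREAM, DISTAL)
PROMOTER_BINS = ("<=1kb", "1-2kb", "2-3kb")


@dataclass(frozen=True)
class FeatureCategory:
    top_level: str
    promoter_bin: str = "n/a"

    def __post_init__(self) -> None:
        if self.top_level not in TOP_LEVELS:
            raise ValueError(f"unknown category {self.top_level!r}")
        if (self.promoter_bin != "n/a") != (self.top_level == PROMOTER):
            raise ValueError("promoter_bin is set iff top_level is Promoter")

    @property
    def six_way(self) -> str:
        return UTR if self.top_level in (UTR5, UTR3) else self.top_level


@dataclass
class AnnotatedRegion:
    region: GenomicInterval
    category: FeatureCategory
    gene_id: Optional[str]
    tss_distance: Optional[int]


def _promoter_bin(abs_dist: int) -> str:
    if abs_dist <= 1000:
        return "<=1kb"
    if abs_dist <= 2000:
        return "1-2kb"
    return "2-3kb"


def annotate_region(
    region: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 3000,
    downstream_len: int = 3000,
) -> AnnotatedRegion:
    """Assign a region's midpoint to one genomic category.

    Within a category, competing genes resolve to the one with the
    smallest |midpoint - TSS|, then lexicographically smaller gene_id.
    On a chromosome without genes the region is DistalIntergenic and no
    nearest gene is reported (distance to a TSS on another chromosome is
    undefined).
    """
    if not genes:
        raise ValueError("gene collection is empty")
    mid = region.midpoint
    same_chrom = [g for g in genes if g.chrom == region.chrom]

    def pick(candidates: list[GeneModel]) -> GeneModel:
        return min(candidates, key=lambda g: (abs(mid - g.tss), g.gene_id))

    # Promoter: strand-aware +/- halfwidth window around the TSS
    promoter_genes = [g for g in same_chrom if abs(mid - g.tss) <= promoter_halfwidth]
    if promoter_genes:
        g = pick(promoter_genes)
        return AnnotatedRegion(
            region=region,
            category=FeatureCategory(PROMOTER, _promoter_bin(abs(mid - g.tss))),
            gene_id=g.gene_id,
            tss_distance=tss_signed_distance(mid, g),
        )

    def hit(top_level: str, candidates: list[GeneModel]) -> AnnotatedRegion:
        g = pick(candidates)
        return AnnotatedRegion(
            region=region,
            category=FeatureCategory(top_level),
            gene_id=g.gene_id,
            tss_distance=tss_signed_distance(mid, g),
        )

    in_utr5 = [g for g in same_chrom if any(u.start <= mid < u.end for u in g.utr5)]
    if in_utr5:
        return hit(UTR5, in_utr5)
    in_utr3 = [g for g in same_chrom if any(u.start <= mid < u.end for u in g.utr3)]
    if in_utr3:
        return hit(UTR3, in_utr3)
    in_exon = [g for g in same_chrom if any(e.start <= mid < e.end for e in g.exons)]
    if in_exon:
        return hit(EXON, in_exon)
    in_body = [
        g for g in same_chrom if g.interval.start <= mid < g.interval.end
    ]
    if in_body:
        return hit(INTRON, in_body)

    def downstream_window(g: GeneModel) -> tuple[int, int]:
        if g.strand == "+":
            return g.interval.end, g.interval.end + downstream_len
        return max(g.interval.start - downstream_len, 0), g.interval.start

    in_down = [
        g for g in same_chrom if downstream_window(g)[0] <= mid < downstream_window(g)[1]
    ]
    if in_down:
        return hit(DOWNSTREAM, in_down)

    gene_id, dist = nearest_tss(region, genes) if same_chrom else (None, None)
    return AnnotatedRegion(
        region=region,
        category=FeatureCategory(DISTAL),
        gene_id=gene_id,
        tss_distance=dist,
    )


def annotate_regions(
    regions: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = 3000,
    downstream_len: int = 3000,
) -> list[AnnotatedRegion]:
    return [
        annotate_region(r, genes, promoter_halfwidth, downstream_len) for r in regions
    ]


def category_distribution(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    """Tabulate counts and percentages per category, promoter bins broken out.

    Rows: the three promoter distance bins, then 5'UTR, 3'UTR, Exon,
    Intron, Downstream, DistalIntergenic.  Percentages are of the total
    region count and sum to 100.
    """
    if not annotated:
        raise ValueError("no annotated regions")
    labels = [f"{PROMOTER} ({b})" for b in PROMOTER_BINS] + [
        UTR5, UTR3, EXON, INTRON, DOWNSTREAM, DISTAL
    ]
    counts = {lab: 0 for lab in labels}
    for a in annotated:
        if a.category.top_level == PROMOTER:
            counts[f"{PROMOTER} ({a.category.promoter_bin})"] += 1
        else:
            counts[a.category.top_level] += 1
    total = len(annotated)
    df = pd.DataFrame(
        {
            "category": labels,
            "count": [counts[lab] for lab in labels],
        }
    )
    df["percentage"] = 100.0 * df["count"] / total
    return df


def six_way_distribution(annotated: Sequence[AnnotatedRegion]) -> pd.DataFrame:
    """Collapse promoter bins and the two UTR classes into the six-way report."""
    if not annotated:
        raise ValueError("no annotated regions")
    counts = {lab: 0 for lab in SIX_WAY}
    for a in annotated:
        counts[a.category.six_way] += 1
    total = len(annotated)
    df = pd.DataFrame({"category": list(SIX_WAY), "count": [counts[c] for c in SIX_WAY]})
    df["percentage"] = 100.0 * df["count"] / total
    return df


# ---------------------------------------------------------------------------
# TSS metaprofiles


@dataclass
class TssProfile:
    """Mean per-bin RPKM around TSSs, stratified by expression level.

    Bins are strand-oriented: bin 0 is the far upstream edge, the last
    bin the far downstream edge, each ``bin_bp`` wide.  ``offsets`` holds
    the oriented bin start offsets relative to the TSS.
    """

    window_bp: int
    bin_bp: int
    offsets: np.ndarray
    strata: dict[str, np.ndarray] = field(default_factory=dict)
    n_genes: dict[str, int] = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return 2 * self.window_bp // self.bin_bp

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {"offset": self.offsets}
        for name, values in self.strata.items():
            data[name] = values
        return pd.DataFrame(data)


def tss_profile(
    fragments: FragmentSet,
    genes: Sequence[GeneModel],
    expression: Mapping[str, float],
    expr_threshold: float = 10.0,
    window: int = 5000,
    bin: int = 100,
) -> TssProfile:
    """Binned fragment RPKM around TSSs, split into high/low expression.

    Every profiled gene must have an expression value; genes with value
    > ``expr_threshold`` form the "high" stratum, the rest "low".  Per
    gene, fragments overlapping each strand-oriented bin are counted and
    converted to RPKM with the bin length and the library size; the
    profile rows are stratum means.  An empty stratum is omitted with a
    warning.
    """
    if window % bin != 0:
        raise ValueError("window must be a multiple of bin")
    missing = [g.gene_id for g in genes if g.gene_id not in expression]
    if missing:
        raise ValueError(
            f"{len(missing)} profiled genes lack expression values "
            f"(first: {missing[0]!r})"
        )
    n_bins = 2 * window // bin
    offsets = np.arange(-window, window, bin)

    starts_by_chrom: dict[str, np.ndarray] = {}
    ends_by_chrom: dict[str, np.ndarray] = {}
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for f in fragments.fragments:
        by_chrom.setdefault(f.chrom, []).append((f.start, f.end))
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        starts_by_chrom[chrom] = np.sort(arr[:, 0])
        ends_by_chrom[chrom] = np.sort(arr[:, 1])
    libsize = fragments.total_mapped
    if libsize == 0:
        raise ValueError("empty fragment library")

    def gene_counts(g: GeneModel) -> np.ndarray:
        starts = starts_by_chrom.get(g.chrom)
        if starts is None:
            return np.zeros(n_bins, dtype=np.int64)
        ends = ends_by_chrom[g.chrom]
        # genomic bin bounds for each oriented bin
        lo_off = offsets
        hi_off = offsets + bin
        if g.strand == "+":
            g_lo = g.tss + lo_off
            g_hi = g.tss + hi_off
        else:
            # oriented offset o maps to genomic position tss - o
            g_lo = g.tss - hi_off + 1
            g_hi = g.tss - lo_off + 1
        n_before_end = np.searchsorted(starts, g_hi, side="left")
        n_at_or_before_start = np.searchsorted(ends, g_lo, side="right")
        return n_before_end - n_at_or_before_start

    strata_members: dict[str, list[GeneModel]] = {"high": [], "low": []}
    for g in genes:
        stratum = "high" if expression[g.gene_id] > expr_threshold else "low"
        strata_members[stratum].append(g)

    profile = TssProfile(window_bp=window, bin_bp=bin, offsets=offsets)
    scale = 1e9 / (bin * libsize)
    for name in ("high", "low"):
        members = strata_members[name]
        if not members:
            logger.warning("no genes in expression stratum %r; omitted", name)
            continue
        total = np.zeros(n_bins, dtype=np.float64)
        for g in members:
            total += gene_counts(g)
        profile.strata[name] = total / len(members) * scale
        profile.n_genes[name] = len(members)
    return profile
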