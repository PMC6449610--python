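"""Integration of differential modification regions with differential
expression: four-group gene classification and the expression-shift test.

Up-regulated genes are grouped by whether their nearest-TSS-assigned
regions include an increase of H3K4me3, of H3K27ac, of both or of
neither; down-regulated genes use decreased regions.  A second, stricter
"proximal" flag requires the assigned region to sit within 1 kb of the
TSS, the focus of the promoter-centric analysis.  The association
between a promoter H3K4me3 gain and an expression rise across
conditions is tested with a paired two-sided Wilcoxon signed-rank test
on per-gene condition means (a paired t-test is available as an
alternative).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff_regions import DECREASED, INCREASED, RegionSignal
from .genome_io import GeneModel
from .interval_core import nearest_tss

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NS = "ns"

GROUPS = ("neither", "mark1_only", "mark2_only", "both")


@dataclass
class DEGene:
    gene_id: str
    log2fc: float
    padj: Optional[float]
    direction: str


@dataclass
class MarkFlags:
    """Per-gene differential-region flags for one histone mark."""

    increased: bool = False
    decreased: bool = False
    proximal_increased: bool = False
    proximal_decreased: bool = False


@dataclass
class GeneGroupAssignment:
    gene_id: str
    direction: str  # up or down
    group: str  # one of GROUPS


def filter_de(
    table: pd.DataFrame, alpha: float = 0.01
) -> tuple[set[str], set[str], list[DEGene]]:
    """Split a DE results table into up/down/ns at adjusted p < alpha.

    ``table`` needs columns gene_id, log2fc, padj.  A gene is up iff
    padj < alpha and log2fc > 0, down iff padj < alpha and log2fc < 0;
    zero fold change or missing padj is ns.  padj outside [0, 1] raises.
    Returns (up set, down set, all DEGene records).
    """
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    bad = table["padj"].dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj values outside [0, 1]")

    up: set[str] = set()
    down: set[str] = set()
    genes: list[DEGene] = []
    for row in table.itertuples(index=False):
        padj = None if pd.isna(row.padj) else float(row.padj)
        direction = NS
        if padj is not None and padj < alpha:
            if row.log2fc > 0:
                direction = UP
                up.add(row.gene_id)
            elif row.log2fc < 0:
                direction = DOWN
                down.add(row.gene_id)
        genes.append(
            DEGene(
                gene_id=row.gene_id,
                log2fc=float(row.log2fc),
                padj=padj,
                direction=direction,
            )
        )
    return up, down, genes


def assign_regions_to_genes(
    regions_by_mark: Mapping[str, Sequence[RegionSignal]],
    genes: Sequence[GeneModel],
    proximal_bp: int = 1000,
) -> dict[str, dict[str, MarkFlags]]:
    """Set per-gene increased/decreased flags from nearest-TSS assignment.

    Each classified region is assigned to the single gene whose TSS is
    nearest its midpoint (ties: lexicographically smaller gene_id); the
    gene's flag for that mark and class is set.  The proximal flag
    additionally requires |midpoint - TSS| <= ``proximal_bp``.  Regions
    on chromosomes without genes are dropped.  Returns
    ``flags[gene_id][mark]``.
    """
    flags: dict[str, dict[str, MarkFlags]] = {
        g.gene_id: {mark: MarkFlags() for mark in regions_by_mark} for g in genes
    }
    for mark, regions in regions_by_mark.items():
        for r in regions:
            if r.change_class not in (INCREASED, DECREASED):
                continue
            gene_id, dist = nearest_tss(r.region, genes)
            if gene_id is None:
                continue
            f = flags[gene_id][mark]
            proximal = abs(dist) <= proximal_bp
            if r.change_class == INCREASED:
                f.increased = True
                f.proximal_increased = f.proximal_increased or proximal
            else:
                f.decreased = True
                f.proximal_decreased = f.proximal_decreased or proximal
    return flags


def group_genes(
    up: set[str],
    down: set[str],
    flags: Mapping[str, Mapping[str, MarkFlags]],
    mark1: str = "H3K4me3",
    mark2: str = "H3K27ac",
    proximal: bool = False,
) -> tuple[list[GeneGroupAssignment], pd.DataFrame]:
    """Four-group classification of up and down genes by mark status.

    Up genes are grouped by increased-region flags, down genes by
    decreased-region flags; with ``proximal=True`` the <= 1 kb proximal
    flags are used instead.  Returns the per-gene assignments and a 2x4
    count table (rows up/down, columns neither/mark1_only/mark2_only/
    both) whose rows sum to the direction's gene count.
    """
    overlap = up & down
    if overlap:
        raise ValueError(f"genes in both up and down sets: {sorted(overlap)[:5]}")

    def flag_of(gene_id: str, mark: str, direction: str) -> bool:
        mf = flags.get(gene_id, {}).get(mark)
        if mf is None:
            return False
        if direction == UP:
            return mf.proximal_increased if proximal else mf.increased
        return mf.proximal_decreased if proximal else mf.decreased

    assignments: list[GeneGroupAssignment] = []
    counts = {d: {g: 0 for g in GROUPS} for d in (UP, DOWN)}
    for direction, gene_set in ((UP, up), (DOWN, down)):
        for gene_id in sorted(gene_set):
            m1 = flag_of(gene_id, mark1, direction)
            m2 = flag_of(gene_id, mark2, direction)
            group = (
                "both" if m1 and m2
                else "mark1_only" if m1
                else "mark2_only" if m2
                else "neither"
            )
            counts[direction][group] += 1
            assignments.append(GeneGroupAssignment(gene_id, direction, group))
    table = pd.DataFrame(
        [[counts[d][g] for g in GROUPS] for d in (UP, DOWN)],
        index=pd.Index([UP, DOWN], name="direction"),
        columns=list(GROUPS),
    )
    return assignments, table


@dataclass
class ShiftTestResult:
    statistic: float
    pvalue: float
    mean_c1: float
    mean_c2: float
    n_genes: int
    test: str = "wilcoxon"


def expression_shift_test(
    gene_ids: Sequence[str],
    expr: pd.DataFrame,
    condition_of_sample: Mapping[str, str],
    conditions: tuple[str, str],
    test: str = "wilcoxon",
) -> ShiftTestResult:
    """Paired test of per-gene expression means between the two conditions.

    ``expr`` is genes x samples (normalized values); each gene's samples
    are averaged within each condition and the paired differences
    (condition2 - condition1) are tested with a two-sided Wilcoxon
    signed-rank test (or paired t-test with ``test="ttest"``).  Requires
    >= 2 genes.  If all paired differences are zero the p-value is 1 by
    convention, with a warning.
    """
    if len(gene_ids) < 2:
        raise ValueError("expression_shift_test requires >= 2 genes")
    missing = [g for g in gene_ids if g not in expr.index]
    if missing:
        raise ValueError(f"genes missing from expression table: {missing[:5]}")
    samples_c1 = [s for s in expr.columns if condition_of_sample.get(s) == conditions[0]]
    samples_c2 = [s for s in expr.columns if condition_of_sample.get(s) == conditions[1]]
    if not samples_c1 or not samples_c2:
        raise ValueError("each condition needs >= 1 sample")
    sub = expr.loc[list(gene_ids)]
    means_c1 = sub[samples_c1].mean(axis=1).to_numpy()
    means_c2 = sub[samples_c2].mean(axis=1).to_numpy()
    diffs = means_c2 - means_c1
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1 by convention")
        return ShiftTestResult(0.0, 1.0, float(means_c1.mean()),
                               float(means_c2.mean()), len(gene_ids), test)
    if test == "wilcoxon":
        res = stats.wilcoxon(diffs, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_rel(means_c2, means_c1)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ShiftTestResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        mean_c1=float(means_c1.mean()),
        mean_c2=float(means_c2.mean()),
        n_genes=len(gene_ids),
        test=test,
    )


def normalize_expression_standin(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios normalization followed by log2(x + 1).

    A documented stand-in for a regularized-log transform: per-sample
    size factor = median over genes of count / geometric mean across
    samples (genes with any zero count are excluded from the median);
    normalized value = log2(count / size_factor + 1).
    """
    mat = counts.to_numpy(dtype=np.float64)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    all_positive = (mat > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene with all-positive counts for size factors")
    log_geo = np.log(mat[all_positive]).mean(axis=1)
    ratios = np.log(mat[all_positive]) - log_geo[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    return pd.DataFrame(
        np.log2(mat / size_factors[None, :] + 1.0),
        index=counts.index,
        columns=counts.columns,
    )
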