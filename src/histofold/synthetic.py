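"""Synthetic two-condition ChIP-seq + RNA-seq data with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
a small multi-chromosome genome with strand-assigned gene models; per
mark, a set of candidate regions whose IP fragment counts follow
Poisson(background x length x fold) with condition-specific enrichment
folds (INPUT follows the background rate everywhere); peak calls over
enriched regions with bounded positional jitter; an RNA count matrix
from a negative-binomial model; and a DE table with known up/down truth.
Crucially, a configurable fraction of truly up-regulated genes receive a
promoter-proximal (<= 1 kb of the TSS) region of the first mark with a
condition-2 enrichment fold >= 4 — the coupling between a promoter
H3K4me3 gain and transcriptional up-regulation that the integration
stage is designed to detect.

Truth bookkeeping: "unchanged" candidate regions carry an equal
enrichment fold in both conditions, so they are peak-covered and
quantified like differential regions — false-positive rates are
measurable rather than vacuous.  Non-coupled regions are placed at
least 3.5 kb from every TSS so promoter-proximal signal is attributable
to coupling alone, and same-mark regions keep >= 1.5 kb edge separation
so peak jitter can never close a merging gap between distinct truth
regions.
"""

from __future__ import annotations

import dataclasses
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    GeneModel,
    GenomicInterval,
    write_bed,
    write_gene_models_gtf,
)
from .integration import normalize_expression_standin


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed gives byte-identical output."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length_bp: int = 3_000_000
    n_genes: int = 150
    gene_length_min: int = 2_000
    gene_length_max: int = 8_000
    gene_spacing_min: int = 8_000
    gene_spacing_max: int = 20_000
    fraction_de_up: float = 0.15
    fraction_de_down: float = 0.15
    marks: tuple[str, ...] = ("H3K4me3", "H3K27ac")
    conditions: tuple[str, str] = ("GD50", "GD95")
    n_enriched_regions: int = 120  # per mark, excluding coupled regions
    region_length_min: int = 800
    region_length_max: int = 1_500
    frac_increased: float = 0.4
    frac_decreased: float = 0.2
    fold_differential: tuple[float, float] = (4.0, 8.0)
    fold_shared: tuple[float, float] = (2.0, 6.0)
    background_rate: float = 0.02  # fragments per bp per library
    fragment_length_bp: int = 200
    peak_jitter_bp: int = 200
    coupling_prob: float = 0.8
    tss_exclusion_bp: int = 3_500
    region_min_gap_bp: int = 1_500
    n_samples_c1: int = 6
    n_samples_c2: int = 4
    nb_dispersion: float = 0.05
    alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in ("fraction_de_up", "fraction_de_down", "coupling_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fraction_de_up + self.fraction_de_down > 1.0:
            raise ValueError("DE fractions sum to more than 1")
        if self.frac_increased + self.frac_decreased > 1.0:
            raise ValueError("region class fractions sum to more than 1")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions required")
        # YAML round-trips tuples as lists
        self.marks = tuple(self.marks)
        self.conditions = tuple(self.conditions)
        self.fold_differential = tuple(self.fold_differential)
        self.fold_shared = tuple(self.fold_shared)


@dataclass
class TruthRegion:
    region_id: str
    interval: GenomicInterval
    mark: str
    fold: dict[str, float]
    true_class: str  # increased / decreased / unchanged
    coupled_gene: Optional[str] = None


@dataclass
class GroundTruth:
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand, direction, coupled
    regions: pd.DataFrame  # region_id, chrom, start, end, mark, fold per cond, class


@dataclass
class SimulationResult:
    config: SimulationConfig
    outdir: Path
    gtf: Path
    peaks: dict[tuple[str, str], Path]  # (mark, condition) -> BED
    fragments: dict[tuple[str, str, str], Path]  # (mark, condition, role) -> BED
    counts_tsv: Path
    de_tsv: Path
    expr_tsv: Path
    truth_tsv: Path
    gene_models: list[GeneModel] = field(default_factory=list)
    truth: Optional[GroundTruth] = None


def _place_genes(cfg: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes: list[GeneModel] = []
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    n_placed = 0
    for chrom in chroms:
        pos = int(rng.integers(cfg.gene_spacing_min, cfg.gene_spacing_max + 1))
        while n_placed < cfg.n_genes:
            length = int(
                rng.integers(cfg.gene_length_min, cfg.gene_length_max + 1)
            )
            if pos + length + cfg.gene_spacing_min > cfg.chrom_length_bp:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            n_placed += 1
            gene_id = f"g{n_placed:05d}"
            body = GenomicInterval(chrom, pos, pos + length, strand)
            # three exons with ~equal spacing; UTRs at the oriented ends
            third = length // 3
            exon_len = max(third // 2, 150)
            exons = [
                GenomicInterval(chrom, pos, pos + exon_len, strand),
                GenomicInterval(chrom, pos + third, pos + third + exon_len, strand),
                GenomicInterval(chrom, pos + length - exon_len, pos + length, strand),
            ]
            utr_len = min(100, exon_len)
            if strand == "+":
                utr5 = [GenomicInterval(chrom, pos, pos + utr_len, strand)]
                utr3 = [GenomicInterval(chrom, pos + length - utr_len, pos + length, strand)]
            else:
                utr5 = [GenomicInterval(chrom, pos + length - utr_len, pos + length, strand)]
                utr3 = [GenomicInterval(chrom, pos, pos + utr_len, strand)]
            genes.append(GeneModel(gene_id, body, exons, utr5, utr3))
            pos += length + int(
                rng.integers(cfg.gene_spacing_min, cfg.gene_spacing_max + 1)
            )
        if n_placed >= cfg.n_genes:
            break
    if n_placed < cfg.n_genes:
        raise ValueError(
            f"genome too small: placed {n_placed} of {cfg.n_genes} genes"
        )
    return genes


class _Blocked:
    """Per-chromosome sorted blocked intervals for rejection placement."""

    def __init__(self) -> None:
        self._by_chrom: dict[str, list[tuple[int, int]]] = {}

    def add(self, chrom: str, start: int, end: int) -> None:
        insort(self._by_chrom.setdefault(chrom, []), (start, end))

    def clashes(self, chrom: str, start: int, end: int) -> bool:
        blocks = self._by_chrom.get(chrom, [])
        i = bisect_left(blocks, (start, start))
        # neighbor on each side suffices: blocks are kept non-nested enough
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(blocks):
                bs, be = blocks[j]
                if bs < end and start < be:
                    return True
        return False


def _draw_region_class(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[str, dict[str, float]]:
    u = rng.random()
    c1, c2 = cfg.conditions
    lo, hi = cfg.fold_differential
    if u < cfg.frac_increased:
        return "increased", {c1: 1.0, c2: float(rng.uniform(lo, hi))}
    if u < cfg.frac_increased + cfg.frac_decreased:
        return "decreased", {c1: float(rng.uniform(lo, hi)), c2: 1.0}
    f = float(rng.uniform(*cfg.fold_shared))
    return "unchanged", {c1: f, c2: f}


def _place_regions(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    genes: list[GeneModel],
    up_genes: list[GeneModel],
) -> list[TruthRegion]:
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    regions: list[TruthRegion] = []
    region_n = 0
    c1, c2 = cfg.conditions
    lo, hi = cfg.fold_differential

    for mark_idx, mark in enumerate(cfg.marks):
        blocked = _Blocked()
        for g in genes:
            blocked.add(
                g.chrom,
                max(g.tss - cfg.tss_exclusion_bp, 0),
                g.tss + cfg.tss_exclusion_bp,
            )
        # coupled promoter regions: first mark only, truly-up genes
        if mark_idx == 0:
            for g in up_genes:
                if rng.random() >= cfg.coupling_prob:
                    continue
                length = int(
                    rng.integers(cfg.region_length_min, cfg.region_length_max + 1)
                )
                center = g.tss + int(rng.integers(-600, 601))
                start = max(center - length // 2, 0)
                region_n += 1
                regions.append(
                    TruthRegion(
                        region_id=f"r{region_n:05d}",
                        interval=GenomicInterval(g.chrom, start, start + length),
                        mark=mark,
                        fold={c1: 1.0, c2: float(rng.uniform(max(lo, 4.0), hi))},
                        true_class="increased",
                        coupled_gene=g.gene_id,
                    )
                )
                blocked.add(
                    g.chrom,
                    max(start - cfg.region_min_gap_bp, 0),
                    start + length + cfg.region_min_gap_bp,
                )
        # background regions, away from all promoters
        placed = 0
        attempts = 0
        max_attempts = 400 * max(cfg.n_enriched_regions, 1)
        while placed < cfg.n_enriched_regions:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {cfg.n_enriched_regions} regions for "
                    f"{mark}; genome too crowded"
                )
            chrom = chroms[int(rng.integers(0, cfg.n_chroms))]
            length = int(
                rng.integers(cfg.region_length_min, cfg.region_length_max + 1)
            )
            start = int(rng.integers(0, cfg.chrom_length_bp - length))
            if blocked.clashes(chrom, start - cfg.region_min_gap_bp, start + length + cfg.region_min_gap_bp):
                continue
            true_class, folds = _draw_region_class(cfg, rng)
            region_n += 1
            regions.append(
                TruthRegion(
                    region_id=f"r{region_n:05d}",
                    interval=GenomicInterval(chrom, start, start + length),
                    mark=mark,
                    fold=folds,
                    true_class=true_class,
                )
            )
            blocked.add(
                chrom,
                max(start - cfg.region_min_gap_bp, 0),
                start + length + cfg.region_min_gap_bp,
            )
            placed += 1
    return regions


def _make_fragments(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    mark_regions: list[TruthRegion],
    condition: str,
    role: str,
) -> np.ndarray:
    """Fragment (chrom_index, start) pairs for one library, sorted."""
    frag = cfg.fragment_length_bp
    rows: list[np.ndarray] = []
    for ci in range(cfg.n_chroms):
        span = cfg.chrom_length_bp - frag
        n_bg = int(rng.poisson(cfg.background_rate * cfg.chrom_length_bp))
        if n_bg:
            starts = rng.integers(0, span, size=n_bg)
            rows.append(np.column_stack([np.full(n_bg, ci), starts]))
    if role == "IP":
        for r in mark_regions:
            fold = r.fold[condition]
            if fold <= 1.0:
                continue
            lam = cfg.background_rate * r.interval.length * (fold - 1.0)
            n_extra = int(rng.poisson(lam))
            if not n_extra:
                continue
            ci = int(r.interval.chrom[3:]) - 1
            lo = max(r.interval.start - frag // 2, 0)
            hi = max(r.interval.end - frag // 2, lo + 1)
            starts = rng.integers(lo, hi, size=n_extra)
            rows.append(np.column_stack([np.full(n_extra, ci), starts]))
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    arr = np.concatenate(rows).astype(np.int64)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    return arr[order]


def _write_fragment_bed(arr: np.ndarray, frag_len: int, path: Path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        lines = [
            f"chr{ci + 1}\t{start}\t{start + frag_len}\n" for ci, start in arr
        ]
        fh.writelines(lines)


def simulate(cfg: SimulationConfig, outdir: str | Path) -> SimulationResult:
    """Generate all pipeline inputs under ``outdir`` and return their paths.

    Emits genes.gtf, per mark x condition peak BEDs, per mark x condition
    IP and INPUT fragment BEDs, counts.tsv, de.tsv, expr.tsv and
    truth.tsv.  Library sizes equal fragment BED line counts; every file
    row traces back to a truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    c1, c2 = cfg.conditions

    genes = _place_genes(cfg, rng)

    # DE truth
    n = len(genes)
    n_up = int(round(cfg.fraction_de_up * n))
    n_down = int(round(cfg.fraction_de_down * n))
    perm = rng.permutation(n)
    direction = np.full(n, "ns", dtype=object)
    direction[perm[:n_up]] = "up"
    direction[perm[n_up:n_up + n_down]] = "down"
    up_genes = [g for g, d in zip(genes, direction) if d == "up"]

    regions = _place_regions(cfg, rng, genes, up_genes)
    coupled_ids = {r.coupled_gene for r in regions if r.coupled_gene}

    gtf = outdir / "genes.gtf"
    write_gene_models_gtf(genes, gtf)

    # peaks: jittered copies of regions enriched in each condition
    peak_paths: dict[tuple[str, str], Path] = {}
    for mark in cfg.marks:
        mark_regions = [r for r in regions if r.mark == mark]
        for cond in cfg.conditions:
            peaks = []
            for r in mark_regions:
                if r.fold[cond] <= 1.0:
                    continue
                j = cfg.peak_jitter_bp
                start = max(r.interval.start + int(rng.integers(-j, j + 1)), 0)
                end = r.interval.end + int(rng.integers(-j, j + 1))
                if end < start + 50:
                    end = start + 50
                peaks.append(
                    GenomicInterval(
                        r.interval.chrom, start, end, name=f"{r.region_id}_{cond}"
                    )
                )
            peaks.sort(key=lambda p: (p.chrom, p.start))
            path = outdir / f"peaks_{mark}_{cond}.bed"
            write_bed(peaks, path)
            peak_paths[(mark, cond)] = path

    # fragment libraries
    frag_paths: dict[tuple[str, str, str], Path] = {}
    for mark in cfg.marks:
        mark_regions = [r for r in regions if r.mark == mark]
        for cond in cfg.conditions:
            for role in ("IP", "INPUT"):
                arr = _make_fragments(cfg, rng, mark_regions, cond, role)
                path = outdir / f"frags_{mark}_{cond}_{role}.bed"
                _write_fragment_bed(arr, cfg.fragment_length_bp, path)
                frag_paths[(mark, cond, role)] = path

    # RNA counts: negative binomial (gamma-Poisson) around per-gene means
    samples = [f"{c1}_{i + 1}" for i in range(cfg.n_samples_c1)] + [
        f"{c2}_{i + 1}" for i in range(cfg.n_samples_c2)
    ]
    sample_cond = [c1] * cfg.n_samples_c1 + [c2] * cfg.n_samples_c2
    high = rng.random(n) < 0.5
    base_mean = np.where(
        high, 2.0 ** rng.uniform(10, 13, size=n), 2.0 ** rng.uniform(4, 7, size=n)
    )
    true_l2fc = np.zeros(n)
    de_mask = direction != "ns"
    signs = np.where(direction == "up", 1.0, -1.0)
    true_l2fc[de_mask] = signs[de_mask] * rng.uniform(1, 3, size=int(de_mask.sum()))
    mean_c2_arr = base_mean * 2.0 ** true_l2fc

    count_mat = np.zeros((n, len(samples)), dtype=np.int64)
    inv_disp = 1.0 / cfg.nb_dispersion
    for j, cond in enumerate(sample_cond):
        mu = base_mean if cond == c1 else mean_c2_arr
        lam = rng.gamma(shape=inv_disp, scale=mu * cfg.nb_dispersion)
        count_mat[:, j] = rng.poisson(lam)
    gene_ids = [g.gene_id for g in genes]
    counts_df = pd.DataFrame(count_mat, index=pd.Index(gene_ids, name="gene_id"),
                             columns=samples)
    counts_tsv = outdir / "counts.tsv"
    counts_df.to_csv(counts_tsv, sep="\t")
    expr_df = normalize_expression_standin(counts_df)
    expr_tsv = outdir / "expr.tsv"
    expr_df.round(6).to_csv(expr_tsv, sep="\t")

    # DE table: padj drawn below alpha for DE genes, above for the rest
    padj = np.where(
        de_mask,
        rng.uniform(1e-8, cfg.alpha * 0.5, size=n),
        rng.uniform(cfg.alpha * 5, 1.0, size=n),
    )
    reported_l2fc = np.where(de_mask, true_l2fc, rng.normal(0, 0.2, size=n))
    de_df = pd.DataFrame(
        {"gene_id": gene_ids, "log2fc": np.round(reported_l2fc, 6),
         "padj": padj}
    )
    de_tsv = outdir / "de.tsv"
    de_df.to_csv(de_tsv, sep="\t", index=False)

    # truth
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "chrom": [g.chrom for g in genes],
            "start": [g.interval.start for g in genes],
            "end": [g.interval.end for g in genes],
            "strand": [g.strand for g in genes],
            "direction": direction,
            "coupled": [int(g.gene_id in coupled_ids) for g in genes],
        }
    )
    truth_regions = pd.DataFrame(
        {
            "region_id": [r.region_id for r in regions],
            "chrom": [r.interval.chrom for r in regions],
            "start": [r.interval.start for r in regions],
            "end": [r.interval.end for r in regions],
            "mark": [r.mark for r in regions],
            f"fold_{c1}": [r.fold[c1] for r in regions],
            f"fold_{c2}": [r.fold[c2] for r in regions],
            "true_class": [r.true_class for r in regions],
            "coupled_gene": [r.coupled_gene or "" for r in regions],
        }
    )
    truth_tsv = outdir / "truth.tsv"
    with open(truth_tsv, "wt", encoding="utf-8", newline="\n") as fh:
        gt = truth_genes.copy()
        gt.insert(0, "kind", "gene")
        rt = truth_regions.copy()
        rt.insert(0, "kind", "region")
        fh.write(gt.to_csv(sep="\t", index=False))
        fh.write(rt.to_csv(sep="\t", index=False))

    return SimulationResult(
        config=cfg,
        outdir=outdir,
        gtf=gtf,
        peaks=peak_paths,
        fragments=frag_paths,
        counts_tsv=counts_tsv,
        de_tsv=de_tsv,
        expr_tsv=expr_tsv,
        truth_tsv=truth_tsv,
        gene_models=genes,
        truth=GroundTruth(genes=truth_genes, regions=truth_regions),
    )


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a config from a YAML-style mapping, rejecting unknown keys."""
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**d)
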