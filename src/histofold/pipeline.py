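"""End-to-end orchestration: simulate -> differential regions (per mark)
-> annotation -> TSS profiles -> expression integration, with a manifest.

The report directory is the contract: per-mark differential-region
tables and class counts, category distributions (overall and per change
class), TSS profile tables per mark and condition, the 2x4 gene-group
tables (any-distance and proximal), the expression-association test
result, and a manifest recording the config, seed, input checksums and
per-stage row counts.  Identical seeds yield byte-identical reports; the
manifest deliberately records no wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .annotation import annotate_regions, category_distribution, tss_profile
from .diff_regions import (
    DECREASED,
    INCREASED,
    RegionSignal,
    call_differential_regions,
    class_counts,
)
from .genome_io import (
    read_bed,
    read_fragments,
    read_gene_models,
    write_regions_tsv,
)
from .integration import (
    assign_regions_to_genes,
    expression_shift_test,
    filter_de,
    group_genes,
)
from .synthetic import SimulationConfig, config_from_dict, simulate

logger = logging.getLogger(__name__)


def format_pct(count: float, total: float) -> str:
    """Percentage to one decimal place, half-up rounding (e.g. '93.5')."""
    if total == 0:
        raise ValueError("total is zero")
    count, total = float(count), float(total)
    count = int(count) if count.is_integer() else count
    total = int(total) if total.is_integer() else total
    pct = Decimal(count) * 100 / Decimal(total)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct_value(count: float, total: float) -> float:
    return float(format_pct(count, total))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "max_gap": 1000,
    "fold_threshold": 2.0,
    "pseudocount": 1.0,
    "alpha": 0.01,
    "expr_threshold": 10.0,
    "proximal_bp": 1000,
    "profile": {"window": 5000, "bin": 100},
    "simulate": {},
}


def _annotated_distribution_table(
    regions: list[RegionSignal], genes, promoter_halfwidth: int = 3000
) -> pd.DataFrame:
    """Fig-4/5-style table: category counts overall and per change class."""
    annotated = annotate_regions([r.region for r in regions], genes, promoter_halfwidth)
    base = category_distribution(annotated)
    out = base.rename(columns={"count": "count_all", "percentage": "pct_all"})
    for cls in (INCREASED, DECREASED):
        subset = [a for a, r in zip(annotated, regions) if r.change_class == cls]
        if subset:
            sub = category_distribution(subset)
            out[f"count_{cls}"] = sub["count"].to_numpy()
            out[f"pct_{cls}"] = sub["percentage"].to_numpy()
        else:
            out[f"count_{cls}"] = 0
            out[f"pct_{cls}"] = 0.0
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].round(4)
    return out


def run_all(config: Mapping[str, Any], outdir: str | Path) -> Path:
    """Run the full pipeline into ``outdir``; returns the report directory.

    ``config`` holds the analysis parameters (seed, max_gap,
    fold_threshold, pseudocount, alpha, expr_threshold, proximal_bp,
    profile.window/bin) and a ``simulate`` section of generator
    overrides.  Any stage failure removes partial report output and
    re-raises naming the stage.
    """
    cfg = dict(DEFAULTS)
    cfg.update(config or {})
    profile_cfg = dict(DEFAULTS["profile"])
    profile_cfg.update(cfg.get("profile") or {})
    sim_overrides = dict(cfg.get("simulate") or {})
    sim_overrides.setdefault("seed", cfg["seed"])
    sim_overrides.setdefault("alpha", cfg["alpha"])
    sim_cfg: SimulationConfig = config_from_dict(sim_overrides)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = outdir / "report"
    stage = "setup"
    try:
        stage = "simulate"
        sim = simulate(sim_cfg, outdir / "sim")
        logger.info("simulate: %d genes, %d truth regions",
                    len(sim.truth.genes), len(sim.truth.regions))

        report.mkdir(exist_ok=True)
        row_counts: dict[str, int] = {
            "genes": len(sim.truth.genes),
            "truth_regions": len(sim.truth.regions),
        }
        genes = sim.gene_models
        c1, c2 = sim_cfg.conditions

        stage = "diff_regions"
        regions_by_mark: dict[str, list[RegionSignal]] = {}
        frag_cache: dict[tuple[str, str, str], Any] = {}
        diff_rows = []
        for mark in sim_cfg.marks:
            for cond in sim_cfg.conditions:
                for role in ("IP", "INPUT"):
                    frag_cache[(mark, cond, role)] = read_fragments(
                        sim.fragments[(mark, cond, role)],
                        library_id=f"{mark}_{cond}_{role}",
                        role=role,
                        mark=mark,
                        condition=cond,
                    )
            regions = call_differential_regions(
                peaks_c1=read_bed(sim.peaks[(mark, c1)]),
                peaks_c2=read_bed(sim.peaks[(mark, c2)]),
                ip_c1=frag_cache[(mark, c1, "IP")],
                input_c1=frag_cache[(mark, c1, "INPUT")],
                ip_c2=frag_cache[(mark, c2, "IP")],
                input_c2=frag_cache[(mark, c2, "INPUT")],
                mark=mark,
                conditions=sim_cfg.conditions,
                max_gap=cfg["max_gap"],
                fold_threshold=cfg["fold_threshold"],
                pseudocount=cfg["pseudocount"],
            )
            regions_by_mark[mark] = regions
            write_regions_tsv(regions, report / f"regions_{mark}.tsv")
            counts = class_counts(regions)
            total = len(regions)
            diff_rows.append(
                {
                    "mark": mark,
                    "increased": counts[INCREASED],
                    "decreased": counts[DECREASED],
                    "unchanged": counts["unchanged"],
                    "total": total,
                    "pct_increased": format_pct(counts[INCREASED], total),
                    "pct_decreased": format_pct(counts[DECREASED], total),
                }
            )
            row_counts[f"regions_{mark}"] = total
            logger.info("diff_regions %s: %s of %d regions", mark, counts, total)
        pd.DataFrame(diff_rows).to_csv(
            report / "diff_region_counts.tsv", sep="\t", index=False
        )

        stage = "annotation"
        for mark in sim_cfg.marks:
            table = _annotated_distribution_table(regions_by_mark[mark], genes)
            table.to_csv(
                report / f"category_distribution_{mark}.tsv", sep="\t", index=False
            )

        stage = "tss_profile"
        expr = pd.read_csv(sim.expr_tsv, sep="\t", index_col="gene_id")
        expr_value = expr.mean(axis=1)
        for mark in sim_cfg.marks:
            for cond in sim_cfg.conditions:
                prof = tss_profile(
                    frag_cache[(mark, cond, "IP")],
                    genes,
                    expr_value.to_dict(),
                    expr_threshold=cfg["expr_threshold"],
                    window=profile_cfg["window"],
                    bin=profile_cfg["bin"],
                )
                prof.to_frame().round(6).to_csv(
                    report / f"tss_profile_{mark}_{cond}.tsv", sep="\t", index=False
                )

        stage = "integration"
        de_table = pd.read_csv(sim.de_tsv, sep="\t")
        up, down, _ = filter_de(de_table, alpha=cfg["alpha"])
        row_counts["de_up"] = len(up)
        row_counts["de_down"] = len(down)
        flags = assign_regions_to_genes(
            regions_by_mark, genes, proximal_bp=cfg["proximal_bp"]
        )
        mark1 = sim_cfg.marks[0]
        mark2 = sim_cfg.marks[1] if len(sim_cfg.marks) > 1 else "none"
        assignments, table = group_genes(up, down, flags, mark1=mark1, mark2=mark2)
        _, table_prox = group_genes(
            up, down, flags, mark1=mark1, mark2=mark2, proximal=True
        )
        table.to_csv(report / "group_counts.tsv", sep="\t")
        table_prox.to_csv(report / "group_counts_proximal.tsv", sep="\t")
        pd.DataFrame(
            {
                "gene_id": [a.gene_id for a in assignments],
                "direction": [a.direction for a in assignments],
                "group": [a.group for a in assignments],
            }
        ).to_csv(report / "gene_groups.tsv", sep="\t", index=False)

        focus = sorted(
            g
            for g in up
            if g in flags and flags[g][mark1].proximal_increased
        )
        sample_cond = {
            s: (c1 if s.startswith(f"{c1}_") else c2) for s in expr.columns
        }
        assoc_lines = [
            f"up-regulated genes with a proximal (<= {cfg['proximal_bp']} bp) "
            f"{mark1}-increased region: {len(focus)}"
        ]
        if len(focus) >= 2:
            res = expression_shift_test(
                focus, expr, sample_cond, conditions=sim_cfg.conditions
            )
            assoc_lines += [
                f"test: paired two-sided Wilcoxon signed-rank, n = {res.n_genes}",
                f"statistic: {res.statistic:.6g}",
                f"p-value: {res.pvalue:.6g}",
                f"mean expression {c1}: {res.mean_c1:.6f}",
                f"mean expression {c2}: {res.mean_c2:.6f}",
            ]
        else:
            assoc_lines.append("too few genes for the association test")
        (report / "association.txt").write_text(
            "\n".join(assoc_lines) + "\n", encoding="utf-8"
        )

        stage = "manifest"
        input_files = sorted(
            p for p in (outdir / "sim").iterdir() if p.is_file()
        )
        manifest = {
            "package_version": __version__,
            "seed": cfg["seed"],
            "config": {
                k: cfg[k]
                for k in (
                    "max_gap",
                    "fold_threshold",
                    "pseudocount",
                    "alpha",
                    "expr_threshold",
                    "proximal_bp",
                )
            },
            "profile": profile_cfg,
            "simulation": {
                k: v for k, v in vars(sim_cfg).items()
            },
            "input_checksums": {p.name: _sha256(p) for p in input_files},
            "row_counts": row_counts,
        }
        (report / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n",
            encoding="utf-8",
        )
    except Exception as exc:
        shutil.rmtree(report, ignore_errors=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
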