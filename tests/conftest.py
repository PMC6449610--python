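import numpy as np
import pytest

from histofold import (
    FragmentSet,
    GeneModel,
    GenomicInterval,
    SimulationConfig,
    call_differential_regions,
    read_bed,
    read_fragments,
    simulate,
)


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, utr5=None, utr3=None):
    return GeneModel(
        gene_id=gene_id,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=exons or [],
        utr5=utr5 or [],
        utr3=utr3 or [],
    )


def make_fragments(intervals, library_id="lib", role="IP", mark="H3K4me3", condition="c1"):
    return FragmentSet(
        library_id=library_id,
        role=role,
        mark=mark,
        condition=condition,
        fragments=list(intervals),
    )


@pytest.fixture
def two_genes():
    """A + gene and a - gene on chr1, far apart."""
    return [
        make_gene("gA", "chr1", 10_000, 15_000, "+"),
        make_gene("gB", "chr1", 40_000, 46_000, "-"),
    ]


RECOVERY_CONFIG = SimulationConfig(
    seed=2_024,
    marks=("H3K4me3",),
    n_genes=30,
    n_enriched_regions=500,
    fold_differential=(4.0, 8.0),
    fold_shared=(4.0, 8.0),
    coupling_prob=0.0,
)


@pytest.fixture(scope="session")
def recovery_sim(tmp_path_factory):
    """The fixed-seed 500-region simulation: true enrichment folds >= 4
    and expected per-region IP fragment counts >= 50 (rate 0.02/bp x
    >= 800 bp x fold >= 4)."""
    outdir = tmp_path_factory.mktemp("recovery")
    sim = simulate(RECOVERY_CONFIG, outdir)
    mark = "H3K4me3"
    c1, c2 = RECOVERY_CONFIG.conditions
    frags = {
        (cond, role): read_fragments(
            sim.fragments[(mark, cond, role)], f"{cond}_{role}", role
        )
        for cond in (c1, c2)
        for role in ("IP", "INPUT")
    }
    peaks = {cond: read_bed(sim.peaks[(mark, cond)]) for cond in (c1, c2)}
    regions = call_differential_regions(
        peaks_c1=peaks[c1],
        peaks_c2=peaks[c2],
        ip_c1=frags[(c1, "IP")],
        input_c1=frags[(c1, "INPUT")],
        ip_c2=frags[(c2, "IP")],
        input_c2=frags[(c2, "INPUT")],
        mark=mark,
        conditions=(c1, c2),
    )
    return {"sim": sim, "regions": regions, "peaks": peaks, "frags": frags}


def truth_vs_called(sim, regions):
    """Pair each truth region with the called region covering its midpoint."""
    by_chrom = {}
    for r in regions:
        by_chrom.setdefault(r.region.chrom, []).append(r)
    pairs = []
    for row in sim.truth.regions.itertuples():
        mid = (row.start + row.end) // 2
        hits = [
            r
            for r in by_chrom.get(row.chrom, [])
            if r.region.start <= mid < r.region.end
        ]
        pairs.append((row, hits[0] if hits else None))
    return pairs
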