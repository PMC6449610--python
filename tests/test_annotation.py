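import numpy as np
import pytest

from histofold import (
    GenomicInterval,
    annotate_region,
    annotate_regions,
    category_distribution,
    six_way_distribution,
    tss_profile,
)
from histofold.annotation import (
    DISTAL,
    DOWNSTREAM,
    EXON,
    INTRON,
    PROMOTER,
    UTR5,
    FeatureCategory,
)
from conftest import make_fragments, make_gene


class TestFeatureCategory:
    def test_promoter_requires_bin(self):
        with pytest.raises(ValueError):
            FeatureCategory(PROMOTER)  # bin n/a on a promoter

    def test_bin_forbidden_off_promoter(self):
        with pytest.raises(ValueError):
            FeatureCategory(EXON, "<=1kb")

    def test_utrs_collapse_in_six_way(self):
        assert FeatureCategory(UTR5).six_way == "UTR"
        assert FeatureCategory(INTRON).six_way == INTRON


@pytest.fixture
def gene_with_structure():
    """+ gene at [10000, 20000) with exons, UTRs and introns."""
    chrom = "chr1"
    exons = [
        GenomicInterval(chrom, 10_000, 11_000, "+"),
        GenomicInterval(chrom, 14_000, 15_000, "+"),
        GenomicInterval(chrom, 19_000, 20_000, "+"),
    ]
    return make_gene(
        "g1",
        chrom,
        10_000,
        20_000,
        "+",
        exons=exons,
        utr5=[GenomicInterval(chrom, 10_000, 10_200, "+")],
        utr3=[GenomicInterval(chrom, 19_800, 20_000, "+")],
    )


def region_at(mid, halfwidth=100, chrom="chr1"):
    return GenomicInterval(chrom, mid - halfwidth, mid + halfwidth)


class TestAnnotateRegion:
    def test_proximal_promoter_upstream(self, gene_with_structure):
        a = annotate_region(region_at(9_500), [gene_with_structure])
        assert a.category == FeatureCategory(PROMOTER, "<=1kb")
        assert a.gene_id == "g1"
        assert a.tss_distance == -500

    @pytest.mark.parametrize(
        "mid,bin_", [(9_100, "<=1kb"), (8_500, "1-2kb"), (7_500, "2-3kb")]
    )
    def test_promoter_distance_bins(self, gene_with_structure, mid, bin_):
        a = annotate_region(region_at(mid), [gene_with_structure])
        assert a.category.promoter_bin == bin_

    def test_promoter_beats_intron_of_other_gene(self, gene_with_structure):
        # midpoint 13500: inside an intron of g1 (and beyond g1's 3 kb
        # promoter window) but 1.5 kb upstream of g2's TSS
        g2 = make_gene("g2", "chr1", 15_000, 30_000, "+")
        a = annotate_region(region_at(13_500), [gene_with_structure, g2])
        assert a.category == FeatureCategory(PROMOTER, "1-2kb")
        assert a.gene_id == "g2"

    def test_utr5_beats_exon(self, gene_with_structure):
        a = annotate_region(
            region_at(10_100), [gene_with_structure], promoter_halfwidth=50
        )
        assert a.category.top_level == UTR5

    def test_exon_and_intron(self, gene_with_structure):
        # shrink promoter so mid-gene features are reachable
        ex = annotate_region(
            region_at(14_500), [gene_with_structure], promoter_halfwidth=1000
        )
        assert ex.category.top_level == EXON
        intr = annotate_region(
            region_at(13_000), [gene_with_structure], promoter_halfwidth=1000
        )
        assert intr.category.top_level == INTRON

    def test_downstream_window_plus_strand(self, gene_with_structure):
        a = annotate_region(
            region_at(21_000), [gene_with_structure], promoter_halfwidth=500
        )
        assert a.category.top_level == DOWNSTREAM

    def test_downstream_window_minus_strand(self):
        g = make_gene("gm", "chr1", 50_000, 60_000, "-")
        a = annotate_region(region_at(48_000), [g], promoter_halfwidth=500)
        assert a.category.top_level == DOWNSTREAM

    def test_distal_intergenic(self, gene_with_structure):
        a = annotate_region(region_at(500_000), [gene_with_structure])
        assert a.category.top_level == DISTAL
        assert a.gene_id == "g1"  # nearest gene still reported on-chromosome

    def test_chromosome_without_genes(self, gene_with_structure):
        a = annotate_region(region_at(5_000, chrom="chr9"), [gene_with_structure])
        assert a.category.top_level == DISTAL
        assert a.gene_id is None and a.tss_distance is None

    def test_empty_gene_collection_rejected(self):
        with pytest.raises(ValueError):
            annotate_region(region_at(100), [])

    def test_gene_order_invariance(self, gene_with_structure):
        g2 = make_gene("g2", "chr1", 15_000, 30_000, "+")
        r = region_at(12_500)
        a1 = annotate_region(r, [gene_with_structure, g2])
        a2 = annotate_region(r, [g2, gene_with_structure])
        assert (a1.category, a1.gene_id) == (a2.category, a2.gene_id)


class TestCategoryDistribution:
    def _annotated(self, gene):
        regions = [region_at(9_500), region_at(9_700), region_at(13_000),
                   region_at(500_000)]
        return annotate_regions(regions, [gene], promoter_halfwidth=1000)

    def test_percentages(self, gene_with_structure):
        df = category_distribution(self._annotated(gene_with_structure))
        by = dict(zip(df["category"], df["percentage"]))
        assert by["Promoter (<=1kb)"] == pytest.approx(50.0)
        assert by[INTRON] == pytest.approx(25.0)
        assert by[DISTAL] == pytest.approx(25.0)
        assert df["percentage"].sum() == pytest.approx(100.0, abs=0.01)
        assert df["count"].sum() == 4

    def test_single_category_is_100(self, gene_with_structure):
        annotated = annotate_regions(
            [region_at(9_500), region_at(9_600)], [gene_with_structure]
        )
        df = category_distribution(annotated)
        assert df.loc[df["category"] == "Promoter (<=1kb)", "percentage"].iloc[0] == 100

    def test_order_permutation_invariance(self, gene_with_structure):
        ann = self._annotated(gene_with_structure)
        df1 = category_distribution(ann)
        df2 = category_distribution(list(reversed(ann)))
        assert df1.equals(df2)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            category_distribution([])

    def test_six_way_counts_sum_to_total(self, gene_with_structure):
        ann = self._annotated(gene_with_structure)
        df = six_way_distribution(ann)
        assert df["count"].sum() == len(ann)


class TestTssProfile:
    def _genes(self):
        return [
            make_gene("hi1", "chr1", 100_000, 110_000, "+"),
            make_gene("hi2", "chr1", 200_000, 210_000, "-"),
            make_gene("lo1", "chr1", 300_000, 310_000, "+"),
        ]

    def test_uniform_coverage_gives_flat_profile(self):
        """Fragments tiling the genome at a fixed step put the same count
        in every bin, so all bins share one RPKM value."""
        genes = self._genes()
        frags = make_fragments(
            GenomicInterval("chr1", s, s + 100) for s in range(0, 400_000, 100)
        )
        expr = {"hi1": 12.0, "hi2": 11.0, "lo1": 2.0}
        prof = tss_profile(frags, genes, expr, window=2000, bin=100)
        for stratum in ("high", "low"):
            values = prof.strata[stratum]
            assert np.allclose(values, values[0])

    def test_promoter_enriched_fragments_peak_centrally(self):
        genes = self._genes()
        frags = []
        for g in genes[:2]:  # only the high-expression genes
            frags += [
                GenomicInterval("chr1", g.tss - 500 + i * 10, g.tss - 400 + i * 10)
                for i in range(100)
            ]
        prof = tss_profile(
            make_fragments(frags), genes, {"hi1": 12, "hi2": 11, "lo1": 2},
            window=5000, bin=100,
        )
        high = prof.strata["high"]
        n = len(high)
        assert high[n // 2 - 5:n // 2 + 5].sum() > 0.5 * high.sum()
        assert prof.strata["low"].sum() == 0

    def test_minus_strand_upstream_fragments_fall_left(self):
        g = make_gene("gm", "chr1", 100_000, 110_000, "-")  # TSS 109999
        # upstream of a - gene = larger coordinates
        frags = make_fragments(
            GenomicInterval("chr1", 109_999 + 3_000 + i * 10, 109_999 + 3_100 + i * 10)
            for i in range(20)
        )
        prof = tss_profile(frags, [g], {"gm": 20.0}, window=5000, bin=100)
        values = prof.strata["high"]
        upstream_half = values[: len(values) // 2]
        assert upstream_half.sum() == pytest.approx(values.sum())
        assert values.sum() > 0

    def test_doubling_window_preserves_central_bins(self):
        genes = self._genes()
        rng = np.random.default_rng(3)
        frags = make_fragments(
            GenomicInterval("chr1", int(s), int(s) + 150)
            for s in rng.integers(0, 400_000, size=5_000)
        )
        expr = {"hi1": 12.0, "hi2": 11.0, "lo1": 2.0}
        small = tss_profile(frags, genes, expr, window=2000, bin=100)
        big = tss_profile(frags, genes, expr, window=4000, bin=100)
        assert big.n_bins == 2 * small.n_bins
        pad = (big.n_bins - small.n_bins) // 2
        assert np.allclose(big.strata["high"][pad:-pad], small.strata["high"])

    def test_missing_expression_value_rejected(self):
        with pytest.raises(ValueError, match="expression"):
            tss_profile(make_fragments([]), self._genes(), {"hi1": 1.0})

    def test_empty_stratum_omitted_with_warning(self, caplog):
        import logging

        genes = self._genes()
        frags = make_fragments([GenomicInterval("chr1", 0, 100)])
        with caplog.at_level(logging.WARNING):
            prof = tss_profile(frags, genes, {g.gene_id: 50.0 for g in genes})
        assert "low" not in prof.strata
        assert "high" in prof.strata
        assert "low" in caplog.text
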