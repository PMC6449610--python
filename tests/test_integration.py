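import numpy as np
import pandas as pd
import pytest

from histofold import (
    GenomicInterval,
    assign_regions_to_genes,
    expression_shift_test,
    filter_de,
    group_genes,
    normalize_expression_standin,
)
from histofold.diff_regions import RegionSignal
from histofold.integration import GROUPS, MarkFlags
from conftest import make_gene


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj"])


class TestFilterDe:
    def test_up_down_ns_partition(self):
        up, down, genes = filter_de(
            de_table(
                [
                    ("a", 1.2, 0.001),
                    ("b", -0.5, 0.02),
                    ("c", 0.0, 0.0001),
                    ("d", -2.0, 0.005),
                ]
            ),
            alpha=0.01,
        )
        assert up == {"a"}
        assert down == {"d"}
        assert {g.gene_id: g.direction for g in genes} == {
            "a": "up", "b": "ns", "c": "ns", "d": "down",
        }

    def test_missing_padj_is_ns(self):
        up, down, genes = filter_de(de_table([("a", 3.0, np.nan)]))
        assert not up and not down
        assert genes[0].direction == "ns"

    def test_padj_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="padj"):
            filter_de(de_table([("a", 1.0, 1.5)]))

    def test_alpha_boundary_is_strict(self):
        up, down, _ = filter_de(de_table([("a", 1.0, 0.01)]), alpha=0.01)
        assert not up


def region(chrom, start, end, change_class, mark="H3K4me3"):
    return RegionSignal(
        region=GenomicInterval(chrom, start, end),
        mark=mark,
        conditions=("c1", "c2"),
        ip_count={}, input_count={}, ip_rpkm={}, input_rpkm={}, signal={},
        fold_change=1.0,
        change_class=change_class,
    )


class TestAssignRegionsToGenes:
    def test_proximal_increased_region_sets_both_flags(self):
        g1 = make_gene("g1", "chr1", 10_000, 20_000, "+")
        flags = assign_regions_to_genes(
            {"H3K4me3": [region("chr1", 9_400, 9_800, "increased")]}, [g1]
        )
        f = flags["g1"]["H3K4me3"]
        assert f.increased and f.proximal_increased
        assert not f.decreased

    def test_distal_region_sets_only_any_distance_flag(self):
        g1 = make_gene("g1", "chr1", 10_000, 20_000, "+")
        flags = assign_regions_to_genes(
            {"H3K4me3": [region("chr1", 4_000, 5_000, "increased")]}, [g1]
        )
        f = flags["g1"]["H3K4me3"]
        assert f.increased and not f.proximal_increased

    def test_equidistant_region_assigned_to_lexicographically_smaller(self):
        ga = make_gene("ga", "chr1", 10_000, 12_000, "+")  # TSS 10000
        gb = make_gene("gb", "chr1", 5_000, 8_001, "-")    # TSS 8000
        # midpoint 9000 is 1000 from both TSSs
        flags = assign_regions_to_genes(
            {"H3K4me3": [region("chr1", 8_900, 9_100, "increased")]}, [ga, gb]
        )
        assert flags["ga"]["H3K4me3"].increased
        assert not flags["gb"]["H3K4me3"].increased

    def test_unchanged_regions_set_nothing(self):
        g1 = make_gene("g1", "chr1", 10_000, 20_000, "+")
        flags = assign_regions_to_genes(
            {"H3K4me3": [region("chr1", 9_500, 9_900, "unchanged")]}, [g1]
        )
        f = flags["g1"]["H3K4me3"]
        assert not (f.increased or f.decreased)


class TestGroupGenes:
    def _flags(self, spec):
        """spec: gene_id -> (k4_flag, k27_flag) for the increased class."""
        out = {}
        for gid, (k4, k27) in spec.items():
            out[gid] = {
                "H3K4me3": MarkFlags(increased=k4),
                "H3K27ac": MarkFlags(increased=k27),
            }
        return out

    def test_counting_on_fixture(self):
        up = {f"u{i}" for i in range(10)}
        spec = {f"u{i}": (False, False) for i in range(10)}
        for i in range(6):
            spec[f"u{i}"] = (True, False)  # K4 only
        spec["u6"] = (True, True)  # both
        assignments, table = group_genes(up, set(), self._flags(spec))
        assert table.loc["up"].tolist() == [3, 6, 0, 1]
        assert table.loc["up"].sum() == len(up)

    def test_groups_partition_each_direction(self):
        up = {"a", "b"}
        down = {"c"}
        flags = self._flags({"a": (True, False), "b": (False, False),
                             "c": (False, False)})
        assignments, table = group_genes(up, down, flags)
        assert table.loc["up"].sum() == 2
        assert table.loc["down"].sum() == 1
        assert {a.gene_id for a in assignments} == up | down

    def test_gene_in_both_directions_rejected(self):
        with pytest.raises(ValueError):
            group_genes({"a"}, {"a"}, {})

    def test_no_de_genes_gives_zero_table(self):
        _, table = group_genes(set(), set(), {})
        assert (table.to_numpy() == 0).all()
        assert list(table.columns) == list(GROUPS)

    def test_down_genes_use_decreased_flags(self):
        flags = {
            "d1": {"H3K4me3": MarkFlags(increased=True, decreased=False),
                   "H3K27ac": MarkFlags()},
        }
        _, table = group_genes(set(), {"d1"}, flags)
        # the increased flag must not leak into the down-direction row
        assert table.loc["down", "neither"] == 1


class TestExpressionShiftTest:
    def _expr(self, n_genes, shift):
        """Condition-2 samples replicate condition 1 plus a fixed shift,
        so the per-gene paired difference is exactly ``shift``."""
        rng = np.random.default_rng(8)
        base = rng.uniform(5, 15, size=(n_genes, 3))
        samples = [f"c1_{i}" for i in range(3)] + [f"c2_{i}" for i in range(3)]
        mat = np.hstack([base, base + shift])
        return pd.DataFrame(
            mat, index=[f"g{i}" for i in range(n_genes)], columns=samples
        )

    @staticmethod
    def _conds():
        cond = {f"c1_{i}": "c1" for i in range(3)}
        cond.update({f"c2_{i}": "c2" for i in range(3)})
        return cond

    def test_identical_conditions_p_is_one(self):
        expr = self._expr(10, 0.0)
        with pytest.warns(UserWarning):
            res = expression_shift_test(
                list(expr.index), expr, self._conds(), ("c1", "c2")
            )
        assert res.pvalue == 1.0

    def test_all_positive_shifts_exact_signed_rank_p(self):
        """n = 20 all-positive, untied differences: the exact two-sided
        signed-rank p is 2 / 2^20 regardless of magnitudes."""
        rng = np.random.default_rng(8)
        base = rng.uniform(5, 15, size=(20, 3))
        shifts = 5.0 + np.arange(20) * 0.01  # positive, all distinct
        mat = np.hstack([base, base + shifts[:, None]])
        samples = [f"c1_{i}" for i in range(3)] + [f"c2_{i}" for i in range(3)]
        expr = pd.DataFrame(mat, index=[f"g{i}" for i in range(20)],
                            columns=samples)
        res = expression_shift_test(
            list(expr.index), expr, self._conds(), ("c1", "c2")
        )
        assert res.pvalue == pytest.approx(2.0 / 2**20)
        assert res.pvalue < 0.001
        assert res.mean_c2 - res.mean_c1 == pytest.approx(shifts.mean())

    def test_tied_uniform_shift_still_significant(self):
        """All differences exactly +5 (tied ranks force the normal
        approximation); significance must survive."""
        expr = self._expr(20, 5.0)
        res = expression_shift_test(
            list(expr.index), expr, self._conds(), ("c1", "c2")
        )
        assert res.pvalue < 0.001
        assert res.mean_c2 - res.mean_c1 == pytest.approx(5.0)

    def test_single_gene_rejected(self):
        expr = self._expr(1, 5.0)
        with pytest.raises(ValueError):
            expression_shift_test(["g0"], expr, self._conds(), ("c1", "c2"))

    def test_condition_swap_antisymmetry(self):
        expr = self._expr(15, 2.0)
        fwd = expression_shift_test(list(expr.index), expr, self._conds(),
                                    ("c1", "c2"))
        rev = expression_shift_test(list(expr.index), expr, self._conds(),
                                    ("c2", "c1"))
        assert rev.pvalue == pytest.approx(fwd.pvalue)
        assert rev.mean_c2 - rev.mean_c1 == pytest.approx(
            -(fwd.mean_c2 - fwd.mean_c1)
        )

    def test_paired_ttest_alternative(self):
        expr = self._expr(20, 5.0)
        res = expression_shift_test(
            list(expr.index), expr, self._conds(), ("c1", "c2"), test="ttest"
        )
        assert res.pvalue < 1e-6


class TestNormalizeExpressionStandin:
    def test_identical_columns_give_log2_count_plus_one(self):
        counts = pd.DataFrame({"s1": [4, 10, 0], "s2": [4, 10, 0]},
                              index=["g1", "g2", "g3"])
        norm = normalize_expression_standin(counts)
        assert np.allclose(norm["s1"], np.log2(np.array([4, 10, 0]) + 1))
        assert norm.loc["g3", "s1"] == 0.0

    def test_doubled_sample_normalizes_back(self):
        counts = pd.DataFrame(
            {"s1": [10, 100, 40], "s2": [20, 200, 80]}, index=["a", "b", "c"]
        )
        norm = normalize_expression_standin(counts)
        # s2's size factor is 2, so normalized values match s1 exactly
        assert np.allclose(norm["s1"], norm["s2"])

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [3, 0]})
        with pytest.raises(ValueError):
            normalize_expression_standin(counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression_standin(pd.DataFrame({"s1": [-1], "s2": [2]}))
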