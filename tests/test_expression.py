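import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam.expression import (
    DOWN,
    NS,
    UP,
    call_degs,
    classify_induction,
    cluster_patterns,
    compare_stresses,
    ddct,
    deg_gene_set,
    log2_matrix,
    qpcr_report,
    roman,
    tissue_groups,
)
from genefam.io_formats import ExpressionTable


def table(gene_ids, condition_ids, values):
    return ExpressionTable(gene_ids, condition_ids, np.array(values, dtype=float))


class TestLog2:
    @pytest.mark.parametrize("value,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_closed_forms(self, value, expected):
        t = table(["g"], ["c"], [[value]])
        assert log2_matrix(t).values[0, 0] == pytest.approx(expected)

    def test_shape_preserved(self, rng):
        t = table(["a", "b"], ["x", "y", "z"], rng.uniform(0, 50, (2, 3)))
        assert log2_matrix(t).values.shape == (2, 3)


class TestTissueGroups:
    TISSUES = ["root", "stem", "leaf", "seed", "capsule"]

    def test_all_five_common(self):
        t = table(["g"], self.TISSUES, [[5, 3, 2, 9, 1.5]])
        groups = tissue_groups(t)
        assert groups.patterns["g"] == tuple(self.TISSUES)
        assert groups.common_count == 1

    def test_single_tissue_specific(self):
        t = table(["g"], self.TISSUES, [[2, 0, 0, 0, 0]])
        groups = tissue_groups(t)
        assert groups.patterns["g"] == ("root",)

    def test_not_expressed(self):
        t = table(["g"], self.TISSUES, [[0.5, 0, 0, 0, 0]])
        groups = tissue_groups(t)
        assert groups.patterns["g"] == ()
        assert groups.group_of("g") == "NOT_EXPRESSED"

    def test_counts_equal_brute_force_tally(self, rng):
        values = rng.uniform(0, 3, (40, 5))
        t = table([f"g{i}" for i in range(40)], self.TISSUES, values)
        groups = tissue_groups(t, expressed_threshold=1.0)
        # set-comprehension oracle
        expected = {}
        for gi in range(40):
            pattern = tuple(
                self.TISSUES[ti] for ti in range(5) if values[gi, ti] > 1.0
            )
            if pattern:
                expected[pattern] = expected.get(pattern, 0) + 1
        assert groups.venn_counts == expected
        assert sum(groups.venn_counts.values()) == len(groups.expressed_genes)

    def test_partition_conservation(self, rng):
        values = rng.uniform(0, 3, (30, 5))
        t = table([f"g{i}" for i in range(30)], self.TISSUES, values)
        groups = tissue_groups(t)
        frame = groups.to_frame()
        assert len(frame) == 30
        expressed = frame[frame["group"] != "NOT_EXPRESSED"]
        assert expressed.groupby("group").size().sum() == len(groups.expressed_genes)


class TestCallDegs:
    def test_up(self):
        t = table(["g"], ["control", "t1"], [[4, 10]])
        (c,) = call_degs(t, "control")
        assert c.verdict == UP
        assert c.fold_change == pytest.approx((10 + 0.01) / (4 + 0.01))

    def test_down(self):
        t = table(["g"], ["control", "t1"], [[4, 1]])
        assert call_degs(t, "control")[0].verdict == DOWN

    def test_ns(self):
        t = table(["g"], ["control", "t1"], [[4, 6]])
        assert call_degs(t, "control")[0].verdict == NS

    def test_missing_control_rejected(self):
        t = table(["g"], ["a", "b"], [[1, 2]])
        with pytest.raises(ValueError):
            call_degs(t, "control")

    @given(
        stress=st.floats(min_value=1.0, max_value=1e4),
        control=st.floats(min_value=1.0, max_value=1e4),
        scale=st.floats(min_value=1.0, max_value=100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_above_one_rpkm(self, stress, control, scale):
        t1 = table(["g"], ["control", "t"], [[control, stress]])
        t2 = table(["g"], ["control", "t"], [[control * scale, stress * scale]])
        v1 = call_degs(t1, "control", epsilon=0.0)[0].verdict
        v2 = call_degs(t2, "control", epsilon=0.0)[0].verdict
        assert v1 == v2


class TestClusters:
    def _calls(self, trajectories):
        calls = []
        for gi, traj in enumerate(trajectories):
            for ti, verdict in enumerate(traj):
                fold = {UP: 5.0, DOWN: 0.1, NS: 1.0}[verdict]
                from genefam.expression import DEGCall

                calls.append(DEGCall(f"g{gi}", f"t{ti}", fold, verdict))
        return calls

    def test_same_trajectory_same_cluster(self):
        clusters = cluster_patterns(self._calls([(NS, UP, NS), (NS, UP, NS)]))
        assert clusters.cluster_ids[(NS, UP, NS)]
        assert len(set(clusters.sizes)) == 1

    def test_all_ns_excluded(self):
        clusters = cluster_patterns(self._calls([(NS, NS, NS), (UP, NS, NS)]))
        assert len(clusters.signatures) == 1

    def test_ordering_by_size(self):
        clusters = cluster_patterns(
            self._calls([(UP, NS, NS)] * 3 + [(NS, DOWN, NS)] * 5)
        )
        assert clusters.cluster_ids[(NS, DOWN, NS)] == "I"
        assert clusters.cluster_ids[(UP, NS, NS)] == "II"


class TestCompareStresses:
    def test_paper_arithmetic(self):
        a = {f"a{i}" for i in range(86)} | {f"c{i}" for i in range(28)}
        b = {f"b{i}" for i in range(18)} | {f"c{i}" for i in range(28)}
        venn = compare_stresses(a, b, 287)
        assert venn.union == 132
        assert venn.both == 28
        assert venn.pct_of_family == 46

    def test_disjoint_union_is_sum(self):
        venn = compare_stresses({"a"}, {"b"}, 10)
        assert venn.union == 2

    def test_family_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            compare_stresses({"a", "b"}, {"c"}, 2)

    @given(
        a=st.sets(st.integers(0, 50)),
        b=st.sets(st.integers(0, 50)),
    )
    @settings(max_examples=100, deadline=None)
    def test_venn_identity(self, a, b):
        venn = compare_stresses({str(x) for x in a}, {str(x) for x in b}, 100)
        assert venn.a_only + venn.b_only + venn.both == venn.union


class TestDdct:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "condition", "replicate", "ct"])

    def test_all_equal_fold_one(self):
        rows = [
            ("t", "stress", 1, 25.0), ("t", "control", 1, 25.0),
            ("ref", "stress", 1, 25.0), ("ref", "control", 1, 25.0),
        ]
        folds, gmean = ddct(self._table(rows), "t", "ref")
        assert folds == [1.0]
        assert gmean == 1.0

    @pytest.mark.parametrize("ddct_value,expected", [(-1, 2.0), (2, 0.25)])
    def test_closed_forms(self, ddct_value, expected):
        rows = [
            ("t", "stress", 1, 25.0 + ddct_value), ("t", "control", 1, 25.0),
            ("ref", "stress", 1, 25.0), ("ref", "control", 1, 25.0),
        ]
        _, gmean = ddct(self._table(rows), "t", "ref")
        assert gmean == pytest.approx(expected)

    def test_reference_against_itself_is_one(self):
        rows = [
            ("ref", "stress", 1, 24.0), ("ref", "control", 1, 26.0),
            ("ref", "stress", 2, 23.5), ("ref", "control", 2, 25.0),
        ]
        folds, gmean = ddct(self._table(rows), "ref", "ref")
        assert folds == [1.0, 1.0]
        assert gmean == 1.0

    def test_missing_reference_rejected(self):
        rows = [("t", "stress", 1, 25.0), ("t", "control", 1, 25.0)]
        with pytest.raises(ValueError):
            ddct(self._table(rows), "t", "ref")

    def test_geometric_mean(self):
        rows = [
            ("t", "stress", 1, 24.0), ("t", "control", 1, 25.0),
            ("t", "stress", 2, 23.0), ("t", "control", 2, 25.0),
            ("ref", "stress", 1, 25.0), ("ref", "control", 1, 25.0),
            ("ref", "stress", 2, 25.0), ("ref", "control", 2, 25.0),
        ]
        folds, gmean = ddct(self._table(rows), "t", "ref")
        assert gmean == pytest.approx(math.sqrt(folds[0] * folds[1]))


class TestClassifyInduction:
    @pytest.mark.parametrize("fold,expected", [(22, UP), (0.3, DOWN), (1.0, NS), (2.0, NS)])
    def test_rule(self, fold, expected):
        assert classify_induction(fold) == expected

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_induction(0.0)


class TestQpcrReport:
    def test_planted_folds(self):
        from genefam.synthetic_data import simulate_qpcr

        ct = simulate_qpcr(["a", "b", "c"], [22.0, 1.0, 0.2], reference_gene="ref", seed=8)
        report = qpcr_report(ct, "ref")
        verdicts = dict(zip(report["gene_id"], report["verdict"]))
        assert verdicts == {"a": UP, "b": NS, "c": DOWN}


def test_roman_numbering():
    assert [roman(i) for i in range(1, 6)] == ["I", "II", "III", "IV", "V"]
    assert roman(25) == "XXV"
    with pytest.raises(ValueError):
        roman(0)
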