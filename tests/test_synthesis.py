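from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ahp_needs.judgments import JudgmentError, JudgmentMatrix
from ahp_needs.synthesis import (
    consolidate_judgments,
    fit_panel,
    propagate_global_weights,
    rank_needs,
    subgroup_median_weights,
)


def _m(entries, items=("x", "y"), node="c"):
    return JudgmentMatrix(node, list(items), entries)


class TestConsolidate:
    def test_idempotent_on_identical_matrices(self):
        m = _m({(0, 1): 5})
        g = consolidate_judgments([m, m, m])
        assert g.entry(0, 1) == Fraction(5)

    def test_geometric_mean_of_9_and_1_is_3(self):
        g = consolidate_judgments([_m({(0, 1): 9}), _m({(0, 1): 1})])
        assert float(g.entry(0, 1)) == pytest.approx(3.0, rel=1e-12)

    def test_reciprocal_judgments_cancel(self):
        g = consolidate_judgments([_m({(0, 1): 2}), _m({(0, 1): Fraction(1, 2)})])
        assert float(g.entry(0, 1)) == pytest.approx(1.0, rel=1e-12)

    def test_respondent_order_invariance(self):
        ms = [_m({(0, 1): v}) for v in (2, 7, Fraction(1, 3))]
        a = consolidate_judgments(ms).entry(0, 1)
        b = consolidate_judgments(ms[::-1]).entry(0, 1)
        assert float(a) == pytest.approx(float(b), rel=1e-12)

    def test_output_reciprocal_by_construction(self):
        g = consolidate_judgments([_m({(0, 1): 3}), _m({(0, 1): 7})])
        assert g.is_reciprocal()

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(JudgmentError, match="mismatch"):
            consolidate_judgments([_m({(0, 1): 2}), _m({(0, 1): 2}, node="d")])


class TestPropagate:
    def test_two_level_product(self, tiny_tree):
        local = {
            "goal": pd.Series({"c1": 0.6, "c2": 0.4}),
            "c1": pd.Series({"a": 0.7, "b": 0.3}),
            "c2": pd.Series({"x": 0.5, "y": 0.3, "z": 0.2}),
        }
        gw = propagate_global_weights(tiny_tree, local)
        assert gw["a"] == pytest.approx(0.42)
        assert gw["z"] == pytest.approx(0.08)
        assert gw.sum() == pytest.approx(1, abs=1e-12)

    def test_single_category_gw_equals_lw(self):
        from ahp_needs.hierarchy import Hierarchy, Node

        h = Hierarchy(
            Node("g", "G", [Node("c", "C", [Node("a", "A"), Node("b", "B")])])
        )
        # degenerate: root has one child, so its local vector is (1,)
        local = {"g": pd.Series({"c": 1.0}), "c": pd.Series({"a": 0.8, "b": 0.2})}
        gw = propagate_global_weights(h, local)
        assert gw["a"] == pytest.approx(0.8)
        assert gw["b"] == pytest.approx(0.2)

    def test_missing_local_vector_rejected(self, tiny_tree):
        with pytest.raises(KeyError, match="c2"):
            propagate_global_weights(
                tiny_tree,
                {"goal": pd.Series({"c1": 0.5, "c2": 0.5}),
                 "c1": pd.Series({"a": 0.5, "b": 0.5})},
            )

    def test_three_level_recursion(self):
        from ahp_needs.hierarchy import Hierarchy, Node

        h = Hierarchy(
            Node(
                "g",
                "G",
                [
                    Node("c1", "C1",
                         [Node("s", "S", [Node("a", "A"), Node("b", "B")]),
                          Node("t", "T", [Node("c", "C"), Node("d", "D")])]),
                    Node("c2", "C2", [Node("e", "E"), Node("f", "F")]),
                ],
            )
        )
        local = {
            "g": pd.Series({"c1": 0.5, "c2": 0.5}),
            "c1": pd.Series({"s": 0.4, "t": 0.6}),
            "s": pd.Series({"a": 0.9, "b": 0.1}),
            "t": pd.Series({"c": 0.5, "d": 0.5}),
            "c2": pd.Series({"e": 0.25, "f": 0.75}),
        }
        gw = propagate_global_weights(h, local)
        assert gw["a"] == pytest.approx(0.5 * 0.4 * 0.9)
        assert gw.sum() == pytest.approx(1, abs=1e-12)


class TestRank:
    def test_descending_with_stable_tie_order(self):
        gw = pd.Series({"p": 0.25, "q": 0.25, "r": 0.5})
        t = rank_needs(gw)
        assert list(t["need"]) == ["r", "p", "q"]
        assert list(t["rank"]) == [1, 2, 2]

    def test_all_equal_all_rank_one(self):
        t = rank_needs(pd.Series({"a": 0.5, "b": 0.5}))
        assert list(t["rank"]) == [1, 1]
        assert list(t["need"]) == ["a", "b"]  # document order preserved

    def test_two_leaves(self):
        t = rank_needs(pd.Series({"a": 0.4, "b": 0.6}))
        assert list(zip(t["need"], t["rank"])) == [("b", 1), ("a", 2)]


class TestPanel:
    def test_weight_normalization_invariants(self, paper_panel):
        _, _, _, res = paper_panel
        for code in res.codes():
            assert res.cw[code].sum() == pytest.approx(1, abs=1e-9)
            assert res.gw[code].sum() == pytest.approx(1, abs=1e-9)
            for node_id, lw in res.local[code].items():
                assert lw.sum() == pytest.approx(1, abs=1e-9)
        assert res.group_cw.sum() == pytest.approx(1, abs=1e-9)
        assert res.group_gw.sum() == pytest.approx(1, abs=1e-9)

    def test_gw_is_cw_times_lw(self, paper_panel):
        _, _, _, res = paper_panel
        h = res.hierarchy
        for leaf in h.leaves():
            cat = h.parent(leaf.id)
            expected = res.group_cw[cat] * res.group_local[cat][leaf.id]
            assert res.group_gw[leaf.id] == pytest.approx(expected, abs=1e-12)

    def test_category_leaf_gw_sums_to_cw(self, paper_panel):
        _, _, _, res = paper_panel
        h = res.hierarchy
        for cat in h.categories():
            total = sum(res.group_gw[c.id] for c in cat.children)
            assert total == pytest.approx(res.group_cw[cat.id], abs=1e-9)

    def test_identical_consistent_respondents_are_fixed_point(self, tiny_tree):
        from ahp_needs.judgments import Judgment

        jds = []
        for code in ("r1", "r2", "r3"):
            jds += [
                Judgment(code, "goal", "c1", "c2", "a", 3),
                Judgment(code, "c1", "a", "b", "a", 2),
                Judgment(code, "c2", "x", "y", "a", 2),
                Judgment(code, "c2", "x", "z", "a", 4),
                Judgment(code, "c2", "y", "z", "a", 2),
            ]
        res = fit_panel(tiny_tree, jds)
        for code in res.codes():
            assert np.allclose(res.gw[code], res.group_gw, atol=1e-9)

    def test_aip_aggregation_close_to_aij_for_homogeneous_panel(self, paper_panel):
        spec, panel, judgments, res_aij = paper_panel
        res_aip = fit_panel(spec.hierarchy, judgments, panel, aggregation="aip")
        assert float((res_aip.group_gw - res_aij.group_gw).abs().max()) < 0.01


class TestSubgroupMedians:
    def test_single_respondent_group_is_that_respondent(self, tiny_tree):
        from ahp_needs.judgments import Judgment, Respondent

        jds = [
            Judgment("solo", "goal", "c1", "c2", "a", 2),
            Judgment("solo", "c1", "a", "b", "equal", 1),
            Judgment("solo", "c2", "x", "y", "a", 3),
            Judgment("solo", "c2", "x", "z", "a", 3),
            Judgment("solo", "c2", "y", "z", "equal", 1),
        ]
        res = fit_panel(tiny_tree, jds, [Respondent("solo", "clinical")])
        med = subgroup_median_weights(res, "clinical")
        assert np.allclose(med["gw"], res.gw["solo"])

    def test_two_respondents_midpoint(self, paper_panel):
        spec, panel, judgments, res = paper_panel
        codes = res.codes("clinical")[:2]
        sub = res.gw_table()[codes]
        mid = (sub[codes[0]] + sub[codes[1]]) / 2
        two = sub.median(axis=1)
        assert np.allclose(two, mid)

    def test_matches_sort_based_oracle(self, paper_panel):
        _, _, _, res = paper_panel
        med = subgroup_median_weights(res, "technical")
        table = res.gw_table("technical")
        for need in table.index:
            vals = np.sort(table.loc[need].to_numpy())
            n = len(vals)
            oracle = (
                vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
            )
            assert med["gw"][need] == pytest.approx(oracle, abs=1e-15)

    def test_medians_not_renormalized(self, paper_panel):
        _, _, _, res = paper_panel
        med = subgroup_median_weights(res, "technical")
        # medians of normalized vectors need not sum to one
        assert med["gw"].sum() != pytest.approx(1, abs=1e-12)

    def test_empty_group_rejected(self, paper_panel):
        _, _, _, res = paper_panel
        with pytest.raises(JudgmentError, match="other"):
            subgroup_median_weights(res, "other")
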