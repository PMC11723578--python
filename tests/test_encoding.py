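"""Encoding classifier, contingency tables, chi-square comparisons."""

import itertools

import numpy as np
import pandas as pd
import pytest

import calshift as cs
from calshift.encoding import CATEGORIES, SUBTYPES
from calshift.errors import DataError, JoinError


LABELS = ("excited", "inhibited", "not_significant")


def encoding_frame(category_counts_by: dict, pair: str = "us") -> pd.DataFrame:
    """Minimal encoding table with given category multiplicities."""
    rows = []
    i = 0
    subtype_for = {"salience": "excited/excited",
                   "valence": "excited/not_significant",
                   "not_significant": "not_significant/not_significant"}
    for cat, n in category_counts_by.items():
        for _ in range(n):
            rows.append({
                "neuron_id_a": f"n{i}", "neuron_id_b": f"n{i}",
                f"{pair}_category": cat, f"{pair}_subtype": subtype_for[cat],
            })
            i += 1
    return pd.DataFrame(rows)


class TestClassifyEncoding:
    @pytest.mark.parametrize("a,b,category", [
        ("excited", "excited", "salience"),
        ("inhibited", "inhibited", "salience"),
        ("not_significant", "not_significant", "not_significant"),
        ("excited", "inhibited", "valence"),
        ("inhibited", "excited", "valence"),
        ("excited", "not_significant", "valence"),
        ("not_significant", "excited", "valence"),
        ("inhibited", "not_significant", "valence"),
        ("not_significant", "inhibited", "valence"),
    ])
    def test_all_nine_cells(self, a, b, category):
        cat, subtype = cs.classify_encoding(a, b)
        assert cat == category
        assert subtype == f"{a}/{b}"

    def test_invalid_label_raises(self):
        with pytest.raises(DataError, match="invalid response label"):
            cs.classify_encoding("strong", "excited")

    def test_category_symmetric_under_swap(self):
        for a, b in itertools.product(LABELS, LABELS):
            assert cs.classify_encoding(a, b)[0] == cs.classify_encoding(b, a)[0]


class TestBuildEncodingTable:
    def _results(self, ids, labels, stimulus):
        return pd.DataFrame({
            "neuron_id": ids, "stimulus": stimulus, "label": labels,
        })

    def test_empty_registration_gives_empty_table(self):
        reg = cs.RegistrationMap([])
        out = cs.build_encoding_table(
            self._results([], [], "food"), self._results([], [], "shock"), reg
        )
        assert len(out) == 0

    def test_unresolved_pair_names_the_id(self):
        reg = cs.RegistrationMap([("x1", "y1")])
        res_a = self._results(["x1"], ["excited"], "food")
        res_b = self._results(["other"], ["excited"], "shock")
        with pytest.raises(JoinError, match="y1"):
            cs.build_encoding_table(res_a, res_b, reg)

    def test_joint_labels_and_partition(self):
        ids_a = [f"a{i}" for i in range(9)]
        ids_b = [f"b{i}" for i in range(9)]
        pairs = list(itertools.product(LABELS, LABELS))
        res_a = self._results(ids_a, [p[0] for p in pairs], "food")
        res_b = self._results(ids_b, [p[1] for p in pairs], "shock")
        table = cs.build_encoding_table(
            res_a, res_b, cs.RegistrationMap(list(zip(ids_a, ids_b)))
        )
        counts = cs.category_counts(table, "us", "subtype")
        assert counts.counts.sum() == 9
        assert set(counts.col_labels) == set(SUBTYPES)
        cat = cs.category_counts(table, "us", "category")
        assert cat.counts.sum() == 9
        assert dict(zip(cat.col_labels, cat.counts[0])) == {
            "salience": 2, "valence": 6, "not_significant": 1}

    def test_recovered_labels_reproduce_true_categories(self, strong_pair_results):
        """Where per-stimulus labels are recovered, categories must agree."""
        res_food, res_shock, registration, truth = strong_pair_results
        table = cs.build_encoding_table(res_food, res_shock, registration)
        merged = table.merge(truth.table, left_on="neuron_id_a",
                             right_on="neuron_id")
        ok = (
            (merged["label_food_x"]
             == merged["label_food_y"].replace("none", "not_significant"))
            & (merged["label_shock_x"]
               == merged["label_shock_y"].replace("none", "not_significant"))
        )
        assert ok.mean() > 0.9  # strong effects: labels essentially recovered
        assert (merged.loc[ok, "us_category_x"]
                == merged.loc[ok, "us_category_y"]).all()


class TestCategoryCounts:
    def test_printed_us_counts_and_percentages(self):
        table = encoding_frame(
            {"salience": 46, "valence": 198, "not_significant": 59})
        ct = cs.category_counts(table, "us", "category")
        assert dict(zip(ct.col_labels, ct.counts[0])) == {
            "salience": 46, "valence": 198, "not_significant": 59}
        pct = dict(zip(ct.col_labels, ct.percentages()[0]))
        # nearest-percent values; 59/303 = 19.47% rounds to 19
        assert pct == {"salience": 15, "valence": 65, "not_significant": 19}

    def test_printed_cs_counts_and_percentages(self):
        table = encoding_frame(
            {"salience": 7, "valence": 57, "not_significant": 239}, pair="cs")
        ct = cs.category_counts(table, "cs", "category")
        pct = dict(zip(ct.col_labels, ct.percentages()[0]))
        assert pct == {"salience": 2, "valence": 19, "not_significant": 79}

    def test_single_neuron_table(self):
        table = encoding_frame({"valence": 1})
        ct = cs.category_counts(table, "us", "category")
        assert ct.counts.tolist() == [[0, 1, 0]]


class TestChiSquare:
    @pytest.mark.parametrize("counts,expected,tol", [
        ([[7, 57, 239], [46, 198, 59]], 215.4, 0.05),
        ([[22, 115, 28], [24, 83, 31]], 3.029, 0.05),
        ([[2, 33, 109], [4, 35, 120]], 0.5126, 0.01),
    ])
    def test_printed_tables(self, counts, expected, tol):
        ct = cs.ContingencyTable(np.array(counts),
                                 ["r1", "r2"], ["c1", "c2", "c3"])
        stat, dof, p = cs.chi_square_independence(ct)
        assert stat == pytest.approx(expected, abs=tol)
        assert dof == 2

    def test_perfect_independence(self):
        ct = cs.ContingencyTable(np.array([[10, 10], [10, 10]]), ["a", "b"], ["c", "d"])
        stat, dof, p = cs.chi_square_independence(ct)
        assert stat == 0.0 and p == 1.0

    def test_diagonal_hand_computation(self):
        # expected count 2.5 in every cell -> statistic 4 * 2.5^2/2.5 = 10
        ct = cs.ContingencyTable(np.array([[5, 0], [0, 5]]), ["a", "b"], ["c", "d"])
        stat, dof, _ = cs.chi_square_independence(ct)
        assert stat == pytest.approx(10.0) and dof == 1

    def test_invariant_under_permutation(self):
        counts = np.array([[7, 57, 239], [46, 198, 59]])
        base = cs.chi_square_independence(
            cs.ContingencyTable(counts, ["a", "b"], ["x", "y", "z"]))[0]
        perm = cs.chi_square_independence(
            cs.ContingencyTable(counts[::-1, ::-1], ["b", "a"], ["z", "y", "x"]))[0]
        assert perm == pytest.approx(base, abs=1e-9)

    def test_degenerate_tables_rejected(self):
        with pytest.raises(DataError):
            cs.chi_square_independence(
                cs.ContingencyTable(np.array([[1, 2, 3]]), ["a"], ["x", "y", "z"]))
        with pytest.raises(DataError, match="sums"):
            cs.chi_square_independence(
                cs.ContingencyTable(np.array([[1, 0], [2, 0]]), ["a", "b"], ["x", "y"]))


class TestOrderGroups:
    def test_known_counts_recovered(self):
        table = encoding_frame(
            {"salience": 4, "valence": 6, "not_significant": 2})
        table["cs_category"] = table["us_category"]
        table["cs_subtype"] = table["us_subtype"]
        groups = {f"n{i}": ("appetitive_first" if i % 2 == 0 else "fear_first")
                  for i in range(12)}
        out = cs.compare_order_groups(table, groups)
        assert out["us"]["df"] == 2
        assert out["us"]["table"].counts.sum() == 12

    def test_identical_groups_give_zero_statistic(self):
        half = encoding_frame({"salience": 5, "valence": 8, "not_significant": 3})
        table = pd.concat([half, half], ignore_index=True)
        table["neuron_id_a"] = [f"m{i}" for i in range(len(table))]
        table["cs_category"] = table["us_category"]
        table["cs_subtype"] = table["us_subtype"]
        groups = ["appetitive_first"] * len(half) + ["fear_first"] * len(half)
        out = cs.compare_order_groups(table, pd.Series(groups))
        assert out["us"]["statistic"] == pytest.approx(0.0)

    def test_missing_assignment_rejected(self):
        table = encoding_frame({"valence": 2})
        table["cs_category"] = table["us_category"]
        with pytest.raises(DataError):
            cs.compare_order_groups(table, {"n0": "appetitive_first"})
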