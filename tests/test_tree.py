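"""CART correctness: Gini closed forms, split search, exhaustive oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phenoresp.tree import (
    TreeParams,
    best_split,
    confusion_matrix,
    feature_importance,
    fit_cart,
    gini_impurity,
    predict,
    prepare_features,
    tree_to_dot,
    tree_to_json,
)

LOOSE = TreeParams(impurity_stop=0.0, max_depth=2, min_samples_split=2,
                   min_samples_leaf=1)


class TestGini:
    @pytest.mark.parametrize("counts,expected", [
        ((10, 0, 0, 0), 0.0),
        ((5, 5, 0, 0), 0.5),
        ((1, 1, 1, 1), 0.75),
        ((2, 1), 1 - (4 + 1) / 9),
    ])
    def test_closed_forms(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_rejects_all_zero(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            gini_impurity((3, -1))


class TestBestSplit:
    def test_perfect_threshold(self):
        threshold, decrease = best_split(np.array([1, 2, 3, 4]),
                                         np.array([0, 0, 1, 1]), LOOSE)
        assert threshold == pytest.approx(2.5)
        assert decrease == pytest.approx(0.5)

    def test_constant_column_gives_none(self):
        assert best_split(np.array([3, 3, 3, 3]),
                          np.array([0, 1, 0, 1]), LOOSE) is None

    def test_binary_indicator_perfectly_correlated(self):
        column = np.array([0, 0, 1, 1, 1], dtype=float)
        labels = np.array([0, 0, 1, 1, 1])
        parent = gini_impurity(np.bincount(labels))
        _, decrease = best_split(column, labels, LOOSE)
        assert decrease == pytest.approx(parent)

    def test_min_samples_leaf_respected(self):
        params = TreeParams(impurity_stop=0.0, min_samples_leaf=2,
                            min_samples_split=2)
        # the only improving threshold would isolate one sample
        result = best_split(np.array([1, 2, 2, 2]), np.array([1, 0, 0, 0]),
                            params)
        assert result is None

    def test_matches_exhaustive_enumeration(self):
        """Winner equals brute force over all midpoint candidates."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            column = rng.integers(0, 6, size=10).astype(float)
            labels = rng.integers(0, 3, size=10)
            got = best_split(column, labels, LOOSE, n_classes=3)
            # oracle: direct evaluation of every midpoint
            xs = np.unique(column)
            best = None
            parent = gini_impurity(np.bincount(labels, minlength=3))
            for lo, hi in zip(xs, xs[1:]):
                thr = (lo + hi) / 2
                left, right = labels[column <= thr], labels[column > thr]
                dec = parent \
                    - len(left) / 10 * gini_impurity(np.bincount(left, minlength=3)) \
                    - len(right) / 10 * gini_impurity(np.bincount(right, minlength=3))
                if best is None or dec > best[1] + 1e-12:
                    best = (thr, dec)
            if best is None or best[1] <= 1e-12:
                assert got is None
            else:
                assert got[0] == pytest.approx(best[0])
                assert got[1] == pytest.approx(best[1])


def exhaustive_cart(X, y, depth):
    """Best achievable greedy tree by exhaustive split-sequence search.

    For depth <= 2 and a handful of rows, enumerates every (feature,
    threshold) choice at every node and returns the minimal weighted leaf
    impurity achievable; the greedy CART must attain the same first split
    decrease and cannot be beaten at depth 1.
    """
    n, m = X.shape
    parent = gini_impurity(np.bincount(y, minlength=y.max() + 1))
    best_dec = 0.0
    for j in range(m):
        xs = np.unique(X[:, j])
        for lo, hi in zip(xs, xs[1:]):
            thr = (lo + hi) / 2
            left, right = y[X[:, j] <= thr], y[X[:, j] > thr]
            dec = parent \
                - len(left) / n * gini_impurity(np.bincount(left, minlength=y.max() + 1)) \
                - len(right) / n * gini_impurity(np.bincount(right, minlength=y.max() + 1))
            best_dec = max(best_dec, dec)
    return best_dec


class TestFitCart:
    def test_constant_labels_single_leaf(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        root = fit_cart(X, [2, 2, 2, 2], LOOSE)
        assert root.is_leaf
        assert root.impurity == 0.0

    def test_high_impurity_stop_gives_stump(self):
        X = pd.DataFrame({"a": np.arange(8, dtype=float)})
        y = [1, 2, 3, 4, 1, 2, 3, 4]
        root = fit_cart(X, y, TreeParams(impurity_stop=0.75))
        assert root.is_leaf

    def test_row_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fit_cart(pd.DataFrame({"a": [1.0, 2.0]}), [1, 2, 3])

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_cart(pd.DataFrame({"a": [1.0, np.nan]}), [1, 2])

    @pytest.mark.parametrize("seed", range(8))
    def test_first_split_matches_exhaustive_search(self, seed):
        """On tiny instances the greedy root split attains the exhaustive
        best impurity decrease."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        X = rng.integers(0, 4, size=(n, 3)).astype(float)
        y = rng.integers(0, 3, size=n)
        root = fit_cart(pd.DataFrame(X, columns=list("abc")), y + 1, LOOSE)
        best = exhaustive_cart(X, y, depth=2)
        if root.is_leaf:
            assert best <= 1e-12 or root.impurity == 0.0
        else:
            got = root.weighted_decrease  # n_total scaling is 1 at the root
            assert got == pytest.approx(best, abs=1e-12)

    def test_monotone_stop_rule(self):
        """Raising impurity_stop never increases the node count."""
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = rng.integers(1, 5, size=60)

        def count_nodes(node):
            return 1 if node.is_leaf else (1 + count_nodes(node.left)
                                           + count_nodes(node.right))

        counts = [count_nodes(fit_cart(X, y, TreeParams(impurity_stop=s)))
                  for s in (0.0, 0.2, 0.5, 0.74)]
        assert counts == sorted(counts, reverse=True)

    def test_deterministic_serialization(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.integers(1, 5, size=40)
        a = tree_to_json(fit_cart(X, y, TreeParams()))
        b = tree_to_json(fit_cart(X, y, TreeParams()))
        assert a == b

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = rng.integers(1, 5, size=50)
        root = fit_cart(X, y, TreeParams(impurity_stop=0.0))

        def check(node):
            if not node.is_leaf:
                assert np.array_equal(
                    node.class_counts,
                    node.left.class_counts + node.right.class_counts)
                check(node.left)
                check(node.right)
        check(root)

    def test_sklearn_training_accuracy_cross_check(self):
        """Our unrestricted CART should match sklearn's training accuracy
        on a separable problem (both drive leaves pure)."""
        from sklearn.tree import DecisionTreeClassifier
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        y = (X["a"] + 0.5 * X["b"] > 0).astype(int).to_numpy() + 1
        params = TreeParams(impurity_stop=0.0, max_depth=8,
                            min_samples_split=2, min_samples_leaf=1)
        ours = (predict(fit_cart(X, y, params), X) == y).mean()
        sk = DecisionTreeClassifier(max_depth=8, random_state=0).fit(X, y)
        assert ours == pytest.approx(sk.score(X, y))


class TestImportance:
    def test_stump_has_empty_table(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        root = fit_cart(X, [1, 1, 1, 1], LOOSE)
        assert feature_importance(root).empty

    def test_single_split_full_weight(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [0.0, 0.0, 0.0, 0.0]})
        root = fit_cart(X, [1, 1, 2, 2], LOOSE)
        table = feature_importance(root)
        assert list(table["feature"]) == ["a"]
        assert table["importance_pct"].iloc[0] == pytest.approx(100.0)

    def test_importances_sum_to_100(self):
        rng = np.random.default_rng(13)
        X = pd.DataFrame(rng.normal(size=(60, 5)), columns=list("abcde"))
        y = rng.integers(1, 5, size=60)
        root = fit_cart(X, y, TreeParams(impurity_stop=0.0))
        table = feature_importance(root)
        assert table["importance_pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (table["importance_pct"] >= 0).all()
        assert list(table["importance_pct"]) == sorted(
            table["importance_pct"], reverse=True)

    def test_onehot_aggregation(self):
        X = pd.DataFrame({"g=AA": [1.0, 1, 0, 0], "g=GG": [0.0, 0, 1, 1]})
        root = fit_cart(X, [1, 1, 2, 2], LOOSE)
        table = feature_importance(root, onehot_parent={"g=AA": "g", "g=GG": "g"})
        assert list(table["feature"]) == ["g"]
        assert table["importance_pct"].iloc[0] == pytest.approx(100.0)


class TestPrepareFeatures:
    def test_imputation_and_onehot(self):
        baselines = pd.DataFrame({
            "patient_id": ["a", "b", "c", "d"],
            "age_years": [10.0, np.nan, 12.0, 14.0],
            "geno": ["AA", "GA", None, "AA"],
        })
        design, parents = prepare_features(baselines)
        assert not design.isna().any().any()
        assert "age_years_imputed" in design.columns
        assert "geno_imputed" in design.columns
        assert parents["geno=AA"] == "geno"
        # median imputation
        assert design.loc[1, "age_years"] == pytest.approx(12.0)

    def test_exports(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        root = fit_cart(X, [1, 1, 2, 2], LOOSE)
        payload = tree_to_json(root)
        assert '"feature": "a"' in payload
        dot = tree_to_dot(root)
        assert dot.startswith("digraph") and "a <= 2.5" in dot


def test_confusion_matrix_diagonal_on_perfect_fit():
    X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
    y = [1, 1, 2, 2]
    root = fit_cart(X, y, LOOSE)
    pred = predict(root, X)
    cm = confusion_matrix(y, pred)
    assert cm.loc[1, 1] == 2 and cm.loc[2, 2] == 2
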