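import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import histact as h


def gini(n, na):
    if n == 0:
        return 0.0
    p = na / n
    return 2 * p * (1 - p)


def exhaustive_best_split(X, y):
    """Independent best-Gini-split search by explicit loops.

    Returns (best_gain, best_feature) with first-feature tie-breaking, or
    (None, None) when no split decreases impurity.
    """
    n = len(y)
    na = int(sum(y))
    parent = n * gini(n, na)
    best_gain, best_f = 0.0, None
    for f in range(X.shape[1]):
        n1 = n1a = 0
        for i in range(n):
            if X[i, f]:
                n1 += 1
                n1a += int(y[i])
        n0, n0a = n - n1, na - n1a
        if n1 == 0 or n0 == 0:
            continue
        gain = parent - n1 * gini(n1, n1a) - n0 * gini(n0, n0a)
        if gain > best_gain + 1e-12:
            best_gain, best_f = gain, f
    return (best_gain, best_f) if best_f is not None else (None, None)


def manual_route(tree, row):
    node = tree.root
    while isinstance(node, h.tree.Split):
        node = node.plus if row[node.feature] else node.minus
    return 1 if node.label == h.ACTIVE else -1


class TestGrowTree:
    def test_perfect_separator_single_node(self):
        X = np.array([[1], [1], [0], [0]], dtype=np.uint8)
        y = np.array(["active", "active", "inactive", "inactive"])
        t = h.grow_tree(X, y, k=1)
        assert t.k == 1
        assert h.training_accuracy(t, X, y) == 1.0

    def test_toy_root_matches_exhaustive_search(self, toy_tree_data):
        X, y, labels = toy_tree_data
        t = h.grow_tree(X, y, k=1, feature_labels=labels)
        ybool = y == "active"
        _, best_f = exhaustive_best_split(X, ybool)
        assert t.root.feature == best_f

    def test_invalid_k_rejected(self, toy_tree_data):
        X, y, _ = toy_tree_data
        with pytest.raises(ValueError):
            h.grow_tree(X, y, k=0)

    def test_constant_labels_single_leaf(self):
        X = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        with pytest.warns(UserWarning, match="identical"):
            t = h.grow_tree(X, np.array(["active", "active"]), k=3)
        assert t.k == 0

    def test_training_accuracy_nondecreasing_in_k(self, cd4_small):
        ds, fm, pr = cd4_small
        y = pr.labels
        accs = [
            h.training_accuracy(h.grow_tree(fm.values, y, k=k), fm.values, y)
            for k in range(1, 8)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(accs, accs[1:]))

    def test_nested_growth(self, cd4_small):
        """The k-node tree's splits are a prefix of the (k+1)-node tree's."""
        ds, fm, pr = cd4_small
        y = pr.labels
        prev = None
        for k in range(1, 6):
            t = h.grow_tree(fm.values, y, k=k)
            feats = sorted((s.feature_label, s.n_active, s.n_inactive) for s in t.splits())
            if prev is not None:
                assert len(set(map(tuple, prev)) - set(map(tuple, feats))) == 0
            prev = feats

    def test_unbounded_k_reproduces_labels(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, (40, 8)).astype(np.uint8)
        # ensure no two identical rows get different labels
        _, uniq_idx = np.unique(X, axis=0, return_index=True)
        X = X[uniq_idx]
        y = rng.integers(0, 2, len(X)).astype(bool)
        if y.all() or not y.any():
            y[0] = ~y[0]
        t = h.grow_tree(X, y, k=len(X))
        assert np.array_equal(t.predict_active(X), y)

    def test_planted_mark_dominates_nodes(self, cd4_medium):
        _, _, pr = cd4_medium
        planted = sum("H2BK5ac" in lab for lab in pr.tree.node_feature_labels())
        assert planted >= 4

    def test_root_gain_matches_sklearn(self):
        from sklearn.tree import DecisionTreeClassifier

        rng = np.random.default_rng(0)
        for _ in range(20):
            n, f = int(rng.integers(10, 60)), int(rng.integers(2, 8))
            X = rng.integers(0, 2, (n, f)).astype(np.uint8)
            beta = rng.normal(0, 1.5, f)
            y = (X @ beta + rng.normal(0, 1, n)) > 0
            if y.all() or not y.any():
                continue
            gain, best_f = exhaustive_best_split(X, y)
            clf = DecisionTreeClassifier(criterion="gini", max_depth=1, random_state=0)
            clf.fit(X, y)
            if clf.get_depth() == 0:
                assert gain is None
                continue
            tr = clf.tree_
            sk_gain = tr.n_node_samples[0] * tr.impurity[0] - sum(
                tr.n_node_samples[c] * tr.impurity[c] for c in (1, 2)
            )
            # sklearn impurity is p(1-p)*2 as well for two classes
            assert gain == pytest.approx(sk_gain, rel=1e-9, abs=1e-9)


class TestAssignIndex:
    def test_single_leaf_active_tree(self):
        t = h.DecisionTree(h.tree.Leaf(h.ACTIVE, 3, 1), ["f0"])
        X = np.zeros((5, 1), dtype=np.uint8)
        assert np.all(h.assign_index(t, X) == 1)

    def test_perfect_tree_reproduces_labels(self):
        X = np.array([[1], [0], [1], [0]], dtype=np.uint8)
        y = np.array([True, False, True, False])
        t = h.grow_tree(X, y, k=1)
        assert np.array_equal(h.assign_index(t, X), np.where(y, 1, -1))

    def test_matches_manual_routing(self, toy_tree_data):
        X, y, labels = toy_tree_data
        t = h.grow_tree(X, y, k=3, feature_labels=labels)
        idx = h.assign_index(t, X)
        for i in range(len(X)):
            assert idx[i] == manual_route(t, X[i])

    def test_feature_alignment_by_label(self, toy_tree_data):
        X, y, labels = toy_tree_data
        t = h.grow_tree(X, y, k=2, feature_labels=labels)
        perm = [2, 0, 1]
        Xp = X[:, perm]
        labs_p = [labels[j] for j in perm]
        assert np.array_equal(h.assign_index(t, Xp, feature_labels=labs_p), h.assign_index(t, X))
        with pytest.raises(KeyError):
            h.assign_index(t, X[:, :2], feature_labels=labels[:2])


class TestDesignationCorrelation:
    def test_identical_and_opposite(self):
        a = np.array([1, -1, 1, -1])
        assert h.designation_correlation(a, a) == pytest.approx(1.0)
        assert h.designation_correlation(a, -a) == pytest.approx(-1.0)

    def test_orthogonal(self):
        a = np.array([1, 1, -1, -1])
        b = np.array([1, -1, 1, -1])
        assert h.designation_correlation(a, b) == pytest.approx(0.0)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = h.designation_correlation(np.ones(4, dtype=int), np.array([1, -1, 1, -1]))
        assert np.isnan(out)

    def test_non_pm1_rejected(self):
        with pytest.raises(ValueError):
            h.designation_correlation(np.array([1, 0]), np.array([1, -1]))

    def test_nested_tree_designations_strongly_correlated(self, cd4_small):
        """Designations from consecutive tree sizes correlate highly, the
        pattern that justifies stopping at a compact tree."""
        ds, fm, pr = cd4_small
        y = pr.labels
        idx = {k: h.assign_index(h.grow_tree(fm.values, y, k=k), fm.values) for k in (4, 5, 6)}
        r45 = h.designation_correlation(idx[4], idx[5])
        r56 = h.designation_correlation(idx[5], idx[6])
        assert r45 > 0.6 and r56 > 0.6


class TestSignificance:
    def test_separable_data_attains_minimum_p(self):
        # 20 genes perfectly separated by one feature: no permutation of a
        # balanced label vector can reproduce 100% accuracy except the
        # original/complement arrangements (probability ~1e-5 each draw)
        X = np.repeat([[1], [0]], 10, axis=0).astype(np.uint8)
        y = np.repeat([True, False], 10)
        p = h.tree_significance(X, y, k=1, B=49, seed=0)
        assert p == pytest.approx(1 / 50)

    def test_b_too_small_rejected(self):
        X = np.zeros((4, 1), dtype=np.uint8)
        with pytest.raises(ValueError):
            h.tree_significance(X, np.array([True, False, True, False]), k=1, B=5)

    def test_planted_signal_significant(self, cd4_small):
        ds, fm, pr = cd4_small
        cols = fm.region_columns("TSS")
        p = h.tree_significance(fm.values[:, cols], pr.labels, k=2, B=99, seed=3)
        assert p <= 0.05


@settings(max_examples=120, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 12),
    f=st.integers(1, 6),
    data=st.data(),
)
def test_root_split_matches_exhaustive_on_small_instances(n, f, data):
    bits = data.draw(st.lists(st.integers(0, 1), min_size=n * (f + 1), max_size=n * (f + 1)))
    arr = np.array(bits, dtype=np.uint8).reshape(n, f + 1)
    X, y = arr[:, :f], arr[:, f].astype(bool)
    gain, best_f = exhaustive_best_split(X, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = h.grow_tree(X, y, k=1)
    if gain is None:
        assert t.k == 0
    else:
        assert isinstance(t.root, h.tree.Split)
        assert t.root.feature == best_f
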