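"""Binary decision trees on presence/absence features, grown best-first.

Trees split on single (region, modification) features: the ``plus`` child
collects genes carrying the mark, the ``minus`` child those lacking it.
Growth is best-first on Gini impurity: at each step the frontier leaf
offering the largest total impurity decrease (summed over samples) is
split, until k internal nodes exist or no split helps.  Because every step
extends the previous tree, the k-node tree is nested inside the
(k+1)-node tree and training accuracy is non-decreasing in k — this is
what makes "the tree pruned to k nodes" well defined here.

Tie-breaking is fully deterministic: among features, the first in canonical
feature order wins; among frontier leaves with equal gain, the leaf with
more samples, then the earlier-created leaf.  Leaf labels are the training
majority, with ties going to "inactive" so an active call always requires
positive evidence.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "ACTIVE",
    "INACTIVE",
    "Leaf",
    "Split",
    "DecisionTree",
    "grow_tree",
    "assign_index",
    "training_accuracy",
    "designation_correlation",
    "tree_significance",
]

ACTIVE = "active"
INACTIVE = "inactive"

_GAIN_TOL = 1e-12


@dataclass
class Leaf:
    label: str
    n_active: int
    n_inactive: int


@dataclass
class Split:
    feature: int
    feature_label: str
    plus: "Node"
    minus: "Node"
    n_active: int
    n_inactive: int


Node = Union[Leaf, Split]


def as_active_bool(labels) -> np.ndarray:
    """Normalize labels to a boolean 'is active' vector."""
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr
    if arr.dtype.kind in "iu" and np.isin(arr, (0, 1)).all():
        return arr.astype(bool)
    if arr.dtype.kind in "US" or arr.dtype == object:
        ok = np.isin(arr, (ACTIVE, INACTIVE))
        if not ok.all():
            bad = arr[~ok][0]
            raise ValueError(f"unrecognized label {bad!r}")
        return arr == ACTIVE
    raise ValueError(f"cannot interpret labels of dtype {arr.dtype}")


@dataclass
class DecisionTree:
    root: Node
    feature_labels: list[str]

    @property
    def k(self) -> int:
        """Number of internal (split) nodes."""
        return len(self.splits())

    def splits(self) -> list[Split]:
        """Internal nodes in preorder (plus branch first)."""
        out: list[Split] = []
        stack: list[Node] = [self.root]
        while stack:
            node = stack.pop()
            if isinstance(node, Split):
                out.append(node)
                stack.append(node.minus)
                stack.append(node.plus)
        return out

    def node_feature_labels(self) -> list[str]:
        return [s.feature_label for s in self.splits()]

    def predict_active(self, features) -> np.ndarray:
        """Route every row to a leaf; True where the leaf label is active."""
        X = np.asarray(features)
        if X.ndim != 2 or X.shape[1] != len(self.feature_labels):
            raise ValueError(
                f"feature matrix has {X.shape[1] if X.ndim == 2 else '?'} columns, "
                f"tree expects {len(self.feature_labels)}"
            )
        out = np.zeros(X.shape[0], dtype=bool)
        stack: list[tuple[Node, np.ndarray]] = [(self.root, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if isinstance(node, Leaf):
                out[idx] = node.label == ACTIVE
            else:
                has = X[idx, node.feature].astype(bool)
                stack.append((node.plus, idx[has]))
                stack.append((node.minus, idx[~has]))
        return out

    # -- serialization: small nested JSON with explicit feature labels -----

    def _node_dict(self, node: Node) -> dict:
        if isinstance(node, Leaf):
            return {
                "label": node.label,
                "n_active": node.n_active,
                "n_inactive": node.n_inactive,
            }
        return {
            "feature": node.feature_label,
            "n_active": node.n_active,
            "n_inactive": node.n_inactive,
            "plus": self._node_dict(node.plus),
            "minus": self._node_dict(node.minus),
        }

    def to_json(self) -> str:
        payload = {"feature_labels": self.feature_labels, "tree": self._node_dict(self.root)}
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        payload = json.loads(text)
        labels = list(payload["feature_labels"])
        index = {lab: i for i, lab in enumerate(labels)}

        def build(d: dict) -> Node:
            if "feature" in d:
                return Split(
                    index[d["feature"]],
                    d["feature"],
                    build(d["plus"]),
                    build(d["minus"]),
                    int(d["n_active"]),
                    int(d["n_inactive"]),
                )
            return Leaf(d["label"], int(d["n_active"]), int(d["n_inactive"]))

        return cls(build(payload["tree"]), labels)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "DecisionTree":
        return cls.from_json(Path(path).read_text())


def _gini_counts(n: np.ndarray, na: np.ndarray) -> np.ndarray:
    """Gini impurity 2p(1-p) from total and active counts; 0 where n == 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, na / np.maximum(n, 1), 0.0)
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray, idx: np.ndarray, min_leaf: int):
    """Best (gain, feature) for a leaf's sample set, or None if no split helps.

    Gain is the total (count-weighted) Gini decrease.  Maximizing it equals
    minimizing h = n1a*n1i/n1 + n0a*n0i/n0, which is compared across
    features in exact integer arithmetic (cross-multiplication), so the
    first-in-canonical-order tie rule is immune to floating-point noise.
    Integer comparisons stay within int64 for leaves up to ~10^5 samples.
    """
    m = idx.size
    ysub = y[idx]
    na = int(ysub.sum())
    ni = m - na
    if na == 0 or ni == 0:
        return None
    sub = X[idx].astype(np.int64)
    n1 = sub.sum(axis=0)
    n1a = ysub.astype(np.int64) @ sub
    n0 = m - n1
    n0a = na - n1a
    n1i = n1 - n1a
    n0i = n0 - n0a
    valid = (n1 >= min_leaf) & (n0 >= min_leaf)
    if not valid.any():
        return None
    num = n1a * n1i * n0 + n0a * n0i * n1
    den = n1 * n0  # > 0 wherever valid
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, num / np.maximum(den, 1), np.inf)
    rmin = ratio.min()
    cand = np.flatnonzero(ratio <= rmin * (1.0 + 1e-9) + 1e-12)
    best = int(cand[0])
    for c in cand[1:]:
        c = int(c)
        if num[c] * den[best] < num[best] * den[c]:  # exact strict improvement
            best = c
    # positive gain test, exact: na*ni/m > num/den
    if na * ni * den[best] <= num[best] * m:
        return None
    gain = 2.0 * (na * ni / m - num[best] / den[best])
    return float(gain), best


def _make_leaf(na: int, ni: int) -> Leaf:
    return Leaf(ACTIVE if na > ni else INACTIVE, na, ni)


def grow_tree(
    features,
    labels,
    k: int,
    min_leaf: int = 1,
    feature_labels: Sequence[str] | None = None,
) -> DecisionTree:
    """Grow a best-first Gini tree with at most k internal nodes.

    Stops early (with fewer nodes) when no remaining split decreases
    impurity.  If all labels are identical a single-leaf tree (k = 0) is
    returned with a warning.
    """
    X = np.ascontiguousarray(features, dtype=np.uint8)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.isin(X, (0, 1)).all():
        raise ValueError("features must be binary (0/1)")
    y = as_active_bool(labels)
    if y.shape[0] != X.shape[0]:
        raise ValueError("features and labels have different lengths")
    if k < 1:
        raise ValueError("k must be >= 1")
    if min_leaf < 1:
        raise ValueError("min_leaf must be >= 1")
    if feature_labels is None:
        labels_list = [f"f{i}" for i in range(X.shape[1])]
    else:
        labels_list = list(feature_labels)
        if len(labels_list) != X.shape[1]:
            raise ValueError("feature_labels length mismatch")

    na_all = int(y.sum())
    ni_all = X.shape[0] - na_all
    if na_all == 0 or ni_all == 0:
        warnings.warn("all labels identical; returning a single-leaf tree")
        return DecisionTree(_make_leaf(na_all, ni_all), labels_list)

    all_idx = np.arange(X.shape[0])

    # frontier entries: mutable bookkeeping for growable leaves
    order = 0
    root_entry = {
        "idx": all_idx,
        "best": _best_split(X, y, all_idx, min_leaf),
        "leaf": _make_leaf(na_all, ni_all),
        "parent": None,
        "side": None,
        "order": order,
    }
    entries = [root_entry]
    root_node: Node = root_entry["leaf"]

    n_splits = 0
    while n_splits < k:
        cands = [e for e in entries if e["best"] is not None]
        if not cands:
            break
        e = max(cands, key=lambda e: (e["best"][0], e["idx"].size, -e["order"]))
        gain, f = e["best"]
        idx = e["idx"]
        has = X[idx, f].astype(bool)
        idx1, idx0 = idx[has], idx[~has]
        na1 = int(y[idx1].sum())
        na0 = int(y[idx0].sum())
        split = Split(
            f,
            labels_list[f],
            _make_leaf(na1, idx1.size - na1),
            _make_leaf(na0, idx0.size - na0),
            int(y[idx].sum()),
            idx.size - int(y[idx].sum()),
        )
        if e["parent"] is None:
            root_node = split
        else:
            setattr(e["parent"], e["side"], split)
        entries = [x for x in entries if x is not e]
        for side, child_idx, child_leaf in (
            ("plus", idx1, split.plus),
            ("minus", idx0, split.minus),
        ):
            order += 1
            entries.append(
                {
                    "idx": child_idx,
                    "best": _best_split(X, y, child_idx, min_leaf),
                    "leaf": child_leaf,
                    "parent": split,
                    "side": side,
                    "order": order,
                }
            )
        n_splits += 1
    return DecisionTree(root_node, labels_list)


def assign_index(
    tree: DecisionTree,
    features,
    feature_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Per-gene +1/-1 designation: +1 iff routed to an active-majority leaf.

    If ``feature_labels`` describe the given matrix's columns, they are
    aligned to the tree's feature order; a feature the tree needs but the
    matrix lacks raises ``KeyError``.
    """
    X = np.asarray(features)
    if feature_labels is not None and list(feature_labels) != tree.feature_labels:
        pos = {lab: j for j, lab in enumerate(feature_labels)}
        missing = [lab for lab in tree.feature_labels if lab not in pos]
        if missing:
            raise KeyError(f"feature matrix is missing tree features {missing}")
        X = X[:, [pos[lab] for lab in tree.feature_labels]]
    return np.where(tree.predict_active(X), 1, -1)


def training_accuracy(tree: DecisionTree, features, labels) -> float:
    y = as_active_bool(labels)
    return float((tree.predict_active(features) == y).mean())


def designation_correlation(a, b) -> float:
    """Pearson correlation of two +1/-1 designation vectors.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("index vectors must be 1-D and of equal length")
    for v in (a, b):
        if not np.isin(v, (1.0, -1.0)).all():
            raise ValueError("index vectors must contain only +1/-1")
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero variance in a designation vector; correlation undefined")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def tree_significance(
    features,
    labels,
    k: int,
    B: int = 200,
    seed: int | None = None,
    min_leaf: int = 1,
) -> float:
    """Permutation p-value for a k-node tree's training accuracy.

    Labels are permuted B times; p = (1 + #{permuted accuracy >= observed})
    / (B + 1), so the smallest attainable p is 1/(B+1).
    """
    if B < 19:
        raise ValueError("need B >= 19 permutations")
    X = np.ascontiguousarray(features, dtype=np.uint8)
    y = as_active_bool(labels)
    obs_tree = grow_tree(X, y, k, min_leaf=min_leaf)
    obs = training_accuracy(obs_tree, X, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        yp = rng.permutation(y)
        t = grow_tree(X, yp, k, min_leaf=min_leaf)
        if training_accuracy(t, X, yp) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (B + 1)
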