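"""Evaluation designs: per-region trees, random train/test trees, and
single-modification trees, scored by prediction accuracy frequency.

Prediction accuracy frequency is the fraction of genes whose tree-based
+1/-1 designation matches their threshold-based active/inactive label.
Per-region and single-modification designs score on all genes (the trees
are descriptive restrictions of the feature space); the train/test design
holds out a random half of the genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionFeatureMatrix
from .tree import DecisionTree, as_active_bool, assign_index, grow_tree

__all__ = [
    "EvalReport",
    "accuracy_frequency",
    "per_region_eval",
    "train_test_eval",
    "single_modification_eval",
    "rank_modifications",
]


@dataclass
class EvalReport:
    """Per-design accuracies and the trees that produced them."""

    design: str
    k_values: list[int]
    train_accuracy: dict[int, float]
    test_accuracy: dict[int, float] | None
    trees: dict[int, DecisionTree]
    seed: int | None = None
    region: str | None = None
    modification: str | None = None
    train_gene_ids: list[str] | None = None
    test_gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for d in filter(None, [self.train_accuracy, self.test_accuracy]):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"accuracy {v} outside [0, 1]")
        if self.train_gene_ids is not None and self.test_gene_ids is not None:
            if set(self.train_gene_ids) & set(self.test_gene_ids):
                raise ValueError("train and test gene sets overlap")

    def to_json(self) -> str:
        payload = {
            "design": self.design,
            "region": self.region,
            "modification": self.modification,
            "seed": self.seed,
            "k_values": self.k_values,
            "train_accuracy": {str(k): round(v, 10) for k, v in self.train_accuracy.items()},
            "test_accuracy": (
                None
                if self.test_accuracy is None
                else {str(k): round(v, 10) for k, v in self.test_accuracy.items()}
            ),
            "trees": {
                str(k): json.loads(t.to_json()) for k, t in sorted(self.trees.items())
            },
            "train_gene_ids": self.train_gene_ids,
            "test_gene_ids": self.test_gene_ids,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def accuracy_frequency(idx, labels) -> float:
    """Fraction of genes where (+1 <-> active) designation matches the label."""
    x = np.asarray(idx, dtype=np.int64)
    y = as_active_bool(labels)
    if x.shape != y.shape:
        raise ValueError("index and labels have different lengths")
    return float(((x == 1) == y).mean())


def _fit_and_score(X, y, k_list, feature_labels, X_test=None, y_test=None):
    trees: dict[int, DecisionTree] = {}
    train_acc: dict[int, float] = {}
    test_acc: dict[int, float] = {}
    for k in k_list:
        t = grow_tree(X, y, k, feature_labels=feature_labels)
        trees[k] = t
        train_acc[k] = accuracy_frequency(assign_index(t, X), y)
        if X_test is not None:
            test_acc[k] = accuracy_frequency(assign_index(t, X_test), y_test)
    return trees, train_acc, test_acc


def per_region_eval(
    fm: RegionFeatureMatrix,
    labels,
    region: str,
    k_list: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
) -> EvalReport:
    """Trees restricted to one region's modification columns, scored on all genes."""
    y = as_active_bool(labels)
    cols = fm.region_columns(region)
    X = fm.values[:, cols]
    feat = [fm.feature_labels[c] for c in cols]
    trees, train_acc, _ = _fit_and_score(X, y, k_list, feat)
    return EvalReport(
        design="per_region",
        region=region,
        k_values=list(k_list),
        train_accuracy=train_acc,
        test_accuracy=None,
        trees=trees,
    )


def train_test_eval(
    fm: RegionFeatureMatrix,
    labels,
    frac: float = 0.5,
    k_list: Sequence[int] = (1, 2, 3, 4, 5, 6, 7),
    seed: int | None = None,
) -> EvalReport:
    """Random train/test split over genes; trees grown on the training half."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must be in (0, 1)")
    y = as_active_bool(labels)
    n = len(fm.gene_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty train or test set")
    tr = np.sort(perm[:n_train])
    te = np.sort(perm[n_train:])
    if y[tr].all() or not y[tr].any():
        raise ValueError("a class is absent from the training split")
    trees, train_acc, test_acc = _fit_and_score(
        fm.values[tr], y[tr], k_list, fm.feature_labels, fm.values[te], y[te]
    )
    return EvalReport(
        design="train_test",
        k_values=list(k_list),
        train_accuracy=train_acc,
        test_accuracy=test_acc,
        trees=trees,
        seed=seed,
        train_gene_ids=[fm.gene_ids[i] for i in tr],
        test_gene_ids=[fm.gene_ids[i] for i in te],
    )


def single_modification_eval(
    fm: RegionFeatureMatrix,
    labels,
    modification: str,
    k: int = 5,
) -> EvalReport:
    """A k-node tree restricted to one mark's 24 region columns, scored on all genes."""
    y = as_active_bool(labels)
    cols = fm.modification_columns(modification)
    X = fm.values[:, cols]
    feat = [fm.feature_labels[c] for c in cols]
    trees, train_acc, _ = _fit_and_score(X, y, [k], feat)
    return EvalReport(
        design="single_modification",
        modification=modification,
        k_values=[k],
        train_accuracy=train_acc,
        test_accuracy=None,
        trees=trees,
    )


def rank_modifications(fm: RegionFeatureMatrix, labels, k: int = 5) -> pd.DataFrame:
    """Accuracy of each mark's k-node tree, sorted best-first.

    Ties break alphabetically by modification name.
    """
    rows = []
    for mod in fm.modifications:
        rep = single_modification_eval(fm, labels, mod, k=k)
        rows.append((mod, rep.train_accuracy[k]))
    df = pd.DataFrame(rows, columns=["modification", "accuracy"])
    df = df.sort_values(["accuracy", "modification"], ascending=[False, True])
    return df.reset_index(drop=True)
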