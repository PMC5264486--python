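"""Exhaustive multifactor-dimensionality-reduction (MDR) combination search.

For a combination of c binary attributes, genes fall into 2^c cells.  On
each training fold a cell is called high-risk when its active:inactive
count ratio strictly exceeds the overall training ratio (empty or tied
cells are low-risk); held-out genes are classified by their cell's risk
and scored by balanced accuracy, (sensitivity + specificity) / 2.  The
reported score ("Tba") is the mean testing balanced accuracy over a
seeded stratified cross-validation.  The search enumerates every
combination up to a given size and keeps the best per size, so unlike
greedy tree growth it considers attribute sets that share no prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionFeatureMatrix
from .tree import as_active_bool

__all__ = [
    "MdrResult",
    "mdr_score",
    "mdr_search",
    "mdr_training_balanced_accuracy",
    "mdr_report",
]


@dataclass
class MdrResult:
    """One scored attribute combination."""

    combo: tuple[str, ...]
    combo_indices: tuple[int, ...]
    fold_tbas: np.ndarray
    tba: float
    risk_map: dict[int, bool]

    def __post_init__(self) -> None:
        if len(self.combo) < 1:
            raise ValueError("combination must have at least one attribute")
        if not (0.0 <= self.tba <= 1.0):
            raise ValueError("balanced accuracy outside [0, 1]")


def _stratified_folds(
    y: np.ndarray, folds: int, seed: int | None
) -> list[np.ndarray]:
    """Seeded stratified fold assignment; returns per-fold test index arrays."""
    if folds < 2:
        raise ValueError("need at least 2 folds")
    act = np.flatnonzero(y)
    ina = np.flatnonzero(~y)
    if act.size < folds or ina.size < folds:
        raise ValueError("fold without both classes: too few genes per class")
    rng = np.random.default_rng(seed)
    act = rng.permutation(act)
    ina = rng.permutation(ina)
    out = []
    for f in range(folds):
        out.append(np.sort(np.concatenate([act[f::folds], ina[f::folds]])))
    return out


def _cell_codes(X: np.ndarray, idxs: Sequence[int]) -> np.ndarray:
    sub = X[:, list(idxs)].astype(np.int64)
    weights = 1 << np.arange(len(idxs), dtype=np.int64)
    return sub @ weights


def _high_risk(codes: np.ndarray, y: np.ndarray, n_cells: int) -> np.ndarray:
    """Cell is high-risk iff active/inactive ratio strictly exceeds the
    overall ratio; comparison done on counts so empty/tied cells are low."""
    a = np.bincount(codes[y], minlength=n_cells)
    i = np.bincount(codes[~y], minlength=n_cells)
    return a * i.sum() > i * a.sum()


def _resolve_combo(combo, feature_labels: Sequence[str] | None, n_features: int):
    idxs: list[int] = []
    names: list[str] = []
    for c in combo:
        if isinstance(c, str):
            if feature_labels is None:
                raise ValueError("string attributes need feature_labels")
            try:
                j = list(feature_labels).index(c)
            except ValueError:
                raise KeyError(f"unknown attribute {c!r}") from None
        else:
            j = int(c)
            if not 0 <= j < n_features:
                raise IndexError(f"attribute index {j} out of range")
        idxs.append(j)
        names.append(feature_labels[j] if feature_labels is not None else f"f{j}")
    if len(set(idxs)) != len(idxs):
        raise ValueError("repeated attribute in combination")
    return tuple(idxs), tuple(names)


def mdr_score(
    features,
    labels,
    combo,
    folds: int = 10,
    seed: int | None = None,
    feature_labels: Sequence[str] | None = None,
    _fold_sets: list[np.ndarray] | None = None,
) -> MdrResult:
    """Cross-validated testing balanced accuracy of one attribute combination.

    ``combo`` may hold column indices or (with ``feature_labels``) attribute
    names.  The score is invariant to attribute order within the combo.
    """
    X = np.asarray(features, dtype=np.uint8)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("features must be binary (0/1)")
    y = as_active_bool(labels)
    idxs, names = _resolve_combo(combo, feature_labels, X.shape[1])
    codes = _cell_codes(X, idxs)
    n_cells = 1 << len(idxs)
    fold_sets = _fold_sets if _fold_sets is not None else _stratified_folds(y, folds, seed)
    tbas = []
    for test in fold_sets:
        train = np.setdiff1d(np.arange(X.shape[0]), test, assume_unique=False)
        ytr, yte = y[train], y[test]
        if not (ytr.any() and (~ytr).any() and yte.any() and (~yte).any()):
            raise ValueError("fold without both classes")
        high = _high_risk(codes[train], ytr, n_cells)
        pred = high[codes[test]]
        sens = float(pred[yte].mean())
        spec = float((~pred[~yte]).mean())
        tbas.append(0.5 * (sens + spec))
    tbas = np.asarray(tbas)
    full_high = _high_risk(codes, y, n_cells)
    observed = np.unique(codes)
    risk_map = {int(c): bool(full_high[c]) for c in observed}
    return MdrResult(names, idxs, tbas, float(tbas.mean()), risk_map)


def mdr_training_balanced_accuracy(features, labels, combo,
                                   feature_labels: Sequence[str] | None = None) -> float:
    """Balanced accuracy of the risk rule fit and scored on all genes."""
    X = np.asarray(features, dtype=np.uint8)
    y = as_active_bool(labels)
    idxs, _ = _resolve_combo(combo, feature_labels, X.shape[1])
    codes = _cell_codes(X, idxs)
    high = _high_risk(codes, y, 1 << len(idxs))
    pred = high[codes]
    return 0.5 * (float(pred[y].mean()) + float((~pred[~y]).mean()))


def mdr_search(
    features,
    labels,
    region: str | None = None,
    k_max: int = 5,
    folds: int = 10,
    seed: int | None = None,
    max_evaluations: int = 200_000,
) -> list[MdrResult]:
    """Exhaustive search over all attribute combinations of size 1..k_max.

    ``features`` may be a :class:`RegionFeatureMatrix` (optionally restricted
    to one region's modification columns via ``region``) or a plain binary
    matrix.  Returns the best combination per size; ties go to the
    lexicographically first combination in canonical attribute order.
    """
    if isinstance(features, RegionFeatureMatrix):
        fm = features
        cols = fm.region_columns(region) if region is not None else np.arange(fm.n_features)
        X = fm.values[:, cols]
        names = [fm.feature_labels[c] for c in cols]
    else:
        if region is not None:
            raise ValueError("region selection requires a RegionFeatureMatrix")
        X = np.asarray(features, dtype=np.uint8)
        names = [f"f{j}" for j in range(X.shape[1])]
    y = as_active_bool(labels)
    m = X.shape[1]
    if not 1 <= k_max <= m:
        raise ValueError("k_max must be between 1 and the number of attributes")
    total = sum(comb(m, s) for s in range(1, k_max + 1))
    if total > max_evaluations:
        raise ValueError(
            f"search over {total} combinations exceeds the budget of "
            f"{max_evaluations}; lower k_max or subset the modifications"
        )
    fold_sets = _stratified_folds(y, folds, seed)
    best: list[MdrResult] = []
    for size in range(1, k_max + 1):
        top: MdrResult | None = None
        for idxs in combinations(range(m), size):
            res = mdr_score(X, y, idxs, feature_labels=names, _fold_sets=fold_sets)
            if top is None or res.tba > top.tba:
                top = res
        assert top is not None
        best.append(top)
    return best


def mdr_report(results: Sequence[MdrResult]) -> pd.DataFrame:
    rows = [(len(r.combo), ",".join(r.combo), r.tba) for r in results]
    return pd.DataFrame(rows, columns=["size", "combination", "tba"])
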