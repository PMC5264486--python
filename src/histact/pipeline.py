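"""End-to-end glue: from raw inputs to threshold-based activity labels.

The two-step protocol: (1) grow a k-node tree separating the expression
extremes (top and bottom fraction of genes by mean expression, emulating
the 3000-most/3000-least design), (2) designate every gene +1/-1 with that
tree and derive the activity threshold from the ranked designation vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ExpressionTable, read_annotation, read_expression, read_signal_table
from .regions import RegionFeatureMatrix, binarize, build_feature_matrix
from .threshold import ThresholdResult, cumulative_threshold, pvalue_threshold
from .tree import DecisionTree, assign_index, grow_tree

__all__ = ["PipelineResult", "derive_threshold", "load_inputs"]

logger = logging.getLogger("histact")


@dataclass
class PipelineResult:
    """Tree, ranked designations and threshold for one dataset."""

    tree: DecisionTree
    index: np.ndarray        # +1/-1 per gene, in decreasing-expression order
    threshold: ThresholdResult
    gene_ids_sorted: list[str]
    expr_sorted: np.ndarray  # mean log2 expression, same order
    labels: np.ndarray       # bool active, aligned to the ORIGINAL fm row order
    order: np.ndarray        # fm row index of each rank

    @property
    def labels_sorted(self) -> np.ndarray:
        return self.threshold.labels


def derive_threshold(
    fm: RegionFeatureMatrix,
    expr: ExpressionTable,
    k: int = 5,
    extreme_fraction: float = 1 / 6,
    method: str = "cumulative",
    min_leaf: int = 1,
) -> PipelineResult:
    """Train a tree on the expression extremes and threshold all genes.

    ``extreme_fraction`` of the genes with highest mean expression are the
    training "active" class and the same number from the bottom the
    "inactive" class (default one sixth per side, the conservative choice
    for the fraction of genes expressed in a single cell type).
    """
    if not 0.0 < extreme_fraction <= 0.5:
        raise ValueError("extreme_fraction must be in (0, 0.5]")
    if set(fm.gene_ids) != set(expr.gene_ids):
        raise ValueError("feature matrix and expression cover different genes")
    row_of = {g: i for i, g in enumerate(fm.gene_ids)}
    mean = expr.mean_expression()
    n = expr.n_genes
    rank_order = sorted(range(n), key=lambda i: (-mean[i], expr.gene_ids[i]))
    gene_ids_sorted = [expr.gene_ids[i] for i in rank_order]
    expr_sorted = mean[rank_order]
    fm_rows = np.array([row_of[g] for g in gene_ids_sorted])
    X_sorted = fm.values[fm_rows]

    m = max(1, int(round(extreme_fraction * n)))
    train_rows = np.concatenate([np.arange(m), np.arange(n - m, n)])
    y_train = np.concatenate([np.ones(m, bool), np.zeros(m, bool)])
    logger.info("training %d-node tree on %d+%d expression-extreme genes", k, m, m)
    tree = grow_tree(
        X_sorted[train_rows], y_train, k, min_leaf=min_leaf, feature_labels=fm.feature_labels
    )
    idx = assign_index(tree, X_sorted)
    if method == "cumulative":
        res = cumulative_threshold(idx, expr_sorted)
    elif method == "pvalue":
        res = pvalue_threshold(idx, expr_sorted)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    logger.info(
        "threshold: g_max=%d Y_max=%d log2=%.3f (%d active)",
        res.g_max, res.y_max, res.threshold_log2, res.n_active,
    )
    labels = np.zeros(n, dtype=bool)
    labels[fm_rows[res.labels]] = True
    return PipelineResult(tree, idx, res, gene_ids_sorted, expr_sorted, labels, fm_rows)


def load_inputs(
    signals_path,
    annotation_path,
    expression_paths,
    bin_size: int = 200,
    count_threshold: int = 0,
):
    """Read the three input files and build the gene-region feature matrix.

    Returns ``(genes, feature_matrix, expression)`` restricted to genes
    present in both the annotation and the expression table.
    """
    genes = read_annotation(annotation_path)
    records = read_signal_table(signals_path, bin_size=bin_size)
    expr = read_expression(expression_paths)
    keep = set(expr.gene_ids)
    genes = [g for g in genes if g.gene_id in keep]
    if not genes:
        raise ValueError("annotation and expression share no genes")
    have = {g.gene_id for g in genes}
    rows = [i for i, g in enumerate(expr.gene_ids) if g in have]
    expr = ExpressionTable(
        [expr.gene_ids[i] for i in rows], expr.sample_ids, expr.values[rows]
    )
    bsm = binarize(records, threshold=count_threshold, bin_size=bin_size)
    fm = build_feature_matrix(bsm, genes)
    return genes, fm, expr
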