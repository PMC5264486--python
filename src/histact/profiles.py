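"""Expression-ranked gene groups and modification occurrence-frequency profiles.

Genes are sorted by decreasing mean log2 expression and cut into G
contiguous groups (default G = 19) of near-equal size.  For a chosen
(modification, region) feature the occurrence frequency of group g is

    F_g = N_g / N_all,

where N_g counts genes in group g carrying the mark and N_all sums N_g over
all groups.  Under no association every F_g sits near the uniform value
1/G; the "transition point" is the group where a set of profiles jointly
comes closest to that uniform value, operationalized as the argmin over
groups of the mean absolute deviation from 1/G.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionTable
from .regions import RegionFeatureMatrix

__all__ = [
    "GenePartition",
    "FreqProfile",
    "partition_genes",
    "occurrence_frequency",
    "transition_point",
    "profiles_frame",
    "write_profiles_report",
    "plot_profiles",
]


@dataclass
class GenePartition:
    """Genes ordered by decreasing mean expression, cut into G groups.

    The first ``n mod G`` groups take the ceiling size, the rest the floor,
    so sizes differ by at most one and sum to n.
    """

    gene_ids: list[str]
    group_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.group_sizes = np.asarray(self.group_sizes, dtype=np.int64)
        if self.group_sizes.sum() != len(self.gene_ids):
            raise ValueError("group sizes must sum to the number of genes")
        if self.group_sizes.max() - self.group_sizes.min() > 1:
            raise ValueError("group sizes must differ by at most 1")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    def group_slices(self) -> list[slice]:
        bounds = np.concatenate([[0], np.cumsum(self.group_sizes)])
        return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]

    def group_of_rank(self, rank: int) -> int:
        """1-based group index of the gene at 1-based rank ``rank``."""
        bounds = np.cumsum(self.group_sizes)
        return int(np.searchsorted(bounds, rank, side="left")) + 1


@dataclass
class FreqProfile:
    """Per-group occurrence counts and frequencies of one (mark, region)."""

    modification: str
    region: str
    counts: np.ndarray
    n_all: int
    frequencies: np.ndarray | None

    @property
    def defined(self) -> bool:
        return self.frequencies is not None


def partition_genes(expr: ExpressionTable, G: int = 19) -> GenePartition:
    """Sort genes by decreasing mean expression (ties broken by gene id)
    and cut into G contiguous rank groups."""
    if G < 2:
        raise ValueError("G must be >= 2")
    n = expr.n_genes
    if n < G:
        raise ValueError(f"need at least G={G} genes, got {n}")
    mean = expr.mean_expression()
    order = sorted(range(n), key=lambda i: (-mean[i], expr.gene_ids[i]))
    q, r = divmod(n, G)
    sizes = np.array([q + 1] * r + [q] * (G - r), dtype=np.int64)
    return GenePartition([expr.gene_ids[i] for i in order], sizes)


def occurrence_frequency(
    fm: RegionFeatureMatrix,
    part: GenePartition,
    modification: str,
    region: str,
) -> FreqProfile:
    """Compute the F_g = N_g / N_all profile of one feature over a partition.

    If the mark never occurs (N_all = 0) the profile is returned with
    ``frequencies=None`` (flagged undefined) rather than dividing by zero.
    """
    col = fm.feature_index(region, modification)
    row_of = {g: i for i, g in enumerate(fm.gene_ids)}
    try:
        rows = [row_of[g] for g in part.gene_ids]
    except KeyError as e:
        raise KeyError(f"partition gene {e.args[0]!r} absent from feature matrix") from None
    vals = fm.values[rows, col]
    counts = np.array([int(vals[s].sum()) for s in part.group_slices()], dtype=np.int64)
    n_all = int(counts.sum())
    freqs = counts / n_all if n_all > 0 else None
    return FreqProfile(modification, region, counts, n_all, freqs)


def transition_point(profiles: Sequence[FreqProfile]) -> int:
    """1-based group index where the profiles jointly come closest to 1/G.

    Minimizes the mean absolute deviation of {F_g across profiles} from the
    uniform frequency; ties break to the smaller group index.
    """
    defined = [p for p in profiles if p.defined]
    if len(defined) < 2:
        raise ValueError("need at least 2 defined profiles")
    G = len(defined[0].counts)
    if any(len(p.counts) != G for p in defined):
        raise ValueError("profiles computed over different partitions")
    F = np.stack([p.frequencies for p in defined])
    dev = np.mean(np.abs(F - 1.0 / G), axis=0)
    return int(np.argmin(dev)) + 1


def profiles_frame(profiles: Sequence[FreqProfile]) -> pd.DataFrame:
    """One row per (modification, region, group) with N_g and F_g."""
    rows = []
    for p in profiles:
        for g, c in enumerate(p.counts, start=1):
            f = float(p.frequencies[g - 1]) if p.defined else np.nan
            rows.append((p.modification, p.region, g, int(c), f))
    return pd.DataFrame(rows, columns=["modification", "region", "group", "N_g", "F_g"])


def write_profiles_report(profiles: Sequence[FreqProfile], path) -> None:
    profiles_frame(profiles).to_csv(path, sep="\t", index=False, float_format="%.6g")


def plot_profiles(profiles: Sequence[FreqProfile], path=None, ax=None):
    """Line plot of F_g per group for each profile, with the 1/G reference."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    G = len(profiles[0].counts)
    x = np.arange(1, G + 1)
    for p in profiles:
        if p.defined:
            ax.plot(x, p.frequencies, label=f"{p.modification}@{p.region}", lw=1.2)
    ax.axhline(1.0 / G, color="grey", ls="--", lw=0.8, label=f"uniform 1/{G}")
    ax.set_xlabel("expression group (1 = highest expression)")
    ax.set_ylabel("occurrence frequency $F_g$")
    ax.legend(fontsize=7, ncol=2)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
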