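"""Genome-bin and gene-region feature construction.

Two binary matrices drive the whole analysis:

* the bin signal matrix ("MATRIX 1"): genomic 200-bp bins x histone
  modifications, entries 1 where the ChIP tag count exceeds a threshold
  (default 0, i.e. simple presence/absence);
* the region feature matrix ("MATRIX 2"): genes x (region, modification)
  pairs over a fixed layout of 24 nucleosome-sized gene regions anchored at
  the TSS and TTS — 10 bins upstream of the TSS (TSS-10 .. TSS-1), the TSS
  bin, 2 bins downstream (TSS+1, TSS+2), the TTS bin, and 10 bins past the
  TTS (TTS+1 .. TTS+10).

Upstream/downstream are strand-aware: for a minus-strand gene "upstream of
TSS" means higher genomic coordinates.  Regions that fall before the start
of the chromosome are encoded as 0 with a mask bit set, so the gene universe
stays aligned across pipeline stages.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneAnnotation, SignalRecord

__all__ = [
    "RegionLayout",
    "BinSignalMatrix",
    "RegionFeatureMatrix",
    "default_layout",
    "binarize",
    "gene_regions",
    "build_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

_DEFAULT_LABELS = tuple(
    [f"TSS-{k}" for k in range(10, 0, -1)]
    + ["TSS", "TSS+1", "TSS+2", "TTS"]
    + [f"TTS+{k}" for k in range(1, 11)]
)

_LABEL_RE = re.compile(r"^(TSS|TTS)(?:([+-])(\d+))?$")


@dataclass(frozen=True)
class RegionLayout:
    """Canonical ordered list of the 24 gene-region labels."""

    labels: tuple[str, ...] = _DEFAULT_LABELS

    def __post_init__(self) -> None:
        if len(self.labels) != 24:
            raise ValueError(f"layout must have exactly 24 regions, got {len(self.labels)}")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate region labels")
        for lab in self.labels:
            if _LABEL_RE.match(lab) is None:
                raise ValueError(f"unparseable region label {lab!r}")

    def anchors_offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Per label: whether anchored at TSS (vs TTS), and the signed bin
        offset in the direction of transcription."""
        is_tss = np.zeros(len(self.labels), dtype=bool)
        offset = np.zeros(len(self.labels), dtype=np.int64)
        for i, lab in enumerate(self.labels):
            m = _LABEL_RE.match(lab)
            assert m is not None
            is_tss[i] = m.group(1) == "TSS"
            if m.group(2) is not None:
                offset[i] = int(m.group(3)) * (1 if m.group(2) == "+" else -1)
        return is_tss, offset


def default_layout() -> RegionLayout:
    return RegionLayout()


@dataclass
class BinSignalMatrix:
    """Binary bins x modifications matrix, stored densely per chromosome.

    ``data[chrom]`` is a (n_bins, n_modifications) uint8 array; bins beyond
    the stored extent implicitly hold 0.
    """

    modifications: list[str]
    data: dict[str, np.ndarray]
    bin_size: int = 200

    def __post_init__(self) -> None:
        self.modifications = list(self.modifications)
        self._mod_index = {m: i for i, m in enumerate(self.modifications)}
        for chrom, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[1] != len(self.modifications):
                raise ValueError(f"chromosome {chrom!r}: bad array shape {arr.shape}")

    def value(self, chrom: str, bin_index: int, modification: str) -> int:
        """0/1 status of one cell; absent chromosomes/bins are 0."""
        arr = self.data.get(chrom)
        j = self._mod_index.get(modification)
        if j is None:
            raise KeyError(f"unknown modification {modification!r}")
        if arr is None or bin_index < 0 or bin_index >= arr.shape[0]:
            return 0
        return int(arr[bin_index, j])


def binarize(
    records: Sequence[SignalRecord],
    threshold: int = 0,
    bin_size: int = 200,
    modifications: Sequence[str] | None = None,
) -> BinSignalMatrix:
    """Collapse tag counts to presence/absence: entry 1 iff count > threshold.

    The default ``threshold=0`` keeps any nonzero signal, so occasional very
    large counts carry no extra weight.  Pass ``modifications`` to fix the
    column universe when the record set may not mention every mark.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if modifications is None:
        mods = sorted({r.modification for r in records})
    else:
        mods = sorted(modifications)
    mod_index = {m: i for i, m in enumerate(mods)}
    data: dict[str, np.ndarray] = {}
    if not records:
        return BinSignalMatrix(mods, data, bin_size)
    df = pd.DataFrame(records, columns=["chrom", "bin_start", "modification", "count"])
    if (df["count"] < 0).any():
        raise ValueError("negative tag count in signal records")
    if (df["bin_start"] % bin_size != 0).any():
        raise ValueError(f"bin_start not a multiple of bin_size={bin_size}")
    try:
        codes = df["modification"].map(mod_index).to_numpy()
    except KeyError:  # pragma: no cover - map yields NaN instead
        raise
    if pd.isna(codes).any():
        unknown = df["modification"][pd.isna(codes)].iloc[0]
        raise KeyError(f"modification {unknown!r} not in declared universe")
    codes = codes.astype(np.int64)
    present = (df["count"] > threshold).to_numpy()
    bins = df["bin_start"].to_numpy() // bin_size
    for chrom, rows in df.groupby("chrom", sort=True).groups.items():
        rows = np.asarray(rows)
        b = bins[rows]
        arr = np.zeros((int(b.max()) + 1, len(mods)), dtype=np.uint8)
        keep = present[rows]
        arr[b[keep], codes[rows][keep]] = 1
        data[str(chrom)] = arr
    return BinSignalMatrix(mods, data, bin_size)


def gene_regions(
    gene: GeneAnnotation,
    layout: RegionLayout | None = None,
    bin_size: int = 200,
) -> list[tuple[str, str, int | None]]:
    """Map a gene to its 24 region bins.

    Offsets are applied in the direction of transcription, so for a
    minus-strand gene TSS-1 lies at a higher genomic coordinate than the
    TSS bin.  Bins falling before the chromosome start are returned as
    ``None`` (missing).
    """
    layout = layout or default_layout()
    is_tss, offset = layout.anchors_offsets()
    sign = 1 if gene.strand == "+" else -1
    tss_bin = gene.tss // bin_size
    tts_bin = gene.tts // bin_size
    out: list[tuple[str, str, int | None]] = []
    for lab, t, o in zip(layout.labels, is_tss, offset):
        b = (tss_bin if t else tts_bin) + sign * int(o)
        out.append((lab, gene.chrom, int(b) if b >= 0 else None))
    return out


def _region_bins(
    genes: Sequence[GeneAnnotation], layout: RegionLayout, bin_size: int
) -> np.ndarray:
    """(n_genes, 24) array of region bin indices; off-chromosome bins < 0."""
    is_tss, offset = layout.anchors_offsets()
    tssb = np.array([g.tss // bin_size for g in genes], dtype=np.int64)
    ttsb = np.array([g.tts // bin_size for g in genes], dtype=np.int64)
    sign = np.array([1 if g.strand == "+" else -1 for g in genes], dtype=np.int64)
    anchor = np.where(is_tss[None, :], tssb[:, None], ttsb[:, None])
    return anchor + sign[:, None] * offset[None, :]


@dataclass
class RegionFeatureMatrix:
    """Genes x (region, modification) binary feature matrix ("MATRIX 2").

    Feature order is canonical: regions in layout order, modifications
    alphabetical within each region.  ``mask`` marks features whose region
    bin fell off the chromosome (value forced to 0).
    """

    gene_ids: list[str]
    regions: tuple[str, ...]
    modifications: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.regions = tuple(self.regions)
        self.modifications = list(self.modifications)
        if self.modifications != sorted(self.modifications):
            raise ValueError("modifications must be alphabetically sorted")
        n, f = len(self.gene_ids), len(self.regions) * len(self.modifications)
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != (n, f) or self.mask.shape != (n, f):
            raise ValueError("values/mask shape mismatch")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("feature values must be 0 or 1")

    @cached_property
    def feature_labels(self) -> list[str]:
        return [f"{r}:{m}" for r in self.regions for m in self.modifications]

    @property
    def n_features(self) -> int:
        return len(self.regions) * len(self.modifications)

    def feature_index(self, region: str, modification: str) -> int:
        try:
            ri = self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}") from None
        try:
            mi = self.modifications.index(modification)
        except ValueError:
            raise KeyError(f"unknown modification {modification!r}") from None
        return ri * len(self.modifications) + mi

    def region_columns(self, region: str) -> np.ndarray:
        if region not in self.regions:
            raise KeyError(f"unknown region {region!r}")
        ri = self.regions.index(region)
        m = len(self.modifications)
        return np.arange(ri * m, (ri + 1) * m)

    def modification_columns(self, modification: str) -> np.ndarray:
        if modification not in self.modifications:
            raise KeyError(f"unknown modification {modification!r}")
        mi = self.modifications.index(modification)
        m = len(self.modifications)
        return np.arange(len(self.regions)) * m + mi

    def to_frame(self) -> pd.DataFrame:
        """String-valued frame; masked entries become 'NA'."""
        out = self.values.astype(str).astype(object)
        out[self.mask] = "NA"
        return pd.DataFrame(out, index=self.gene_ids, columns=self.feature_labels)


def build_feature_matrix(
    bsm: BinSignalMatrix,
    genes: Sequence[GeneAnnotation],
    layout: RegionLayout | None = None,
    modifications: Sequence[str] | None = None,
) -> RegionFeatureMatrix:
    """Assemble MATRIX 2 by looking up each gene's 24 region bins in MATRIX 1.

    Genes on chromosomes absent from the signal matrix get an all-zero,
    fully masked row (with a warning) rather than being dropped.
    """
    layout = layout or default_layout()
    mods = sorted(modifications) if modifications is not None else sorted(bsm.modifications)
    if not mods:
        raise ValueError("modification list must be non-empty")
    n, nr, nm = len(genes), len(layout.labels), len(mods)
    bins = _region_bins(genes, layout, bsm.bin_size)
    region_mask = bins < 0
    vals = np.zeros((n, nr, nm), dtype=np.uint8)
    src = np.array([bsm.modifications.index(m) if m in bsm.modifications else -1 for m in mods])
    have = np.flatnonzero(src >= 0)
    chroms = np.array([g.chrom for g in genes])
    for chrom in np.unique(chroms):
        rows = np.flatnonzero(chroms == chrom)
        arr = bsm.data.get(str(chrom))
        if arr is None:
            warnings.warn(f"chromosome {chrom!r} absent from signal matrix; genes masked")
            region_mask[rows] = True
            continue
        b = bins[rows]
        valid = (b >= 0) & (b < arr.shape[0])
        bc = np.clip(b, 0, arr.shape[0] - 1)
        sub = arr[bc]  # (n_rows, 24, n_bsm_mods)
        sub[~valid] = 0
        full = np.zeros((len(rows), nr, nm), dtype=np.uint8)
        if have.size:
            full[:, :, have] = sub[:, :, src[have]]
        vals[rows] = full
    values = vals.reshape(n, nr * nm)
    mask = np.repeat(region_mask, nm, axis=1)
    values = np.where(mask, 0, values).astype(np.uint8)
    return RegionFeatureMatrix([g.gene_id for g in genes], layout.labels, mods, values, mask)


def write_feature_matrix(fm: RegionFeatureMatrix, path) -> None:
    df = fm.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_feature_matrix(path) -> RegionFeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    labels = list(df.columns)
    pairs = []
    for lab in labels:
        if ":" not in lab:
            raise ValueError(f"{path}: feature label {lab!r} is not 'REGION:MOD'")
        r, m = lab.split(":", 1)
        pairs.append((r, m))
    regions = tuple(dict.fromkeys(r for r, _ in pairs))
    mods = sorted({m for _, m in pairs})
    want = [f"{r}:{m}" for r in regions for m in mods]
    if set(want) != set(labels):
        raise ValueError(f"{path}: feature labels do not form a region x modification grid")
    df = df[want]
    raw = df.to_numpy()
    mask = raw == "NA"
    values = np.where(mask, "0", raw).astype(np.uint8)
    return RegionFeatureMatrix(list(df.index.astype(str)), regions, mods, values, mask)
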