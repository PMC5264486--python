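"""Readers and writers for the pipeline's external tabular formats.

All tables are tab-separated with a header line.  Genomic coordinates are
0-based, half-open; genomic bins are fixed 200-bp (configurable) windows
anchored at position 0 of each chromosome, so the bin holding position ``p``
is ``p // bin_size``.  Expression values are assumed to already be on a
log2 scale (the RMA output convention); nothing in the pipeline
re-transforms them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "GeneAnnotation",
    "ExpressionTable",
    "read_signal_table",
    "write_signal_table",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
]


class SignalRecord(NamedTuple):
    """One ChIP tag count for a (chromosome, bin, modification) cell.

    ``bin_start`` is the 0-based bp coordinate of the left edge of the bin
    and must be a non-negative multiple of the bin size.
    """

    chrom: str
    bin_start: int
    modification: str
    count: int


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's chromosome, strand and TSS/TTS anchor coordinates.

    For a plus-strand gene the TSS precedes the TTS (``tss < tts``); for a
    minus-strand gene the order is reversed (``tss > tts``).
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss == self.tts:
            raise ValueError(f"gene {self.gene_id!r}: tss == tts ({self.tss})")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id!r}: '+' strand requires tss < tts")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id!r}: '-' strand requires tss > tts")
        if min(self.tss, self.tts) < 0:
            raise ValueError(f"gene {self.gene_id!r}: negative coordinate")


@dataclass
class ExpressionTable:
    """Genes x samples matrix of log2-scale normalized expression values."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression table")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def mean_expression(self) -> np.ndarray:
        """Arithmetic mean across samples (log2 scale), one value per gene."""
        return self.values.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionTable":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())


def _first_bad_line(mask: pd.Series) -> int:
    # +2: one for the header line, one for 0- vs 1-based numbering
    return int(np.flatnonzero(mask.to_numpy())[0]) + 2


def _integer_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    num = pd.to_numeric(df[col], errors="coerce")
    bad = num.isna() | (num != num.round())
    if bad.any():
        raise ValueError(
            f"{path}: malformed integer in column {col!r} at line {_first_bad_line(bad)}"
        )
    return num.to_numpy(dtype=np.int64)


def read_signal_table(path, bin_size: int = 200) -> list[SignalRecord]:
    """Read a per-bin signal table (columns chrom, bin_start, modification, count).

    Unknown columns are ignored.  Rows violating the record invariants
    (negative counts, bin starts that are not multiples of ``bin_size``)
    raise a :class:`ValueError` naming the offending line.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "bin_start", "modification", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    blank = df["chrom"].isna() | df["modification"].isna()
    if blank.any():
        raise ValueError(f"{path}: malformed row at line {_first_bad_line(blank)}")
    bin_start = _integer_column(df, "bin_start", path)
    count = _integer_column(df, "count", path)
    neg = pd.Series(count < 0)
    if neg.any():
        raise ValueError(f"{path}: negative count at line {_first_bad_line(neg)}")
    if (bin_start < 0).any():
        raise ValueError(
            f"{path}: negative bin_start at line {_first_bad_line(pd.Series(bin_start < 0))}"
        )
    offgrid = pd.Series(bin_start % bin_size != 0)
    if offgrid.any():
        raise ValueError(
            f"{path}: bin_start not a multiple of bin_size={bin_size} "
            f"at line {_first_bad_line(offgrid)}"
        )
    chroms = df["chrom"].tolist()
    mods = df["modification"].tolist()
    return [
        SignalRecord(c, int(b), m, int(n))
        for c, b, m, n in zip(chroms, bin_start, mods, count)
    ]


def write_signal_table(records: Sequence[SignalRecord], path) -> None:
    df = pd.DataFrame(records, columns=["chrom", "bin_start", "modification", "count"])
    df.to_csv(path, sep="\t", index=False)


_ANNOT_COLS = ["gene_id", "chrom", "strand", "tss", "tts"]


def read_annotation(path) -> list[GeneAnnotation]:
    """Read gene annotation from a headered TSV or a BED6-like file.

    The TSV form has columns ``gene_id chrom strand tss tts``.  A headerless
    6-column BED-like file (``chrom start end name score strand``) is also
    accepted: the TSS is taken at ``start`` for plus-strand and ``end`` for
    minus-strand genes.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "gene_id" in first.split():
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = [c for c in _ANNOT_COLS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing annotation columns {missing}")
    else:
        bed = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if bed.shape[1] < 6:
            raise ValueError(f"{path}: BED-like annotation needs 6 columns")
        bed = bed.iloc[:, :6]
        bed.columns = ["chrom", "start", "end", "name", "score", "strand"]
        plus = bed["strand"] == "+"
        df = pd.DataFrame(
            {
                "gene_id": bed["name"],
                "chrom": bed["chrom"],
                "strand": bed["strand"],
                "tss": np.where(plus, bed["start"], bed["end"]),
                "tts": np.where(plus, bed["end"], bed["start"]),
            }
        )
    tss = _integer_column(df, "tss", path)
    tts = _integer_column(df, "tts", path)
    dup = df["gene_id"].duplicated()
    if dup.any():
        which = df["gene_id"][dup].iloc[0]
        raise ValueError(f"{path}: duplicate gene id {which!r}")
    genes = [
        GeneAnnotation(str(g), str(c), str(s), int(a), int(b))
        for g, c, s, a, b in zip(df["gene_id"], df["chrom"], df["strand"], tss, tts)
    ]
    return genes


def write_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.strand, g.tss, g.tts) for g in genes],
        columns=_ANNOT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression(paths) -> ExpressionTable:
    """Read and column-concatenate one or more gene x sample TSV files.

    Each file must have a ``gene_id`` column followed by numeric sample
    columns.  The result covers the intersection of gene ids across files,
    in the row order of the first file.  Duplicate sample names across files
    are disambiguated with a numeric suffix.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if not paths:
        raise ValueError("no expression files given")
    frames = []
    for p in paths:
        df = pd.read_csv(p, sep="\t", dtype={0: str})
        if "gene_id" not in df.columns:
            raise ValueError(f"{p}: expression file must have a 'gene_id' column")
        if df["gene_id"].duplicated().any():
            raise ValueError(f"{p}: duplicate gene id in expression file")
        frames.append(df.set_index("gene_id"))
    shared = [g for g in frames[0].index if all(g in f.index for f in frames[1:])]
    if not shared:
        raise ValueError("expression files share no gene ids")
    seen: dict[str, int] = {}
    cols: list[np.ndarray] = []
    names: list[str] = []
    for f in frames:
        sub = f.loc[shared]
        for c in sub.columns:
            vals = pd.to_numeric(sub[c], errors="raise").to_numpy(dtype=float)
            name = str(c)
            if name in seen:
                seen[name] += 1
                warnings.warn(f"duplicate sample id {name!r}; renamed")
                name = f"{name}.{seen[str(c)]}"
            else:
                seen[name] = 1
            names.append(name)
            cols.append(vals)
    return ExpressionTable(shared, names, np.column_stack(cols))


def write_expression(table: ExpressionTable, path) -> None:
    df = table.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
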