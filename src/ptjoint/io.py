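"""Readers and writers for the on-disk formats the pipeline touches.

Every genomic coordinate in this package is 0-based half-open (BED
convention): a fragment ``[start, end)`` covers bases ``start .. end-1``.
Writers never emit 1-based coordinates.

Formats
-------
fragments TSV
    five columns ``chrom  start  end  barcode  count`` (10x fragments-file
    dialect), optionally gzip/bgzip compressed; ``#`` lines are comments.
count matrix
    MatrixMarket coordinate file plus one-entry-per-line barcode and
    feature files (``mmread``/``mmwrite`` under the hood).
BED
    BED3/BED4 intervals; an optional fifth column carries a summit offset
    relative to ``start`` (narrowPeak-style).
gene annotation TSV
    ``gene_id  chrom  strand  body_start  body_end``; the TSS is derived
    from the strand (5' end of the body).
labels TSV
    ``barcode  label``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

FRAGMENT_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


class FormatError(ValueError):
    """A file violates the format contract (bad coordinates, bad labels...)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with an optional summit."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise FormatError(
                f"summit {self.summit} outside interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneRecord:
    """A minimal gene model: id, span, strand and the derived TSS."""

    gene_id: str
    chrom: str
    strand: str
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be + or -")
        if self.body_start >= self.body_end:
            raise FormatError(f"gene {self.gene_id}: body_start >= body_end")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end: body_start for +, body_end - 1 for -."""
        return self.body_start if self.strand == "+" else self.body_end - 1


@dataclass
class FragmentSet:
    """Barcoded genomic fragments for one histone modality.

    ``data`` holds one row per record with columns chrom/start/end/barcode/
    count.  ``deduplicated`` is True once :func:`deduplicate` has collapsed
    duplicate (chrom, start, end, barcode) records.
    """

    data: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    deduplicated: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"fragment table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def barcodes(self) -> np.ndarray:
        return self.data["barcode"].unique()

    def subset_barcodes(self, barcodes: Iterable[str]) -> "FragmentSet":
        keep = self.data["barcode"].isin(set(barcodes))
        return FragmentSet(
            self.data.loc[keep].reset_index(drop=True),
            dict(self.chrom_sizes),
            self.deduplicated,
        )


@dataclass
class CountMatrix:
    """Sparse cells x features count matrix with unique labels."""

    values: sp.csr_matrix
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match labels "
                f"({len(self.row_labels)}, {len(self.col_labels)})"
            )
        if len(set(self.row_labels)) != len(self.row_labels):
            raise FormatError("duplicate row labels")
        if len(set(self.col_labels)) != len(self.col_labels):
            raise FormatError("duplicate column labels")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("count matrix has negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.toarray(), index=self.row_labels, columns=self.col_labels
        )


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def read_fragments(
    path: str | Path,
    chrom_sizes: Mapping[str, int],
    strict: bool = False,
) -> FragmentSet:
    """Read a 10x-style fragments TSV (plain or gzip/bgzip).

    Records outside ``chrom_sizes`` bounds are dropped with a warning, or
    raise when ``strict`` is set.  Malformed lines raise :class:`FormatError`
    naming the offending 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=FRAGMENT_COLUMNS,
            dtype={"chrom": str, "barcode": str},
        )
    except (ValueError, pd.errors.ParserError):
        _locate_bad_fragment_line(path)
        raise
    if df.empty:
        return FragmentSet(
            pd.DataFrame(columns=FRAGMENT_COLUMNS), dict(chrom_sizes), False
        )
    for col in ("start", "end", "count"):
        if not np.issubdtype(df[col].dtype, np.integer):
            _locate_bad_fragment_line(path)
            raise FormatError(f"{path}: non-integer values in column '{col}'")
    bad = (df["start"] >= df["end"]) | (df["count"] < 1)
    if bad.any():
        _locate_bad_fragment_line(path)
        raise FormatError(f"{path}: invalid fragment record")
    sizes = pd.Series(dict(chrom_sizes))
    known = df["chrom"].isin(sizes.index)
    within = known.copy()
    within[known] = (
        df.loc[known, "end"].to_numpy()
        <= sizes[df.loc[known, "chrom"]].to_numpy()
    ) & (df.loc[known, "start"].to_numpy() >= 0)
    if not within.all():
        n_bad = int((~within).sum())
        if strict:
            raise FormatError(
                f"{path}: {n_bad} fragments outside chrom_sizes bounds"
            )
        logger.warning("%s: dropped %d out-of-bounds fragments", path, n_bad)
        df = df.loc[within].reset_index(drop=True)
    return FragmentSet(df, dict(chrom_sizes), False)


def _locate_bad_fragment_line(path: Path) -> None:
    """Scan a fragments file line-by-line to name the first bad line."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:  # type: ignore[operator]
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected >=5 columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinate or count"
                ) from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            if count < 1:
                raise FormatError(f"{path}:{lineno}: count < 1")


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    """Write a fragments TSV (plain text, canonical format)."""
    frags.data.to_csv(path, sep="\t", header=False, index=False)


def deduplicate(frags: FragmentSet) -> FragmentSet:
    """Collapse duplicate (chrom, start, end, barcode) records.

    Duplicate removal is barcode-aware: identical coordinates from two
    different cells are two distinct molecules and are both kept.  Counts
    collapse to 1; output is sorted by (chrom, start, end, barcode).
    """
    df = (
        frags.data.drop_duplicates(subset=["chrom", "start", "end", "barcode"])
        .sort_values(["chrom", "start", "end", "barcode"], kind="mergesort")
        .reset_index(drop=True)
    )
    df = df.assign(count=1)
    return FragmentSet(df, dict(frags.chrom_sizes), True)


# ---------------------------------------------------------------------------
# count matrices (MTX trio)
# ---------------------------------------------------------------------------

def read_count_matrix(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> CountMatrix:
    mat = sp.csr_matrix(scipy.io.mmread(mtx_path))
    barcodes = _read_lines(barcodes_path)
    features = _read_lines(features_path)
    if mat.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"MTX shape {mat.shape} does not match {len(barcodes)} barcodes "
            f"x {len(features)} features"
        )
    return CountMatrix(mat, barcodes, features)


def write_count_matrix(
    matrix: CountMatrix,
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(matrix.values))
    _write_lines(barcodes_path, matrix.row_labels)
    _write_lines(features_path, matrix.col_labels)


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _write_lines(path: str | Path, lines: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(f"{line}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 (+ optional summit-offset fifth column)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            summit = None
            if len(parts) > 4 and parts[4] not in (".", "", "-1"):
                summit = start + int(parts[4])
            out.append(GenomicInterval(parts[0], start, end, name, summit))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    any_summit = any(iv.summit is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or any_summit:
                cols.append(iv.name if iv.name is not None else ".")
            if any_summit:
                cols.append(
                    str(iv.summit - iv.start) if iv.summit is not None else "."
                )
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | Path) -> list[GeneRecord]:
    """Read the minimal gene annotation TSV.

    Columns: gene_id, chrom, strand, body_start, body_end (0-based
    half-open).  A header line starting with 'gene_id' is tolerated.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "gene_id":
                continue
            if len(parts) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            try:
                body_start, body_end = int(parts[3]), int(parts[4])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer gene span"
                ) from None
            try:
                genes.append(
                    GeneRecord(parts[0], parts[1], parts[2], body_start, body_end)
                )
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tbody_start\tbody_end\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.body_start}\t{g.body_end}\n"
            )


# ---------------------------------------------------------------------------
# cluster labels
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, str]:
    """Read a barcode -> cluster-label TSV; duplicate barcodes are an error."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if parts[0] in labels:
                raise FormatError(
                    f"{path}:{lineno}: duplicate barcode '{parts[0]}'"
                )
            labels[parts[0]] = parts[1]
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for barcode, label in labels.items():
            fh.write(f"{barcode}\t{label}\n")
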