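"""Readers and writers for the external formats the pipeline touches.

The dialects matter here: SpaceRanger's ``tissue_positions_list.csv`` comes
both headerless (older SpaceRanger) and headered, 10x count matrices are
MatrixMarket triplets with sidecar gene/barcode lists, ImageJ exports affine
matrices as JSON, and MGI-style homology tables are tab-separated with a
homology-group key. Everything round-trips and nothing reorders observations
relative to file order.

Axis convention: pixel coordinates are (row, col) = (y, x), matching the
``pxl_row_in_fullres`` / ``pxl_col_in_fullres`` column names.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "SpotPositionRecord",
    "AffineTransform2D",
    "HomologRecord",
    "BedInterval",
    "CountsMatrix",
    "FormatError",
    "read_counts_triplet",
    "write_counts_triplet",
    "read_spot_positions",
    "write_spot_positions",
    "read_affine_json",
    "read_homolog_table",
    "write_bed",
]

#: native Visium capture-area bounds (inclusive)
NATIVE_ARRAY_ROW_MAX = 77
NATIVE_ARRAY_COL_MAX = 127

POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


@dataclass
class SpotPositionRecord:
    """One row of a tissue-positions table.

    ``array_row``/``array_col`` index the hexagonal capture grid (0..77 and
    0..127 on a native area; unbounded above after stitching); the pixel
    fields locate the spot centre on the full-resolution image.
    """

    barcode: str
    in_tissue: int
    array_row: int
    array_col: int
    pxl_row_in_fullres: float
    pxl_col_in_fullres: float


@dataclass
class AffineTransform2D:
    """2x3 affine matrix in pixel units (rotation/scale block | translation)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise FormatError(f"affine matrix must be 2x3, got {m.shape}")
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise FormatError("affine rotation block is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    @property
    def is_rigid(self) -> bool:
        return abs(abs(np.linalg.det(self.matrix[:, :2])) - 1.0) <= 1e-6


@dataclass(frozen=True)
class HomologRecord:
    source_symbol: str
    target_symbol: str
    source_taxon: str
    target_taxon: str


@dataclass(frozen=True)
class BedInterval:
    """0-based half-open genomic interval named after a gene."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for {self.name}: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.name}")


@dataclass
class CountsMatrix:
    """Sparse genes x observations count matrix with string identifiers."""

    matrix: sp.csr_matrix
    genes: list[str]
    barcodes: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def _read_lines(path: Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_counts_triplet(matrix_path, genes_path, barcodes_path) -> CountsMatrix:
    """Read a 10x-style MTX triplet (matrix + gene list + barcode list)."""
    matrix_path = Path(matrix_path)
    genes = _read_lines(Path(genes_path))
    barcodes = _read_lines(Path(barcodes_path))
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path}: header declares {mat.shape[0]} rows but "
            f"{genes_path} lists {len(genes)} genes"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path}: header declares {mat.shape[1]} columns but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative counts")
    return CountsMatrix(mat, genes, barcodes)


def write_counts_triplet(counts: CountsMatrix, matrix_path, genes_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.matrix))
    Path(genes_path).write_text("".join(g + "\n" for g in counts.genes))
    Path(barcodes_path).write_text("".join(b + "\n" for b in counts.barcodes))


def read_spot_positions(
    path,
    dialect: str = "headered",
    validate_native: bool = False,
) -> list[SpotPositionRecord]:
    """Read a tissue-positions CSV in either SpaceRanger dialect.

    ``dialect`` is ``"headered"`` or ``"headerless"``; column order is the
    same in both. With ``validate_native`` the native array bounds
    (row 0..77, col 0..127) are enforced.
    """
    if dialect not in ("headered", "headerless"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header = 0 if dialect == "headered" else None
    df = pd.read_csv(path, header=header, names=POSITION_COLUMNS)
    if df.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 columns, found {df.shape[1]}")

    dup = df["barcode"][df["barcode"].duplicated()]
    if len(dup):
        raise FormatError(f"{path}: duplicate barcode(s): {sorted(set(dup))}")

    if validate_native:
        bad_rows = df.index[
            (df["array_row"] < 0)
            | (df["array_row"] > NATIVE_ARRAY_ROW_MAX)
            | (df["array_col"] < 0)
            | (df["array_col"] > NATIVE_ARRAY_COL_MAX)
        ].tolist()
        if bad_rows:
            raise FormatError(
                f"{path}: array coordinates outside native bounds "
                f"[0,{NATIVE_ARRAY_ROW_MAX}]x[0,{NATIVE_ARRAY_COL_MAX}] "
                f"at rows {bad_rows}"
            )
        parity = (df["array_row"] + df["array_col"]) % 2
        if parity.nunique() > 1:
            warnings.warn(
                f"{path}: mixed (array_row + array_col) parity; native "
                "Visium arrays have constant parity",
                stacklevel=2,
            )

    return [
        SpotPositionRecord(
            barcode=str(r.barcode),
            in_tissue=int(r.in_tissue),
            array_row=int(r.array_row),
            array_col=int(r.array_col),
            pxl_row_in_fullres=float(r.pxl_row_in_fullres),
            pxl_col_in_fullres=float(r.pxl_col_in_fullres),
        )
        for r in df.itertuples(index=False)
    ]


def write_spot_positions(records: Sequence[SpotPositionRecord], path, dialect: str = "headered") -> None:
    df = pd.DataFrame(
        [
            (r.barcode, r.in_tissue, r.array_row, r.array_col, r.pxl_row_in_fullres, r.pxl_col_in_fullres)
            for r in records
        ],
        columns=POSITION_COLUMNS,
    )
    df.to_csv(path, index=False, header=(dialect == "headered"))


def read_affine_json(
    path,
    capture_areas: Iterable[str] | None = None,
    allow_missing: bool = False,
) -> dict[str, AffineTransform2D]:
    """Read ImageJ-style affine matrices keyed by capture-area id.

    With ``allow_missing`` and an explicit ``capture_areas`` list, areas
    absent from the file get the identity transform.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: expected a JSON object keyed by capture area")
    out = {area: AffineTransform2D(np.asarray(mat, dtype=float)) for area, mat in raw.items()}
    if capture_areas is not None:
        missing = [a for a in capture_areas if a not in out]
        if missing and not allow_missing:
            raise FormatError(f"{path}: no transform for capture area(s) {missing}")
        for a in missing:
            out[a] = AffineTransform2D.identity()
    return out


def read_homolog_table(path, source_taxon: str, target_taxon: str) -> list[HomologRecord]:
    """Read an MGI ``HOM_AllOrganism.rpt``-style TSV and pair symbols.

    Symbols are joined within each homology group across the two taxa; any
    source or target symbol taking part in more than one pair is dropped so
    only unique one-to-one matches survive.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"DB Class Key", "Common Organism Name", "Symbol"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    pairs: list[tuple[str, str]] = []
    for _, grp in df.groupby("DB Class Key", sort=False):
        src = grp.loc[grp["Common Organism Name"] == source_taxon, "Symbol"].tolist()
        tgt = grp.loc[grp["Common Organism Name"] == target_taxon, "Symbol"].tolist()
        pairs.extend((s, t) for s in src for t in tgt)

    src_counts = pd.Series([p[0] for p in pairs]).value_counts() if pairs else pd.Series(dtype=int)
    tgt_counts = pd.Series([p[1] for p in pairs]).value_counts() if pairs else pd.Series(dtype=int)
    return [
        HomologRecord(s, t, source_taxon, target_taxon)
        for s, t in pairs
        if src_counts[s] == 1 and tgt_counts[t] == 1
    ]


def write_bed(intervals: Sequence[BedInterval], path) -> None:
    """Write sorted 0-based half-open BED (chrom, start, end, name)."""
    rows = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end, iv.name))
    with open(path, "w") as fh:
        for iv in rows:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
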