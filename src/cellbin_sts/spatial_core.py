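"""Grid conventions, domain types and file I/O shared by the whole pipeline.

Coordinate conventions
----------------------
All spatial coordinates are 0-based integer pixel-bin indices with the origin
at the top-left corner of the chip, ``x`` increasing rightward and ``y``
increasing downward.  Arrays are indexed ``[y, x]``.  Distances are expressed
in bin units unless a micrometre conversion is requested explicitly through
:func:`bins_to_um2`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "GridSpec",
    "SpotTable",
    "DensityMap",
    "CellbinMatrix",
    "SPLICE_CLASSES",
    "DENSITY_CHANNELS",
    "SPOT_COLUMNS",
    "is_mito_gene",
    "bins_to_um2",
    "equivalent_circle_radius",
    "equivalent_square_side",
    "read_spot_table",
    "write_spot_table",
    "read_label_map",
    "write_label_map",
    "read_cellbin_matrix",
    "write_cellbin_matrix",
]

SPLICE_CLASSES = ("spliced", "unspliced")
DENSITY_CHANNELS = ("unspliced", "spliced", "total")
SPOT_COLUMNS = ("barcode", "x_bin", "y_bin", "gene", "splice_class", "umi_count")

_MITO_RE = re.compile(r"^mt-", re.IGNORECASE)


def is_mito_gene(gene_id: str) -> bool:
    """True for mitochondrial gene identifiers (``mt-`` prefix, any case)."""
    return bool(_MITO_RE.match(gene_id))


@dataclass(frozen=True)
class GridSpec:
    """Physical layout of the chip pixel-bin grid.

    Parameters
    ----------
    width_bins, height_bins
        Grid extent in bins; valid x indices are ``0..width_bins-1`` and
        valid y indices ``0..height_bins-1``.
    pitch_nm
        Physical edge length of one square pixel bin, in nanometres.
    """

    width_bins: int
    height_bins: int
    pitch_nm: float = 250.0

    def __post_init__(self) -> None:
        if self.pitch_nm <= 0:
            raise ValueError(f"pitch_nm must be positive, got {self.pitch_nm}")
        if self.width_bins < 1 or self.height_bins < 1:
            raise ValueError(
                f"grid extent must be >= 1 bin, got {self.width_bins} x {self.height_bins}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(height_bins, width_bins)``."""
        return (self.height_bins, self.width_bins)

    def contains(self, x_bin: np.ndarray, y_bin: np.ndarray) -> np.ndarray:
        x = np.asarray(x_bin)
        y = np.asarray(y_bin)
        return (x >= 0) & (x < self.width_bins) & (y >= 0) & (y < self.height_bins)


def bins_to_um2(area_bins: float, grid: GridSpec) -> float:
    """Convert an area in pixel bins to square micrometres.

    ``area_bins * (pitch_nm / 1000)**2``; rejects negative input.
    """
    if area_bins < 0:
        raise ValueError(f"area_bins must be non-negative, got {area_bins}")
    return float(area_bins) * (grid.pitch_nm / 1000.0) ** 2


def equivalent_circle_radius(area_bins: float) -> float:
    """Radius (in pixels) of the circle with the given area; rounding is the caller's."""
    if area_bins < 0:
        raise ValueError(f"area_bins must be non-negative, got {area_bins}")
    return math.sqrt(area_bins / math.pi)


def equivalent_square_side(area_bins: float) -> float:
    """Side length (in pixels) of the square with the given area."""
    if area_bins < 0:
        raise ValueError(f"area_bins must be non-negative, got {area_bins}")
    return math.sqrt(area_bins)


@dataclass
class SpotTable:
    """Molecule-level records on the pixel-bin grid.

    ``data`` has columns ``barcode, x_bin, y_bin, gene, splice_class,
    umi_count`` with one row per distinct ``(barcode, x_bin, y_bin, gene,
    splice_class)``; ``umi_count`` is the number of distinct UMIs observed for
    that combination.
    """

    data: pd.DataFrame
    grid: GridSpec

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"SpotTable missing columns: {missing}")
        df = self.data.loc[:, list(SPOT_COLUMNS)].reset_index(drop=True)
        df["x_bin"] = df["x_bin"].astype(np.int64)
        df["y_bin"] = df["y_bin"].astype(np.int64)
        df["umi_count"] = df["umi_count"].astype(np.int64)
        inside = self.grid.contains(df["x_bin"].to_numpy(), df["y_bin"].to_numpy())
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            row = df.iloc[i]
            raise ValueError(
                f"row {i}: coordinate ({row.x_bin}, {row.y_bin}) outside grid "
                f"{self.grid.width_bins} x {self.grid.height_bins}"
            )
        bad_class = ~df["splice_class"].isin(SPLICE_CLASSES)
        if bad_class.any():
            i = int(np.flatnonzero(bad_class.to_numpy())[0])
            raise ValueError(
                f"row {i}: unknown splice_class {df['splice_class'].iloc[i]!r}"
            )
        if (df["umi_count"] < 1).any():
            i = int(np.flatnonzero((df["umi_count"] < 1).to_numpy())[0])
            raise ValueError(f"row {i}: umi_count must be >= 1")
        dup = df.duplicated(subset=["barcode", "x_bin", "y_bin", "gene", "splice_class"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValueError(f"row {i}: duplicate (barcode, coordinate, gene, splice_class)")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def is_mito(self) -> pd.Series:
        return self.data["gene"].map(is_mito_gene)

    def total_umi(self, channel: str = "total") -> int:
        if channel not in DENSITY_CHANNELS:
            raise ValueError(f"unknown channel {channel!r}")
        df = self.data
        if channel != "total":
            df = df[df["splice_class"] == channel]
        return int(df["umi_count"].sum())

    def subset(self, mask: np.ndarray | pd.Series) -> "SpotTable":
        return SpotTable(self.data.loc[np.asarray(mask)].reset_index(drop=True), self.grid)


@dataclass
class DensityMap:
    """Per-bin UMI density for one splice channel; shape matches the grid."""

    values: np.ndarray
    channel: str
    grid: GridSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.channel not in DENSITY_CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"density shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if (self.values < 0).any():
            raise ValueError("density values must be non-negative")

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class CellbinMatrix:
    """Sparse cellbin x gene UMI count matrix with per-cellbin metadata.

    ``cellbins`` carries one row per matrix row with columns ``id, area_bins,
    centroid_x, centroid_y, total_umi, n_genes, mito_fraction``.
    """

    counts: scipy.sparse.csr_matrix
    cellbins: pd.DataFrame
    genes: list[str]

    def __post_init__(self) -> None:
        self.counts = scipy.sparse.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.cellbins):
            raise ValueError("cellbin metadata rows do not match matrix rows")
        if self.counts.shape[1] != len(self.genes):
            raise ValueError("gene list does not match matrix columns")
        if len(self.counts.data) and self.counts.data.min() < 0:
            raise ValueError("count matrix entries must be non-negative")
        row_totals = np.asarray(self.counts.sum(axis=1)).ravel()
        meta_totals = self.cellbins["total_umi"].to_numpy()
        if not np.array_equal(row_totals.astype(np.int64), meta_totals.astype(np.int64)):
            raise ValueError("matrix row totals disagree with cellbin total_umi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


# ---------------------------------------------------------------------------
# I/O

def write_spot_table(table: SpotTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_spot_table(path: str | Path, grid: GridSpec) -> SpotTable:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "gene": str, "splice_class": str})
    return SpotTable(df, grid)


def infer_grid(path: str | Path, pitch_nm: float = 250.0) -> GridSpec:
    """GridSpec just large enough for the coordinates in a spot-table TSV."""
    df = pd.read_csv(path, sep="\t", usecols=["x_bin", "y_bin"])
    return GridSpec(
        width_bins=int(df["x_bin"].max()) + 1,
        height_bins=int(df["y_bin"].max()) + 1,
        pitch_nm=pitch_nm,
    )


def write_label_map(labels: np.ndarray, path: str | Path) -> None:
    """Write an integer label raster as 16-bit PGM (.pgm, plain text) or TIFF."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2D")
    if labels.min() < 0 or labels.max() > 65535:
        raise ValueError("label values must fit in uint16")
    path = Path(path)
    arr = labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, arr)
        return
    with open(path, "w") as fh:
        fh.write(f"P2\n{arr.shape[1]} {arr.shape[0]}\n65535\n")
        for row in arr:
            fh.write(" ".join(map(str, row.tolist())) + "\n")


def read_label_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path).astype(np.int32)
    with open(path) as fh:
        tokens = fh.read().split()
    if tokens[0] != "P2":
        raise ValueError(f"{path}: expected plain PGM (P2), got {tokens[0]!r}")
    width, height = int(tokens[1]), int(tokens[2])
    data = np.array(tokens[4 : 4 + width * height], dtype=np.int32)
    return data.reshape(height, width)


def write_cellbin_matrix(matrix: CellbinMatrix, out_dir: str | Path) -> None:
    """Write MatrixMarket counts plus `cellbins.tsv` and `genes.tsv`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", matrix.counts.astype(np.int64))
    matrix.cellbins.to_csv(out_dir / "cellbins.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": matrix.genes}).to_csv(out_dir / "genes.tsv", sep="\t", index=False)


def read_cellbin_matrix(in_dir: str | Path) -> CellbinMatrix:
    in_dir = Path(in_dir)
    counts = scipy.sparse.csr_matrix(scipy.io.mmread(in_dir / "matrix.mtx"))
    cellbins = pd.read_csv(in_dir / "cellbins.tsv", sep="\t")
    genes = pd.read_csv(in_dir / "genes.tsv", sep="\t")["gene"].astype(str).tolist()
    return CellbinMatrix(counts, cellbins, genes)
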