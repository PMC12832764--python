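"""Radial gradient analysis inside tubule cross-sections.

Each cellbin inside a manually outlined tubule is assigned its minimum
Euclidean distance from centroid to the tubule's rasterized boundary pixels;
per-gene Pearson correlation of expression with that distance then ranks
genes whose expression rises or falls from the outer boundary toward the
lumen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import pearsonr
from shapely.geometry import Point, Polygon

from .cellbin_segmentation import CellbinSet
from .spatial_core import CellbinMatrix, GridSpec
from .tissue_mask import _draw_segment

__all__ = [
    "TubuleBoundary",
    "GradientResult",
    "select_cellbins_in_tubules",
    "min_distance_to_boundary",
    "distance_table",
    "gene_distance_correlation",
    "compute_gradient",
    "rank_gradient_genes",
    "gene_gene_correlation",
    "read_tubules_geojson",
    "write_tubules_geojson",
    "read_tubules_csv",
]


@dataclass
class TubuleBoundary:
    """Closed boundary polyline of one tubule, in bin coordinates."""

    id: int
    vertices: np.ndarray  # (n, 2) array of (x, y); closed implicitly

    def __post_init__(self) -> None:
        pts = np.asarray(self.vertices, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(pts) > 1 and (pts[0] == pts[-1]).all():
            pts = pts[:-1]
        if len(pts) < 3:
            raise ValueError("a tubule boundary needs at least 3 vertices")
        self.vertices = pts

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def boundary_pixels(self) -> np.ndarray:
        """Rasterized boundary as unique (x, y) integer pixel rows."""
        pts = np.rint(self.vertices).astype(int)
        xmax = int(pts[:, 0].max()) + 2
        ymax = int(pts[:, 1].max()) + 2
        raster = np.zeros((ymax, xmax), dtype=bool)
        for (x0, y0), (x1, y1) in zip(pts, np.roll(pts, -1, axis=0)):
            _draw_segment(raster, x0, y0, x1, y1)
        ys, xs = np.nonzero(raster)
        return np.column_stack([xs, ys])


@dataclass(frozen=True)
class GradientResult:
    gene: str
    n: int
    r: float
    p: float
    direction: str  # "positive" or "negative"
    defined: bool = True


def select_cellbins_in_tubules(
    cellbins: CellbinSet | pd.DataFrame, tubules: list[TubuleBoundary]
) -> pd.DataFrame:
    """Cellbins whose centroid lies strictly inside exactly one tubule.

    Overlapping tubule outlines are a digitization error and are rejected.
    Returns the cellbin table restricted to selected rows, with a
    ``tubule_id`` column appended.
    """
    polygons = [(t.id, t.polygon) for t in tubules]
    for i in range(len(polygons)):
        for j in range(i + 1, len(polygons)):
            inter = polygons[i][1].intersection(polygons[j][1])
            if inter.area > 0:
                raise ValueError(
                    f"tubule outlines {polygons[i][0]} and {polygons[j][0]} overlap"
                )
    table = cellbins.table if isinstance(cellbins, CellbinSet) else cellbins
    assignment = np.full(len(table), -1, dtype=np.int64)
    xs = table["centroid_x"].to_numpy()
    ys = table["centroid_y"].to_numpy()
    for tid, poly in polygons:
        for i in range(len(table)):
            if assignment[i] < 0 and poly.contains(Point(xs[i], ys[i])):
                assignment[i] = tid
    selected = table.loc[assignment >= 0].copy()
    selected["tubule_id"] = assignment[assignment >= 0]
    return selected.reset_index(drop=True)


def min_distance_to_boundary(
    centroid: tuple[float, float], boundary_pixels: np.ndarray
) -> float:
    """Minimum Euclidean distance from a centroid to any boundary pixel."""
    pts = np.asarray(boundary_pixels, dtype=float)
    if pts.size == 0:
        raise ValueError("empty boundary pixel set")
    dist, _ = cKDTree(pts).query(np.asarray(centroid, dtype=float))
    return float(dist)


def distance_table(
    selected: pd.DataFrame, tubules: list[TubuleBoundary]
) -> pd.DataFrame:
    """Per-cellbin distance to its own tubule's boundary pixels."""
    by_id = {t.id: t.boundary_pixels() for t in tubules}
    rows = []
    for r in selected.itertuples(index=False):
        d = min_distance_to_boundary((r.centroid_x, r.centroid_y), by_id[r.tubule_id])
        rows.append((r.id, r.tubule_id, d))
    return pd.DataFrame(rows, columns=["cellbin_id", "tubule_id", "distance_bins"])


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def gene_distance_correlation(
    expr: np.ndarray, dist: np.ndarray, gene: str = ""
) -> GradientResult:
    """Two-sided Pearson test of one gene's expression against radial distance.

    The p-value comes from the t distribution with n-2 degrees of freedom.
    Zero variance in either vector leaves the result undefined (excluded
    from ranking) rather than raising.
    """
    expr = np.asarray(expr, dtype=float)
    dist = np.asarray(dist, dtype=float)
    if expr.shape != dist.shape:
        raise ValueError("expression and distance vectors differ in length")
    n = expr.size
    if n < 3:
        raise ValueError("need at least 3 cellbins for a correlation")
    if np.ptp(expr) == 0 or np.ptp(dist) == 0:
        return GradientResult(gene, n, float("nan"), float("nan"), "positive", defined=False)
    r, p = _pearson(expr, dist)
    return GradientResult(gene, n, r, p, "positive" if r >= 0 else "negative")


def normalize_expression(matrix: CellbinMatrix, scale: float = 1e4) -> np.ndarray:
    """Library-size normalization: counts * scale / total UMI per cellbin."""
    counts = matrix.counts.toarray().astype(float)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, counts * scale / np.maximum(totals, 1), 0.0)


def compute_gradient(
    matrix: CellbinMatrix,
    distances: pd.DataFrame,
    normalize: bool = True,
    min_cells: int = 10,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression with radial distance.

    Only cellbins in ``distances`` enter; genes expressed in fewer than
    ``min_cells`` of them are excluded up front.  Expression defaults to
    library-size-normalized counts (x 1e4 / total UMI); set
    ``normalize=False`` for raw counts.
    """
    id_to_row = {cid: i for i, cid in enumerate(matrix.cellbins["id"].to_numpy())}
    rows = np.array([id_to_row[c] for c in distances["cellbin_id"].to_numpy()])
    dist = distances["distance_bins"].to_numpy(dtype=float)
    expr = normalize_expression(matrix) if normalize else matrix.counts.toarray().astype(float)
    expr = expr[rows]
    raw_sub = matrix.counts.toarray()[rows]

    results = []
    for j, gene in enumerate(matrix.genes):
        if int((raw_sub[:, j] > 0).sum()) < min_cells:
            continue
        res = gene_distance_correlation(expr[:, j], dist, gene)
        results.append(res)
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "n": r.n,
                "r": r.r,
                "p": r.p,
                "direction": r.direction,
                "defined": r.defined,
            }
            for r in results
        ]
    )


def rank_gradient_genes(
    results: pd.DataFrame, k: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k positively and negatively correlated genes.

    Undefined results are excluded; ties in r break lexicographically by
    gene id.  Asking for more than available returns everything with a
    warning.
    """
    if len(results) == 0:
        raise ValueError("no gradient results to rank")
    defined = results[results["defined"]].copy() if "defined" in results else results.copy()
    if k > len(defined):
        warnings.warn(
            f"requested top {k} but only {len(defined)} genes available", stacklevel=2
        )
        k = len(defined)
    pos = defined.sort_values(["r", "gene"], ascending=[False, True]).head(k)
    neg = defined.sort_values(["r", "gene"], ascending=[True, True]).head(k)
    return pos.reset_index(drop=True), neg.reset_index(drop=True)


def gene_gene_correlation(expr_a: np.ndarray, expr_b: np.ndarray) -> tuple[float, float]:
    """Two-sided Pearson correlation between two genes' expression vectors."""
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("expression vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 cellbins for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return _pearson(a, b)


# ---------------------------------------------------------------------------
# Tubule I/O

def write_tubules_geojson(tubules: list[TubuleBoundary], path: str | Path) -> None:
    features = []
    for t in tubules:
        ring = t.vertices.tolist() + [t.vertices[0].tolist()]
        features.append(
            {
                "type": "Feature",
                "properties": {"id": int(t.id)},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_tubules_geojson(path: str | Path) -> list[TubuleBoundary]:
    with open(path) as fh:
        data = json.load(fh)
    tubules = []
    for feature in data["features"]:
        ring = np.asarray(feature["geometry"]["coordinates"][0], dtype=float)
        tubules.append(TubuleBoundary(int(feature["properties"]["id"]), ring))
    return tubules


def read_tubules_csv(path: str | Path) -> list[TubuleBoundary]:
    """CSV with columns ``tubule_id,x_bin,y_bin``; one closed ring per id."""
    df = pd.read_csv(path)
    return [
        TubuleBoundary(int(tid), g[["x_bin", "y_bin"]].to_numpy())
        for tid, g in df.groupby("tubule_id", sort=True)
    ]
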