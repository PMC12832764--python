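"""Binary tissue masks from expression heatmaps.

Two routes are provided: threshold-based binarization of a density map
(Otsu), and the manual-contour route — rasterize an annotated contour, flood
fill its interior with 8-neighbourhood connectivity, and apply a 5x5
morphological closing.  Barcodes falling on mask pixels are then extracted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .spatial_core import DensityMap, GridSpec, SpotTable

__all__ = [
    "TissueMask",
    "otsu_threshold",
    "binarize",
    "mask_from_density",
    "rasterize_contour",
    "mask_from_contour",
    "barcodes_in_mask",
    "read_contour_csv",
    "write_mask",
    "read_mask",
]

CLOSING_KERNEL = np.ones((5, 5), dtype=bool)


@dataclass
class TissueMask:
    values: np.ndarray
    grid: GridSpec
    provenance: str  # "manual_contour" or "threshold"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.provenance not in ("manual_contour", "threshold"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def area_bins(self) -> int:
        return int(self.values.sum())


def otsu_threshold(values: np.ndarray | DensityMap, nbins: int = 256) -> float:
    """Threshold maximizing between-class variance of the value histogram.

    Pixels strictly above the returned threshold are foreground.  Constant
    input has no separating threshold and raises ``ValueError``.
    """
    if isinstance(values, DensityMap):
        values = values.values
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("otsu_threshold: empty input")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        raise ValueError("otsu_threshold: degenerate histogram (constant input)")
    hist, edges = np.histogram(v, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    # cumulative class weights / means for every candidate split between bins
    w0 = np.cumsum(w)[:-1]
    w1 = w.sum() - w0
    m = np.cumsum(w * centers)
    m0 = m[:-1] / np.where(w0 > 0, w0, np.nan)
    m1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, np.nan)
    between = w0 * w1 * (m0 - m1) ** 2
    between = np.where(np.isnan(between), -np.inf, between)
    k = int(np.argmax(between))
    # split k puts bins 0..k in the background; the class boundary is the
    # upper edge of bin k, so "> threshold" selects exactly bins k+1..
    return float(edges[k + 1])


def binarize(density: DensityMap, threshold: float | None = None) -> TissueMask:
    """Foreground = pixels strictly above the (Otsu by default) threshold."""
    if threshold is None:
        threshold = otsu_threshold(density)
    return TissueMask(density.values > threshold, density.grid, "threshold")


def mask_from_density(density: DensityMap, close: bool = True) -> TissueMask:
    """Default threshold pipeline: Otsu binarization then 5x5 closing."""
    mask = binarize(density)
    values = _closing(mask.values) if close else mask.values
    return TissueMask(values, density.grid, "threshold")


def _closing(mask: np.ndarray) -> np.ndarray:
    # pad so border erosion cannot shrink the region (closing stays extensive)
    padded = np.pad(mask, 2, mode="constant")
    closed = ndi.binary_closing(padded, structure=CLOSING_KERNEL)
    return closed[2:-2, 2:-2]


def _draw_segment(mask: np.ndarray, x0: int, y0: int, x1: int, y1: int) -> None:
    """Rasterize one segment as a 4-connected line (blocks 8-connected fill)."""
    from skimage.draw import line

    rr, cc = line(y0, x0, y1, x1)
    mask[rr, cc] = True
    # insert a connector at every diagonal step so the barrier is 4-connected
    dy = np.diff(rr)
    dx = np.diff(cc)
    diag = (dy != 0) & (dx != 0)
    mask[rr[:-1][diag] + dy[diag], cc[:-1][diag]] = True


def rasterize_contour(contour: np.ndarray, grid: GridSpec) -> np.ndarray:
    """Rasterize a closed polyline (``(x, y)`` vertex rows) onto the grid.

    The polyline is closed implicitly (last vertex connects back to the
    first).  Fewer than 3 distinct vertices is degenerate.
    """
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array of (x, y) vertices")
    pts = np.rint(pts).astype(int)
    # drop an explicit closing vertex before counting distinct ones
    if len(pts) > 1 and (pts[0] == pts[-1]).all():
        pts = pts[:-1]
    if len(np.unique(pts, axis=0)) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct vertices")
    if not np.all(grid.contains(pts[:, 0], pts[:, 1])):
        raise ValueError("contour vertex outside grid")
    raster = np.zeros(grid.shape, dtype=bool)
    for (x0, y0), (x1, y1) in zip(pts, np.roll(pts, -1, axis=0)):
        _draw_segment(raster, x0, y0, x1, y1)
    return raster


def mask_from_contour(
    contour: np.ndarray,
    grid: GridSpec,
    seed_point: tuple[int, int],
    bridge_gaps: bool = True,
) -> TissueMask:
    """Flood-fill a manually annotated contour into a tissue mask.

    The contour is rasterized, optionally closed with a 5x5 kernel to bridge
    small annotation gaps, flood-filled from ``seed_point`` (``(x, y)``,
    strictly interior) with 8-neighbourhood connectivity, and the filled
    region (including the boundary) is closed with the same 5x5 kernel.
    A fill that escapes to the image border means the contour is open.
    """
    barrier = rasterize_contour(contour, grid)
    if bridge_gaps:
        barrier = _closing(barrier)
    sx, sy = int(seed_point[0]), int(seed_point[1])
    if not bool(grid.contains(sx, sy)):
        raise ValueError(f"seed point ({sx}, {sy}) outside grid")
    if barrier[sy, sx]:
        raise ValueError(f"seed point ({sx}, {sy}) lies on the contour")
    free = ~barrier
    filled, _ = ndi.label(free, structure=np.ones((3, 3), dtype=bool))
    seed_label = filled[sy, sx]
    region = filled == seed_label
    border = np.zeros_like(region)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    if (region & border).any():
        raise ValueError("flood fill reached the image border: contour is not closed")
    values = _closing(region | barrier)
    return TissueMask(values, grid, "manual_contour")


def barcodes_in_mask(spots: SpotTable, mask: TissueMask) -> SpotTable:
    """Records whose bin lies on a True mask pixel."""
    if mask.grid.shape != spots.grid.shape:
        raise ValueError("mask grid does not match spot table grid")
    inside = mask.values[spots.data["y_bin"].to_numpy(), spots.data["x_bin"].to_numpy()]
    return spots.subset(inside)


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Vertex list CSV with columns ``x_bin,y_bin`` (closed implicitly)."""
    df = pd.read_csv(path)
    return df[["x_bin", "y_bin"]].to_numpy()


def write_mask(mask: TissueMask, path: str | Path) -> None:
    from .spatial_core import write_label_map

    write_label_map(mask.values.astype(np.uint16) * 255, path)


def read_mask(path: str | Path, grid: GridSpec, provenance: str = "threshold") -> TissueMask:
    from .spatial_core import read_label_map

    return TissueMask(read_label_map(path) > 0, grid, provenance)
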