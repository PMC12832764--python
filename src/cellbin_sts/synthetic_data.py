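"""Seeded ground-truth scene generator for end-to-end pipeline testing.

A scene is a row of ring-shaped tubules; round cells sit inside each tubule
at stratified radial depths.  Molecules are drawn per bin from Poisson
rates: unspliced-dominated signal concentrated in nuclei, spliced-dominated
signal in the cytoplasm, sparse background molecules outside cells, planted
"gradient" genes whose rates vary linearly with the cell's distance to the
tubule boundary, and "extracellular" genes emitted only outside cells.

The splice-class mixtures (nuclei 80/20 unspliced/spliced, cytoplasm 5/95)
are generator conventions chosen to make unspliced density a usable nuclear
marker, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cellbin_segmentation import SegmentationParams
from .radial_gradient import TubuleBoundary
from .spatial_core import GridSpec, SpotTable

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "SegmentationScore",
    "generate_scene",
    "evaluate_segmentation",
    "scene_segmentation_params",
    "default_scene",
]

_MAX_PLACEMENT_FAILURES = 10_000


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    ``gradient_genes`` rows are ``(gene_id, slope_per_bin, baseline)``: the
    per-bin Poisson rate inside a cell is ``max(0, baseline + slope * d)``
    with ``d`` the cell's distance to its tubule boundary.
    """

    n_tubules: int = 5
    cells_per_tubule: int = 10
    nucleus_radius_bins: float = 10.0
    cell_radius_bins: float = 20.0
    tubule_outer_radius_bins: float = 100.0
    tubule_lumen_radius_bins: float = 25.0
    unspliced_nuclear_rate: float = 0.5
    spliced_cyto_rate: float = 0.4
    background_rate: float = 0.02
    n_genes: int = 24
    gradient_genes: tuple[tuple[str, float, float], ...] = (
        ("gradp1", 0.004, 0.02),
        ("gradp2", 0.004, 0.02),
        ("gradn1", -0.004, 0.25),
        ("gradn2", -0.004, 0.25),
    )
    extracellular_genes: tuple[str, ...] = ("ecm-a", "ecm-b")
    mito_genes: tuple[str, ...] = ("mt-Nd4", "mt-Cytb")
    pitch_nm: float = 250.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.nucleus_radius_bins >= self.cell_radius_bins:
            raise ValueError("nucleus radius must be smaller than cell radius")
        if self.tubule_lumen_radius_bins >= self.tubule_outer_radius_bins:
            raise ValueError("lumen radius must be smaller than tubule radius")
        rates = (self.unspliced_nuclear_rate, self.spliced_cyto_rate, self.background_rate)
        if any(r < 0 for r in rates):
            raise ValueError("rates must be non-negative")

    @property
    def grid(self) -> GridSpec:
        spacing = 2 * self.tubule_outer_radius_bins + 40
        return GridSpec(
            width_bins=int(self.n_tubules * spacing),
            height_bins=int(2 * self.tubule_outer_radius_bins + 60),
            pitch_nm=self.pitch_nm,
        )

    @property
    def regular_genes(self) -> tuple[str, ...]:
        return tuple(f"gene{i:03d}" for i in range(self.n_genes))


@dataclass
class GroundTruth:
    """Everything the generator knows: true labels, cells, tubules, gene roles."""

    label_map: np.ndarray  # true cell labels, 0 = background
    nucleus_map: np.ndarray  # boolean nucleus mask
    cells: pd.DataFrame  # cell_id, tubule_id, cx, cy, radii, dist_to_boundary
    tubules: list[TubuleBoundary]
    gene_params: pd.DataFrame  # gene, role, slope, baseline
    grid: GridSpec


def _tubule_centers(spec: SceneSpec) -> np.ndarray:
    spacing = 2 * spec.tubule_outer_radius_bins + 40
    cy = spec.grid.height_bins / 2
    return np.array(
        [(spacing / 2 + i * spacing, cy) for i in range(spec.n_tubules)], dtype=float
    )


def _place_cells(spec: SceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample non-overlapping cells at stratified radial depths."""
    r_cell = spec.cell_radius_bins
    rho_min = spec.tubule_lumen_radius_bins + r_cell + 3
    rho_max = spec.tubule_outer_radius_bins - r_cell - 2
    if rho_min >= rho_max:
        raise ValueError("tubule annulus too thin for the requested cell radius")
    strata = np.linspace(rho_min, rho_max, 2)
    rows = []
    failures = 0
    centers = _tubule_centers(spec)
    cell_id = 1
    for tid, (tx, ty) in enumerate(centers, start=1):
        placed: list[tuple[float, float]] = []
        for j in range(spec.cells_per_tubule):
            stratum = j % len(strata)
            n_in_stratum = math.ceil(spec.cells_per_tubule / len(strata))
            base_angle = 2 * math.pi * (j // len(strata)) / n_in_stratum
            base_angle += stratum * math.pi / n_in_stratum
            while True:
                angle = base_angle + rng.uniform(-0.06, 0.06)
                rho = float(np.clip(strata[stratum] + rng.uniform(-2.5, 2.5), rho_min, rho_max))
                cx = tx + rho * math.cos(angle)
                cy = ty + rho * math.sin(angle)
                ok = all(
                    (cx - px) ** 2 + (cy - py) ** 2 >= (2 * r_cell + 1) ** 2
                    for px, py in placed
                )
                if ok:
                    placed.append((cx, cy))
                    dist = spec.tubule_outer_radius_bins - rho
                    rows.append((cell_id, tid, cx, cy, spec.nucleus_radius_bins, r_cell, dist))
                    cell_id += 1
                    break
                failures += 1
                if failures > _MAX_PLACEMENT_FAILURES:
                    raise ValueError("cell placement failed: scene packing infeasible")
    return pd.DataFrame(
        rows,
        columns=["cell_id", "tubule_id", "cx", "cy", "nucleus_r", "cell_r", "dist_to_boundary"],
    )


def _paint_cells(spec: SceneSpec, cells: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.grid.shape
    labels = np.zeros((h, w), dtype=np.int32)
    nuclei = np.zeros((h, w), dtype=bool)
    for r in cells.itertuples(index=False):
        x0 = max(0, int(r.cx - r.cell_r) - 1)
        x1 = min(w, int(r.cx + r.cell_r) + 2)
        y0 = max(0, int(r.cy - r.cell_r) - 1)
        y1 = min(h, int(r.cy + r.cell_r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (xx - r.cx) ** 2 + (yy - r.cy) ** 2
        disk = d2 <= r.cell_r**2
        labels[y0:y1, x0:x1][disk] = r.cell_id
        nuclei[y0:y1, x0:x1] |= d2 <= r.nucleus_r**2
    return labels, nuclei


def _circle_polygon(cx: float, cy: float, radius: float, n_vertices: int = 72) -> np.ndarray:
    angles = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(angles), cy + radius * np.sin(angles)])


def _sample_bins(
    rng: np.random.Generator,
    ys: np.ndarray,
    xs: np.ndarray,
    rate: float,
    genes: np.ndarray,
    splice: str,
    rows: list,
) -> None:
    """Append one molecule row per Poisson draw over the given bins."""
    if rate <= 0 or len(ys) == 0 or len(genes) == 0:
        return
    counts = rng.poisson(rate, size=len(ys))
    total = int(counts.sum())
    if total == 0:
        return
    rep_y = np.repeat(ys, counts)
    rep_x = np.repeat(xs, counts)
    gene_choice = genes[rng.integers(0, len(genes), size=total)]
    rows.append(
        pd.DataFrame(
            {"x_bin": rep_x, "y_bin": rep_y, "gene": gene_choice, "splice_class": splice}
        )
    )


def generate_scene(spec: SceneSpec | None = None) -> tuple[SpotTable, GroundTruth]:
    """Draw one seeded scene; identical spec (incl. seed) gives identical output."""
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    cells = _place_cells(spec, rng)
    labels, nuclei = _paint_cells(spec, cells)

    base_genes = np.array(spec.regular_genes + spec.mito_genes)
    bg_genes = np.array(spec.regular_genes + spec.extracellular_genes)
    rows: list[pd.DataFrame] = []

    nuc_y, nuc_x = np.nonzero(nuclei)
    cyto = (labels > 0) & ~nuclei
    cyto_y, cyto_x = np.nonzero(cyto)
    out_y, out_x = np.nonzero(labels == 0)

    # nuclei: unspliced-dominated; cytoplasm: spliced-dominated
    _sample_bins(rng, nuc_y, nuc_x, 0.8 * spec.unspliced_nuclear_rate, base_genes, "unspliced", rows)
    _sample_bins(rng, nuc_y, nuc_x, 0.2 * spec.unspliced_nuclear_rate, base_genes, "spliced", rows)
    _sample_bins(rng, cyto_y, cyto_x, 0.05 * spec.spliced_cyto_rate, base_genes, "unspliced", rows)
    _sample_bins(rng, cyto_y, cyto_x, 0.95 * spec.spliced_cyto_rate, base_genes, "spliced", rows)
    _sample_bins(rng, out_y, out_x, spec.background_rate, bg_genes, "spliced", rows)

    # gradient genes: per-cell rate linear in distance to the tubule boundary
    for cell in cells.itertuples(index=False):
        mask = labels == cell.cell_id
        ys, xs = np.nonzero(mask)
        for gene, slope, baseline in spec.gradient_genes:
            rate = max(0.0, baseline + slope * cell.dist_to_boundary)
            _sample_bins(rng, ys, xs, rate, np.array([gene]), "spliced", rows)

    if rows:
        molecules = pd.concat(rows, ignore_index=True)
    else:
        molecules = pd.DataFrame(columns=["x_bin", "y_bin", "gene", "splice_class"])
    spot_df = (
        molecules.groupby(["x_bin", "y_bin", "gene", "splice_class"], sort=True)
        .size()
        .reset_index(name="umi_count")
    )
    spot_df["barcode"] = [
        f"s{y:05d}x{x:05d}" for y, x in zip(spot_df["y_bin"], spot_df["x_bin"])
    ]
    table = SpotTable(spot_df, grid)

    tubules = [
        TubuleBoundary(tid, _circle_polygon(tx, ty, spec.tubule_outer_radius_bins))
        for tid, (tx, ty) in enumerate(_tubule_centers(spec), start=1)
    ]
    gene_params = pd.concat(
        [
            pd.DataFrame({"gene": list(spec.regular_genes), "role": "regular"}),
            pd.DataFrame({"gene": list(spec.mito_genes), "role": "mito"}),
            pd.DataFrame({"gene": list(spec.extracellular_genes), "role": "extracellular"}),
            pd.DataFrame(
                {
                    "gene": [g for g, _, _ in spec.gradient_genes],
                    "role": "gradient",
                    "slope": [s for _, s, _ in spec.gradient_genes],
                    "baseline": [b for _, _, b in spec.gradient_genes],
                }
            ),
        ],
        ignore_index=True,
    )
    truth = GroundTruth(labels, nuclei, cells, tubules, gene_params, grid)
    return table, truth


def scene_segmentation_params(spec: SceneSpec | None = None) -> SegmentationParams:
    """Segmentation parameters adjusted to the synthetic sample's cell scale.

    The algorithm's stock defaults target much larger, denser tissue scans;
    for the generated scenes the smoothing scale tracks the nucleus radius
    and the expansion cap the nucleus-to-membrane distance.
    """
    spec = spec or SceneSpec()
    sigma = spec.nucleus_radius_bins / 2
    max_area = int(math.pi * spec.cell_radius_bins**2 * 1.5)
    expansion = int(round(spec.cell_radius_bins - spec.nucleus_radius_bins))
    return SegmentationParams(
        sigma_bins=sigma,
        min_core_umi=30,
        max_area_bins=max_area,
        min_total_umi=100,
        expansion_max_dist_bins=expansion,
    )


def default_scene(seed: int = 1) -> tuple[SpotTable, GroundTruth]:
    """The standard 5-tubule, 50-cell test scene."""
    return generate_scene(SceneSpec(seed=seed))


@dataclass(frozen=True)
class SegmentationScore:
    n_true: int
    n_predicted: int
    matched_fraction: float
    count_error: float
    mean_matched_iou: float


def evaluate_segmentation(
    predicted: np.ndarray, truth: GroundTruth, iou_threshold: float = 0.5
) -> SegmentationScore:
    """Greedy one-to-one matching of predicted to true cells by descending IoU."""
    predicted = np.asarray(predicted)
    if predicted.shape != truth.label_map.shape:
        raise ValueError("predicted label map shape differs from ground truth")
    true_map = truth.label_map
    n_true = int(true_map.max())
    n_pred = int(predicted.max())
    if n_true == 0:
        raise ValueError("ground truth contains no cells")
    if n_pred == 0:
        return SegmentationScore(n_true, 0, 0.0, -1.0, 0.0)

    both = (true_map > 0) & (predicted > 0)
    pairs, inter = np.unique(
        np.stack([true_map[both], predicted[both]]), axis=1, return_counts=True
    )
    true_areas = np.bincount(true_map.ravel(), minlength=n_true + 1)
    pred_areas = np.bincount(predicted.ravel(), minlength=n_pred + 1)
    ious = []
    for (t, p), i in zip(pairs.T, inter):
        union = true_areas[t] + pred_areas[p] - i
        ious.append((i / union, int(t), int(p)))
    ious.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = []
    for iou, t, p in ious:
        if iou < iou_threshold:
            break
        if t in used_t or p in used_p:
            continue
        used_t.add(t)
        used_p.add(p)
        matched.append(iou)
    return SegmentationScore(
        n_true=n_true,
        n_predicted=n_pred,
        matched_fraction=len(matched) / n_true,
        count_error=(n_pred - n_true) / n_true,
        mean_matched_iou=float(np.mean(matched)) if matched else 0.0,
    )
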