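import numpy as np
import pandas as pd
import pytest
import scipy.ndimage as ndi

from cellbin_sts.cellbin_segmentation import (
    SegmentationParams,
    assign_spots,
    build_density,
    detect_cores,
    expand_cores,
    segment,
    smooth,
)
from cellbin_sts.spatial_core import DensityMap, GridSpec, SpotTable
from cellbin_sts.synthetic_data import SceneSpec, generate_scene, scene_segmentation_params

from conftest import random_spot_table


def _gauss_blob(shape, cy, cx, sigma, total):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    g = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
    return total * g / g.sum()


class TestParams:
    def test_invalid(self):
        with pytest.raises(ValueError):
            SegmentationParams(sigma_bins=0)
        with pytest.raises(ValueError):
            SegmentationParams(expansion_max_dist_bins=-1)
        with pytest.raises(ValueError):
            SegmentationParams(min_total_umi=0)


class TestBuildDensity:
    def test_additivity_same_bin(self, grid):
        df = pd.DataFrame(
            {
                "barcode": ["b1", "b2"],
                "x_bin": [5, 5],
                "y_bin": [7, 7],
                "gene": ["g1", "g2"],
                "splice_class": ["unspliced", "unspliced"],
                "umi_count": [2, 3],
            }
        )
        density = build_density(SpotTable(df, grid), "unspliced")
        assert density.values[7, 5] == 5

    def test_total_channel_sums_classes(self, small_spots):
        total = build_density(small_spots, "total")
        assert total.total() == small_spots.total_umi("total") == 6

    @pytest.mark.parametrize("channel", ["unspliced", "spliced", "total"])
    def test_conservation_randomized(self, grid, channel):
        rng = np.random.default_rng(12)
        spots = random_spot_table(rng, grid, n=500)
        density = build_density(spots, channel)
        assert density.total() == spots.total_umi(channel)


class TestSmooth:
    GRID = GridSpec(101, 101)

    def test_impulse_normalized(self):
        values = np.zeros(self.GRID.shape)
        values[50, 50] = 1.0
        out = smooth(DensityMap(values, "total", self.GRID), 3.0)
        assert out.total() == pytest.approx(1.0, abs=1e-6)

    def test_constant_unchanged(self):
        values = np.full(self.GRID.shape, 2.5)
        out = smooth(DensityMap(values, "total", self.GRID), 4.0)
        assert np.allclose(out.values, 2.5, atol=1e-9)

    def test_linearity(self):
        a = np.zeros(self.GRID.shape)
        a[30, 30] = 1.0
        b = np.zeros(self.GRID.shape)
        b[70, 60] = 1.0
        sa = smooth(DensityMap(a, "total", self.GRID), 3.0).values
        sb = smooth(DensityMap(b, "total", self.GRID), 3.0).values
        sab = smooth(DensityMap(a + b, "total", self.GRID), 3.0).values
        assert np.allclose(sab, sa + sb, atol=1e-9)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            smooth(DensityMap(np.zeros(self.GRID.shape), "total", self.GRID), 0)


class TestDetectCores:
    GRID = GridSpec(120, 120)

    def _params(self):
        return SegmentationParams(sigma_bins=4, min_core_umi=50)

    def test_two_blobs_two_cores(self):
        values = _gauss_blob(self.GRID.shape, 40, 40, 4, 500) + _gauss_blob(
            self.GRID.shape, 40, 80, 4, 500
        )
        smoothed = DensityMap(values, "unspliced", self.GRID)
        cores = detect_cores(smoothed, self._params())
        assert cores.max() == 2
        assert cores[40, 40] > 0 and cores[40, 80] > 0
        assert cores[40, 40] != cores[40, 80]

    def test_single_blob(self):
        values = _gauss_blob(self.GRID.shape, 60, 60, 4, 500)
        cores = detect_cores(DensityMap(values, "unspliced", self.GRID), self._params())
        assert cores.max() == 1

    def test_uniform_background_no_cores(self):
        values = np.full(self.GRID.shape, 0.1)
        cores = detect_cores(DensityMap(values, "unspliced", self.GRID), self._params())
        assert cores.max() == 0

    def test_low_umi_core_dropped(self):
        values = _gauss_blob(self.GRID.shape, 40, 40, 4, 500) + _gauss_blob(
            self.GRID.shape, 40, 80, 4, 30
        )
        cores = detect_cores(DensityMap(values, "unspliced", self.GRID), self._params())
        assert cores.max() == 1
        assert cores[40, 40] == 1

    def test_label_order_by_core_umi(self):
        values = _gauss_blob(self.GRID.shape, 40, 40, 4, 300) + _gauss_blob(
            self.GRID.shape, 80, 80, 4, 900
        )
        cores = detect_cores(DensityMap(values, "unspliced", self.GRID), self._params())
        assert cores[80, 80] == 1  # higher-UMI core gets label 1
        assert cores[40, 40] == 2


class TestExpandCores:
    GRID = GridSpec(120, 120)

    def _one_core(self):
        cores = np.zeros(self.GRID.shape, dtype=np.int32)
        cores[55:66, 55:66] = 1
        return cores

    def test_growth_monotone_until_area_cap(self):
        cores = self._one_core()
        total = DensityMap(np.full(self.GRID.shape, 1.0), "total", self.GRID)
        areas = []
        for dist in [0, 5, 10, 20, 40]:
            p = SegmentationParams(
                sigma_bins=4, min_core_umi=1, min_total_umi=1,
                max_area_bins=2000, expansion_max_dist_bins=dist,
            )
            labels = expand_cores(cores, total, p)
            areas.append(int((labels == 1).sum()))
        assert areas == sorted(areas)
        assert areas[-1] == 2000  # max_area binds
        assert areas[0] == 121  # no growth at distance 0

    def test_two_cores_stay_disjoint(self):
        cores = np.zeros(self.GRID.shape, dtype=np.int32)
        cores[20:30, 20:30] = 1
        cores[20:30, 40:50] = 2
        total = DensityMap(np.full(self.GRID.shape, 1.0), "total", self.GRID)
        for dist in [5, 20, 60]:
            p = SegmentationParams(
                sigma_bins=4, min_core_umi=1, min_total_umi=1,
                max_area_bins=40000, expansion_max_dist_bins=dist,
            )
            labels = expand_cores(cores, total, p)
            assert (labels[cores == 1] == labels[20, 20]).all()
            lab1 = set(map(tuple, np.argwhere(labels == labels[25, 25])))
            lab2 = set(map(tuple, np.argwhere(labels == labels[25, 45])))
            assert labels[25, 25] != labels[25, 45]
            assert not lab1 & lab2

    def test_no_substrate_no_growth(self):
        cores = self._one_core()
        values = np.zeros(self.GRID.shape)
        values[55:66, 55:66] = 2.0  # signal only inside the core
        total = DensityMap(values, "total", self.GRID)
        p = SegmentationParams(
            sigma_bins=4, min_core_umi=1, min_total_umi=1,
            max_area_bins=40000, expansion_max_dist_bins=30,
        )
        labels = expand_cores(cores, total, p, raw_total=total)
        assert np.array_equal(labels > 0, cores > 0)

    def test_low_total_umi_dropped(self):
        cores = self._one_core()
        raw = DensityMap(np.zeros(self.GRID.shape), "total", self.GRID)
        smoothed = DensityMap(np.full(self.GRID.shape, 1.0), "total", self.GRID)
        p = SegmentationParams(
            sigma_bins=4, min_core_umi=1, min_total_umi=100,
            max_area_bins=40000, expansion_max_dist_bins=5,
        )
        labels = expand_cores(cores, smoothed, p, raw_total=raw)
        assert labels.max() == 0


class TestAssignSpots:
    def test_full_recall_inside_label(self, grid):
        labels = np.ones(grid.shape, dtype=np.int32)
        rng = np.random.default_rng(1)
        spots = random_spot_table(rng, grid, n=100)
        cellbins, matrix, unassigned = assign_spots(labels, spots)
        assert len(unassigned) == 0
        assert cellbins.table["total_umi"].iloc[0] == spots.total_umi()

    def test_background_spot_unassigned(self, grid):
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[0:10, 0:10] = 1
        df = pd.DataFrame(
            {
                "barcode": ["a", "b"],
                "x_bin": [5, 50],
                "y_bin": [5, 50],
                "gene": ["g", "g"],
                "splice_class": ["spliced", "spliced"],
                "umi_count": [2, 7],
            }
        )
        spots = SpotTable(df, grid)
        cellbins, matrix, unassigned = assign_spots(labels, spots)
        assert unassigned.data["barcode"].tolist() == ["b"]
        assert cellbins.table["total_umi"].iloc[0] == 2

    def test_conservation_randomized(self, grid):
        rng = np.random.default_rng(9)
        spots = random_spot_table(rng, grid, n=400)
        labels = rng.integers(0, 4, size=grid.shape).astype(np.int32)
        cellbins, matrix, unassigned = assign_spots(labels, spots)
        assigned_umi = int(cellbins.table["total_umi"].sum())
        assert assigned_umi + unassigned.total_umi() == spots.total_umi()
        assert matrix.counts.sum() == assigned_umi

    def test_centroid_is_pixel_mean(self, grid):
        labels = np.zeros(grid.shape, dtype=np.int32)
        labels[10:13, 20:23] = 1  # 3x3 block: centroid (21, 11)
        rng = np.random.default_rng(2)
        spots = random_spot_table(rng, grid, n=50)
        cellbins, _, _ = assign_spots(labels, spots)
        row = cellbins.table.iloc[0]
        assert row.centroid_x == pytest.approx(21.0)
        assert row.centroid_y == pytest.approx(11.0)
        assert row.area_bins == 9


class TestSegment:
    def test_default_scene_cellbin_count(self, scene1_segmentation):
        _, truth, _, labels, cellbins, _ = scene1_segmentation
        assert 45 <= len(cellbins) <= 55

    def test_empty_table_error(self, grid):
        empty = SpotTable(
            pd.DataFrame(
                {
                    "barcode": [],
                    "x_bin": [],
                    "y_bin": [],
                    "gene": [],
                    "splice_class": [],
                    "umi_count": [],
                }
            ),
            grid,
        )
        with pytest.raises(ValueError, match="empty"):
            segment(empty)

    def test_scale_equivariance(self):
        # doubling every count while doubling both UMI thresholds must not
        # move any label boundary
        spec = SceneSpec(n_tubules=1, cells_per_tubule=4, seed=3)
        spots, _ = generate_scene(spec)
        params = scene_segmentation_params(spec)
        doubled_df = spots.data.copy()
        doubled_df["umi_count"] *= 2
        doubled = SpotTable(doubled_df, spots.grid)
        params2 = SegmentationParams(
            sigma_bins=params.sigma_bins,
            min_core_umi=params.min_core_umi * 2,
            max_area_bins=params.max_area_bins,
            min_total_umi=params.min_total_umi * 2,
            expansion_max_dist_bins=params.expansion_max_dist_bins,
        )
        labels1, _, _ = segment(spots, params)
        labels2, _, _ = segment(doubled, params2)
        assert np.array_equal(labels1, labels2)

    def test_partition_and_constraints(self, scene1_segmentation):
        spots, _, params, labels, cellbins, _ = scene1_segmentation
        t = cellbins.table
        assert (t["area_bins"] <= params.max_area_bins).all()
        assert (t["total_umi"] >= params.min_total_umi).all()
        # every label 8-connected
        for label_id in t["id"]:
            region = labels == label_id
            _, n_comp = ndi.label(region, structure=np.ones((3, 3)))
            assert n_comp == 1

    def test_cores_within_cellbins(self, scene1):
        spots, _ = scene1
        params = scene_segmentation_params()
        unspliced = build_density(spots, "unspliced")
        total = build_density(spots, "total")
        su = smooth(unspliced, params.sigma_bins)
        stt = smooth(total, params.sigma_bins)
        cores = detect_cores(su, params, raw_unspliced=unspliced)
        labels = expand_cores(cores, stt, params, raw_total=total)
        # each surviving core's pixels all lie inside a single cellbin
        for core_id in range(1, cores.max() + 1):
            core_pixels = labels[cores == core_id]
            surviving = core_pixels[core_pixels > 0]
            if len(surviving):
                assert len(np.unique(surviving)) == 1
                assert (core_pixels > 0).all()

    def test_determinism(self):
        spec = SceneSpec(n_tubules=1, cells_per_tubule=4, seed=5)
        spots, _ = generate_scene(spec)
        params = scene_segmentation_params(spec)
        labels1, cb1, _ = segment(spots, params)
        labels2, cb2, _ = segment(spots, params)
        assert np.array_equal(labels1, labels2)
        pd.testing.assert_frame_equal(cb1.table, cb2.table)
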