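import numpy as np
import pandas as pd
import pytest

from cellbin_sts.cellbin_segmentation import segment
from cellbin_sts.spatial_core import GridSpec, SpotTable
from cellbin_sts.synthetic_data import (
    SceneSpec,
    generate_scene,
    scene_segmentation_params,
)


@pytest.fixture
def grid():
    return GridSpec(width_bins=100, height_bins=80)


@pytest.fixture
def small_spots(grid):
    df = pd.DataFrame(
        {
            "barcode": ["b1", "b2", "b3"],
            "x_bin": [0, 10, 99],
            "y_bin": [0, 20, 79],
            "gene": ["geneA", "mt-Nd4", "geneB"],
            "splice_class": ["spliced", "unspliced", "spliced"],
            "umi_count": [1, 2, 3],
        }
    )
    return SpotTable(df, grid)


def random_spot_table(rng, grid, n=200, genes=("g1", "g2", "mt-x")):
    """Randomized valid SpotTable for property tests."""
    df = pd.DataFrame(
        {
            "x_bin": rng.integers(0, grid.width_bins, n),
            "y_bin": rng.integers(0, grid.height_bins, n),
            "gene": rng.choice(list(genes), n),
            "splice_class": rng.choice(["spliced", "unspliced"], n),
            "umi_count": 1,
        }
    )
    df = (
        df.groupby(["x_bin", "y_bin", "gene", "splice_class"], sort=True)
        .size()
        .reset_index(name="umi_count")
    )
    df["barcode"] = [f"b{x}_{y}" for x, y in zip(df["x_bin"], df["y_bin"])]
    return SpotTable(df, grid)


@pytest.fixture(scope="session")
def scene1():
    """The default 50-cell scene, seed 1 (shared: generation is ~1 s)."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def scene1_segmentation(scene1):
    """Seed-1 scene segmented with the scene-adapted parameters."""
    spots, truth = scene1
    params = scene_segmentation_params()
    labels, cellbins, matrix = segment(spots, params)
    return spots, truth, params, labels, cellbins, matrix
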