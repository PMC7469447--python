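import numpy as np
import pytest

from adipometry.fixtures import FixtureParams, add_artifacts, make_fluorescent_overlay, make_grid_cells, make_voronoi_tissue
from adipometry.io_calibration import Calibration
from adipometry.segmentation import detect_cells


@pytest.fixture(scope="session")
def cal1() -> Calibration:
    return Calibration(mpp=1.0)


@pytest.fixture(scope="session")
def grid_fixture():
    """3x3 grid of radius-20 discs on a dark background, mpp 1."""
    return make_grid_cells(3, 3, 20, FixtureParams(rng_seed=7))


@pytest.fixture(scope="session")
def voronoi_fixture():
    """50-cell sealed-membrane Voronoi mosaic, mpp 1."""
    return make_voronoi_tissue(FixtureParams(rng_seed=0))


@pytest.fixture(scope="session")
def voronoi_population(voronoi_fixture, cal1):
    img, _ = voronoi_fixture
    return detect_cells(img, cal1)


@pytest.fixture(scope="session")
def artifact_fixture():
    """Grid fixture with haze, 20 dust specks, and a scratch."""
    params = FixtureParams(rng_seed=3, n_dust=20, scratch=True, haze=0.2)
    img, gt = make_grid_cells(3, 3, 20, params)
    return add_artifacts(img, gt, params)


@pytest.fixture(scope="session")
def fluor_fixture():
    """12 disjoint RGB blobs on black, 128x128."""
    return make_fluorescent_overlay(FixtureParams(rng_seed=1, n_cells=12, shape=(128, 128)))
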