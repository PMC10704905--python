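import numpy as np
import pytest

from blobsieve import SimulationConfig, TrackPointCloud, run_pipeline


@pytest.fixture
def unit_square():
    return TrackPointCloud("sq", [(0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)])


@pytest.fixture
def unit_cube():
    pts = [(x, y, z) for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
    return TrackPointCloud("cube", pts)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def sim2d_run():
    """One full pipeline run on the default 2D ground-truth dataset."""
    cfg = SimulationConfig(dim=2, seed=7)
    return run_pipeline(cfg, seed=7)


@pytest.fixture(scope="session")
def sim3d_run():
    cfg = SimulationConfig(dim=3, seed=7)
    return run_pipeline(cfg, seed=7)
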