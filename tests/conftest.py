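import numpy as np
import pytest

from puffmapper import CellROI, PipelineConfig, SimulationConfig, simulate_movie


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_movie():
    """A small simulated cell with moderate activity, shared across tests."""
    cfg = SimulationConfig(n_frames=200, image_shape=(96, 96), n_sites=8,
                           cell_radius_um=6.5, firing_rate=0.4, rng_seed=3,
                           drift_rate=0.02)
    stack, mask, manifest = simulate_movie(cfg)
    return cfg, stack, mask, manifest


@pytest.fixture(scope="session")
def small_movie_roi(small_movie):
    cfg, stack, mask, manifest = small_movie
    return CellROI(mask=mask, pixel_size=cfg.pixel_size)
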