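import warnings

import numpy as np
import pytest

from voltdend.config import PipelineConfig
from voltdend.synth import SceneConfig, simulate_movie

# statsmodels mixed-model convergence chatter is irrelevant to the assertions
warnings.filterwarnings("ignore", module="statsmodels")


@pytest.fixture(scope="session")
def two_cell_movie():
    """One nominal-noise two-cell movie shared by segmentation/trace tests."""
    cfg = SceneConfig(n_cells=2, field_shape=(20, 64), duration_s=60.0, seed=11)
    movie, daq, gt = simulate_movie(cfg)
    return cfg, movie, daq, gt


@pytest.fixture(scope="session")
def clean_movie():
    """Noise-free, bleach-free, drift-free single-cell movie with one forced
    spike at t = 1 s."""
    cfg = SceneConfig(
        n_cells=1,
        field_shape=(16, 48),
        duration_s=4.0,
        noise_scale=0.0,
        bleach_enabled=False,
        drift_sd=0.0,
        cs_spike_times=[[1.0]],
        seed=0,
    )
    movie, daq, gt = simulate_movie(cfg)
    return cfg, movie, daq, gt


@pytest.fixture()
def pipeline_config():
    return PipelineConfig()
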