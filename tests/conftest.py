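import numpy as np
import pytest

from fcp import WorldConfig, generate_covariates, generate_truth, generate_world


@pytest.fixture(scope="session")
def small_config() -> WorldConfig:
    return WorldConfig(grid_height=64, grid_width=64,
                       lat_range=(-16.0, 16.0), lon_range=(0.0, 32.0),
                       plot_density=8.0, seed=7)


@pytest.fixture(scope="session")
def small_world(small_config):
    """64x64 world with ~330 plots; shared across the suite."""
    return generate_world(small_config)


@pytest.fixture(scope="session")
def big_world():
    """Default 128x128 world (the documented study conditions)."""
    config = WorldConfig(seed=3)
    stack = generate_covariates(config)
    truth = generate_truth(stack, config)
    return config, stack, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
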