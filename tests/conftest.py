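import numpy as np
import pytest

from mrtherm import SimulationConfig, simulate_temperature


@pytest.fixture(scope="session")
def fast_config():
    """Small, quick heating scenario shared by end-to-end tests."""
    return SimulationConfig(
        grid_shape=(64, 64),
        pixel_spacing_mm=(150.0 / 64, 150.0 / 64),
        n_slices=3,
        sonication_duration_s=60.0,
        post_duration_s=60.0,
        noise_sd_rad=0.0,
        seed=123,
    )


@pytest.fixture(scope="session")
def fast_truth(fast_config):
    return simulate_temperature(fast_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210614)
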