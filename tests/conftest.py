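import numpy as np
import pytest

from capstall.config import SimulationConfig


@pytest.fixture(scope="session")
def small_sim_config():
    """A small but fully featured simulation: 12 capillaries, 120 frames."""
    return SimulationConfig(
        height_px=256,
        width_px=256,
        n_frames=120,
        n_capillaries=12,
        capillary_length_px=(90, 130),
        stall_onset_rate=1.0,
        stalling_fraction=0.6,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_sim_config):
    from capstall.simulate import simulate_angiogram

    series, truth = simulate_angiogram(small_sim_config)
    return small_sim_config, series, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
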