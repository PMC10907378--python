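import numpy as np
import pytest

from trasein.simulate import SimConfig, simulate_movie


@pytest.fixture(scope="session")
def small_sim():
    """Small default-style movie shared by read-only tests."""
    config = SimConfig(
        n_neurons=15,
        n_nematocytes=2,
        image_shape=(96, 128),
        n_frames=120,
        rng_seed=11,
        deformation_amplitude_px=2.0,
        spike_rate_hz=0.15,
    )
    anchor, activity, truth = simulate_movie(config)
    return config, anchor, activity, truth


@pytest.fixture(scope="session")
def benchmark_sim():
    """Default synthetic benchmark for end-to-end properties."""
    config = SimConfig(
        n_neurons=20,
        n_nematocytes=2,
        image_shape=(128, 176),
        n_frames=500,
        rng_seed=42,
        deformation_amplitude_px=2.0,
        spike_rate_hz=0.1,
        refractory_frames=40,
        noise_sigma_anchor=1.0,
        noise_sigma_activity=1.0,
        min_spacing_px=12.0,
        body_sigma_px=3.0,
    )
    anchor, activity, truth = simulate_movie(config)
    return config, anchor, activity, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
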