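import numpy as np
import pytest

from munet import SimSpec, make_sensor_array, uniform_coupling


@pytest.fixture(scope="session")
def sensor_array_small():
    return make_sensor_array(n_channels=12, spacing=13.0, seed=0)


@pytest.fixture(scope="session")
def sensor_array_full():
    return make_sensor_array(n_channels=76, spacing=13.0, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def pair_spec(coupling: float, seed: int, duration: float = 40.0,
              impf: float = 9.5) -> SimSpec:
    """Two-channel spec with a given shared-signal fraction and no events."""
    return SimSpec(n_channels=2, fs=500.0, duration=duration, impf=impf,
                   coupling=uniform_coupling(2, coupling), n_events=0,
                   seed=seed, noise_sd=0.3)
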