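import numpy as np
import pytest

from spindilometer.simkit import SimConfig, simulate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """A 2-minute six-channel simulated recording with its ground truth."""
    cfg = SimConfig(seed=7, duration_s=120.0)
    recording, events = simulate_recording(cfg)
    return cfg, recording, events


@pytest.fixture(scope="session")
def blob_data():
    """Two well-separated Gaussian blobs (3 sigma apart), d=2, n=200."""
    gen = np.random.default_rng(99)
    n = 100
    X0 = gen.normal(loc=0.0, scale=1.0, size=(n, 2))
    X1 = gen.normal(loc=3.0, scale=1.0, size=(n, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n + [1] * n)
    return X, y
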