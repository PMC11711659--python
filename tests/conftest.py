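import numpy as np
import pytest

from aepkit.preprocess import EpochedAverage
from aepkit.simulate import DEFAULT_TEMPLATE, EarSimParams, Stimulus


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture
def quiet_params():
    """Noise-free ear: deterministic rendering."""
    return EarSimParams(true_threshold=40.0, noise_sd=0.0, heartbeat_amp=0.0)


@pytest.fixture
def tone_stim():
    return Stimulus("tone", 80.0, 300.0)


def make_average(time_ms, mean, sem=None, n=100, condition=None):
    """Build an EpochedAverage directly from arrays (unit-test helper)."""
    time_ms = np.asarray(time_ms, dtype=float)
    mean = np.asarray(mean, dtype=float)
    if sem is None:
        sem = np.zeros_like(mean)
    elif np.isscalar(sem):
        sem = np.full_like(mean, float(sem))
    return EpochedAverage(
        time_ms=time_ms,
        mean=mean,
        sem=np.asarray(sem, dtype=float),
        n_epochs_retained=n,
        condition=condition or {},
    )


@pytest.fixture
def average_factory():
    return make_average
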