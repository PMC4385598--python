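import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from shadematch import SyntheticModelParams, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """40 noisy synthetic specimens; shared across read-only tests."""
    return generate_dataset(40, SyntheticModelParams(seed=7))


@pytest.fixture(scope="session")
def noiseless_params():
    """Linear, noise-free generator settings (exact forward model)."""
    return SyntheticModelParams(seed=11, curvature=0.0, noise_sd=np.zeros(3))


def finite_difference_gradient(f, vec, h=1e-6):
    """Central-difference gradient of a scalar function of a vector."""
    vec = np.asarray(vec, dtype=float)
    g = np.zeros_like(vec)
    for i in range(vec.size):
        up, down = vec.copy(), vec.copy()
        up[i] += h
        down[i] -= h
        g[i] = (f(up) - f(down)) / (2 * h)
    return g
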