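import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from medcast.series import make_supervised
from medcast.simulate import SimConfig, simulate_expenditure


@pytest.fixture(scope="session")
def stationary_series():
    """Default stationary synthetic medicine (1,565 days)."""
    return simulate_expenditure(SimConfig(seed=7))


@pytest.fixture(scope="session")
def integrated_series():
    """Default first-order-integrated synthetic medicine (1,565 days)."""
    return simulate_expenditure(SimConfig(regime="integrated", seed=7))


@pytest.fixture(scope="session")
def linear_recurrence():
    """Noiseless deterministic recurrence y_t = 0.5 y_{t-1} + 0.25 as a
    supervised lag-2 set (the learnability oracle for the neural trainers)."""
    y = [1.0]
    for _ in range(400):
        y.append(0.5 * y[-1] + 0.25)
    y = np.asarray(y)
    return make_supervised(y, 2), y
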