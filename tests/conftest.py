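import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mrsum as mr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dataset(seed: int, J: int = 10, theta: float = 0.5,
                   se: float = 0.05) -> mr.MRInput:
    """A clean random summarized dataset with noisy outcome associations."""
    rng = np.random.default_rng(seed)
    bx = np.abs(rng.normal(0.3, 0.1, J))
    by = theta * bx + rng.normal(0.0, se, J)
    bxse = np.full(J, 0.03)
    byse = se * rng.uniform(0.8, 1.2, J)
    return mr.make_input(bx, bxse, by, byse)


@pytest.fixture
def clean_data() -> mr.MRInput:
    return random_dataset(7, J=10)


@pytest.fixture
def exact_data() -> mr.MRInput:
    """by exactly 0.5 * bx: every consistent estimator must return 0.5."""
    bx = np.array([0.2, 0.35, 0.4, 0.15, 0.3, 0.25, 0.45, 0.1, 0.5, 0.28])
    return mr.make_input(bx, np.full(10, 0.02), 0.5 * bx, np.full(10, 0.04))
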