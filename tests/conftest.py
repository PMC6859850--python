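import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def noisy_series_fixtures():
    """50 seeded Poisson bounded-growth series for fit-optimality checks.

    Each entry is (times, y, y_eq_true, k_true) with strictly positive counts.
    """
    rng = np.random.default_rng(20240917)
    t = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
    out = []
    while len(out) < 50:
        y_eq = rng.uniform(50.0, 500.0)
        hl = np.exp(rng.uniform(np.log(0.5), np.log(24.0)))
        k = -np.log(2.0) / hl
        mu = y_eq * (1.0 - np.exp(k * t))
        y = rng.poisson(mu).astype(float)
        if (y > 0).all():
            out.append((t, y, y_eq, k))
    return out
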