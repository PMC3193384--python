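import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def opt_rho_schedules():
    """Optimized relaxation-target schedules for n = 2..6 (shared: ~15 s)."""
    from vfalin.protocol import optimize_schedule

    return {n: optimize_schedule(n, target="rho1") for n in range(2, 7)}


@pytest.fixture(scope="session")
def opt_amp_schedule2():
    from vfalin.protocol import optimize_schedule

    return optimize_schedule(2, target="amplitude")


@pytest.fixture
def rng():
    return np.random.default_rng(20110322)
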