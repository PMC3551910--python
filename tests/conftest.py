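import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dotpomdp import MTParams, PriorParams, RewardParams, solve

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mt() -> MTParams:
    return MTParams()


@pytest.fixture(scope="session")
def default_sol():
    """Policy solved at the package's default study conditions."""
    sol = solve(RewardParams(), prior=PriorParams(), n=1, horizon=400)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def fast_sol():
    """Smaller, quickly solved policy (lower reward ratio, short horizon)
    for tests that only need *a* converged collapsing-bound policy."""
    sol = solve(RewardParams(reward_correct=100.0), n=1, horizon=150)
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def coherence_grid():
    return np.array([0.0, 0.032, 0.064, 0.128, 0.256, 0.512])
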