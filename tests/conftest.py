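import numpy as np
import pytest
from hypothesis import settings

from ktwsim import CommunityState, SimulationParams

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(P, g=None, gamma=1e-3):
    """CommunityState from linear abundances (normalised), equal rates default."""
    P = np.asarray(P, dtype=float)
    P = P / P.sum()
    n = P.size
    g = np.zeros(n) if g is None else np.asarray(g, dtype=float)
    return CommunityState(
        log_abundance=np.log(P),
        growth_rate=g,
        collapse_ratio=np.full(n, gamma) if np.isscalar(gamma) else np.asarray(gamma),
    )


@pytest.fixture
def two_species():
    return make_state([0.5, 0.5], g=[1.0, 0.0])


@pytest.fixture(scope="session")
def criterion_run():
    """Long mixed-rate run shared by the steady-state identity checks.

    N=20 Gaussian-rate community (sigma=2), gamma=1e-4, 5e4 collapse events:
    long enough that every survivor cycles many times.
    """
    from ktwsim import simulate

    params = SimulationParams(
        n_species=20,
        sigma=2.0,
        rate_distribution="gaussian",
        tau=1.0,
        gamma=1e-4,
        n_events=50_000,
        seed=42,
    )
    return simulate(params)
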