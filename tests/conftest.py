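import pytest
from hypothesis import HealthCheck, settings

import crossfeed as cf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def experimental_rules() -> cf.LocalRules:
    """Local rules of the two-auxotroph cross-feeding community: the
    small-neighborhood type has r=10 and the growth-rate ratio is
    0.22/0.78 (the well-mixed equilibrium of the measured community)."""
    return cf.LocalRules(r_A=10, r_B=130, mu_hat_A=0.22, mu_hat_B=0.78)


@pytest.fixture(scope="session")
def experimental_ca() -> cf.CAConfig:
    """Lattice parameterization of the same community: extended Moore
    ranges 1 (8 neighbors) and 5 (120 neighbors) on a 100x100 torus."""
    return cf.CAConfig(
        d_A=1, d_B=5, mu_hat_A=0.22, mu_hat_B=0.78,
        height=100, width=100, init_freq_A=0.5, n_events=100_000, seed=0,
    )
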