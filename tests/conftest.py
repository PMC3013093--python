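import numpy as np
import pytest

from vesselhomog import DimensionlessParams, build_profile, solve_exact


@pytest.fixture(scope="session")
def case_a_params():
    """Moderate case-A point: p = delta*kappa*eps^2 = 0.025."""
    return DimensionlessParams(eps=1 / 20, delta=0.1, kappa=100.0, f=1.0)


@pytest.fixture(scope="session")
def case_b_params():
    """Opaque-vessel point: p = 100, sqrt(kappa)*delta*eps ~ 4.5."""
    return DimensionlessParams(eps=1 / 20, delta=0.2, kappa=2e5, f=1.0)


@pytest.fixture(scope="session")
def case_a_solution(case_a_params):
    profile = build_profile(case_a_params)
    return profile, solve_exact(
        profile, case_a_params.f, case_a_params.g0, case_a_params.g1)


@pytest.fixture(scope="session")
def case_b_solution(case_b_params):
    profile = build_profile(case_b_params)
    return profile, solve_exact(
        profile, case_b_params.f, case_b_params.g0, case_b_params.g1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
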