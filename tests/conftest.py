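"""Shared fixtures and closed-form helpers for the test suite."""

import numpy as np
import pytest
from hypothesis import settings

from areakin.fixtures import FixtureSpec, make_root_series
from areakin.root_transport import calibrate_to_scenario1

# property tests must behave identically on every run/machine
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def two_state_solution(times, n1_0, n2_0, a, b):
    """Closed-form amounts of the linear exchange n1' = -a n1 + b n2.

    Independent of the integrator: eigen-decomposition of the 2x2 rate
    matrix done by hand (eigenvalues 0 and -(a+b))."""
    times = np.asarray(times, dtype=float)
    total = n1_0 + n2_0
    lam = a + b
    n1_eq = total * b / lam
    n1 = n1_eq + (n1_0 - n1_eq) * np.exp(-lam * times)
    return np.column_stack([n1, total - n1])


@pytest.fixture(scope="session")
def root_scenarios():
    return make_root_series(FixtureSpec())


@pytest.fixture(scope="session")
def scenario1(root_scenarios):
    return root_scenarios[0]


@pytest.fixture(scope="session")
def calibrated(scenario1):
    return calibrate_to_scenario1(1.0, 1.0, scenario1, verify=False)
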