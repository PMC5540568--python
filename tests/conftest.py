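import numpy as np
import pytest

from crcscreen import (build_population, make_default_lifetable,
                       make_default_params, make_default_policy,
                       make_population_spec)


@pytest.fixture(scope="session")
def default_params():
    return {s: make_default_params(s) for s in ("male", "female")}


@pytest.fixture(scope="session")
def default_tables():
    return {s: make_default_lifetable(s) for s in ("male", "female")}


@pytest.fixture(scope="session")
def default_policy():
    return make_default_policy()


@pytest.fixture(scope="session")
def small_spec():
    return make_population_spec(sample_size=5_000)


@pytest.fixture(scope="session")
def small_population(small_spec, default_params, default_tables):
    """10,000 persons (5,000 per sex) with resolved histories; read-only."""
    rng = np.random.default_rng(2024)
    return build_population(small_spec, default_params, default_tables, rng)


def ode_occupancy_probabilities(onset_rate, p_progressive, rate_small_large,
                                rate_large_pre, stage_rates, sojourn_rates,
                                age):
    """Independent compartment-ODE oracle for state occupancy.

    With a constant adenoma onset rate and exponential dwell times, the
    expected number of lesions per person in each state solves a linear
    constant-coefficient ODE with a constant source; because disjoint
    state categories of a marked Poisson process hold independent Poisson
    counts, exact person-level "most advanced state" probabilities follow
    in closed form from the expected counts.

    Returns (p_none, p_by_category) with categories ordered
    small < large < preclinical I..IV < clinical.
    """
    from scipy.linalg import expm
    a, b = rate_small_large, rate_large_pre
    prog, soj = stage_rates, sojourn_rates
    A = np.zeros((10, 10))
    A[0, 0] = -a
    A[1, 1] = -a
    A[2, 0] = a
    A[2, 2] = -b
    A[3, 1] = a
    A[4, 2] = b
    A[4, 4] = -(prog[0] + soj[0])
    A[5, 4] = prog[0]
    A[5, 5] = -(prog[1] + soj[1])
    A[6, 5] = prog[1]
    A[6, 6] = -(prog[2] + soj[2])
    A[7, 6] = prog[2]
    A[7, 7] = -soj[3]
    A[8, 4:8] = soj
    A[0, 9] = onset_rate * p_progressive
    A[1, 9] = onset_rate * (1.0 - p_progressive)
    x = np.zeros(10)
    x[9] = 1.0
    m = (expm(A * age) @ x)[:9]
    counts = np.array([m[0] + m[1], m[2] + m[3], m[4], m[5], m[6], m[7], m[8]])
    p_none = np.exp(-counts.sum())
    probs = np.array([np.exp(-counts[i + 1:].sum())
                      * (1.0 - np.exp(-counts[i]))
                      for i in range(len(counts))])
    return p_none, probs
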