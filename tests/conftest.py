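import numpy as np
import pytest

from dberm import (
    DBERMParams,
    GroupDistribution,
    SHR_REFERENCE,
    WKY_REFERENCE,
    simulate_cohort,
)


@pytest.fixture
def shr_params() -> DBERMParams:
    """Reference SHR-like parameter set (group medians)."""
    return SHR_REFERENCE


@pytest.fixture
def wky_params() -> DBERMParams:
    """Reference WKY-like parameter set (group medians)."""
    return WKY_REFERENCE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_valid_params(rng: np.random.Generator) -> DBERMParams:
    """A random parameter vector satisfying all ordering constraints."""
    omega = rng.uniform(0.01, 3.0)
    b0 = omega + rng.uniform(0.5, 40.0)
    w0 = b0 * rng.uniform(1.5, 20.0)
    alpha = rng.uniform(0.0, 0.3)
    beta = alpha + rng.uniform(0.0, 0.3)
    return DBERMParams(
        L0=rng.uniform(0.0, 8.0),
        w0=w0,
        b0=b0,
        gamma=rng.uniform(0.0, 0.3),
        alpha=alpha,
        beta=beta,
        delta=rng.uniform(5e-4, 5e-3),
        omega=omega,
    )


@pytest.fixture
def small_wky_cohort():
    """A compact single-session cohort from the WKY reference medians."""
    groups = [GroupDistribution("WKY", WKY_REFERENCE, sdlog=0.2)]
    return simulate_cohort(groups, n_rats_per_strain=3, n_sessions=1,
                           duration=15.0, seed=11)
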