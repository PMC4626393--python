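import numpy as np
import pandas as pd
import pytest

import cohortbump as cb


@pytest.fixture
def small_table() -> cb.AgePeriodTable:
    """Deterministic 3 ages x 4 periods table with plausible counts."""
    ages = np.array([42.5, 47.5, 52.5])
    periods = np.array([1962.5, 1967.5, 1972.5, 1977.5])
    A, P = np.meshgrid(ages, periods, indexing="ij")
    rng = np.random.default_rng(42)
    cells = pd.DataFrame({
        "age": A.ravel(), "period": P.ravel(),
        "deaths": rng.poisson(50.0, A.size),
        "person_years": np.full(A.size, 1e5),
    })
    return cb.AgePeriodTable(cells)


@pytest.fixture(scope="session")
def sim_positive() -> cb.AgePeriodTable:
    """One table from the liver-like positive-bump scenario."""
    return cb.simulate_table(cb.default_scenario("bump-positive", seed=7))


@pytest.fixture(scope="session")
def sim_null() -> cb.AgePeriodTable:
    return cb.simulate_table(cb.default_scenario("null", seed=7))


def random_small_table(rng: np.random.Generator,
                       n_ages: int = 4, n_periods: int = 4
                       ) -> cb.AgePeriodTable:
    """Small random table for oracle-equivalence checks: smooth random
    log-rates, moderate exposures."""
    ages = np.arange(n_ages) * 5.0 + 40.0
    periods = np.arange(n_periods) * 5.0 + 1960.0
    A, P = np.meshgrid(ages, periods, indexing="ij")
    at = (A.ravel() - A.mean()) / max(A.std(), 1.0)
    pt = (P.ravel() - P.mean()) / max(P.std(), 1.0)
    beta0 = (-6.0 + rng.normal(0, 0.5) + rng.normal(0, 0.3) * at
             + rng.normal(0, 0.3) * pt + rng.normal(0, 0.1) * at * pt)
    z = rng.uniform(5e4, 2e5, A.size)
    deaths = rng.poisson(z * np.exp(beta0))
    cells = pd.DataFrame({"age": A.ravel(), "period": P.ravel(),
                          "deaths": deaths, "person_years": z})
    return cb.AgePeriodTable(cells)
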