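import numpy as np
import pandas as pd
import pytest

from preconrisk import Cohort, CovariateSchema
from preconrisk.simulate import default_cohort_params, simulate_cohort


@pytest.fixture
def simple_schema():
    return CovariateSchema(x=("a", "b"), z=("a",), x_prime=("b",), z_prime=("b",))


@pytest.fixture
def four_pattern_df():
    """One subject in each of the four observed-data categories (tau=6)."""
    return pd.DataFrame(
        {
            "id": [1, 2, 3, 4],
            "U": [2, 6, 3, 4],
            "conceived": [0, 0, 1, 1],
            "r1": [0, 1, 1, 1],
            "y2": [np.nan, np.nan, np.nan, 4.0],
            "r2": [0, 1, 0, 1],
            "a": [0.1, -0.5, 1.2, 0.0],
            "b": [1, 0, 1, 0],
        }
    )


@pytest.fixture
def four_pattern_cohort(four_pattern_df, simple_schema):
    return Cohort(four_pattern_df, tau=6, schema=simple_schema)


@pytest.fixture(scope="session")
def default_params():
    return default_cohort_params(n=4000)


@pytest.fixture(scope="session")
def default_cohort(default_params):
    return simulate_cohort(default_params, seed=11)


@pytest.fixture(scope="session")
def complete_default_cohort(default_cohort):
    """Default simulated cohort restricted to complete-covariate subjects."""
    cov = list(default_cohort.covariate_names)
    keep = ~default_cohort.df[cov].isna().any(axis=1)
    return Cohort(
        default_cohort.df.loc[keep].reset_index(drop=True),
        default_cohort.tau,
        default_cohort.schema,
        validate=False,
    )
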