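import warnings

import numpy as np
import pytest

from epolr import (
    CohortConfig,
    CohortTable,
    OrdinalScale,
    TransformationSpec,
    fit,
    fixture_small_trial,
    generate_cohort,
)


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Silence expected small-sample warnings (few observations per stratum)
    so test output stays readable; errors still propagate."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*fewer than.*basis",
                                category=UserWarning)
        warnings.filterwarnings("ignore", message=".*did not report.*",
                                category=UserWarning)
        yield


@pytest.fixture(scope="session")
def small_trial() -> CohortTable:
    return fixture_small_trial(seed=7)


@pytest.fixture(scope="session")
def small_spec(small_trial) -> TransformationSpec:
    return TransformationSpec(
        scale=OrdinalScale(10), strata_levels=("all",), n_params=4,
        baseline_varying=True, baseline_range=(0.0, 10.0))


@pytest.fixture(scope="session")
def selfcare_cohort():
    """A moderate single-stratum cohort plus its generating truth."""
    return generate_cohort(CohortConfig(preset="scim_selfcare",
                                        n_subjects=300, seed=20))


@pytest.fixture(scope="session")
def selfcare_null_fit(selfcare_cohort):
    table, truth = selfcare_cohort
    return fit(table, truth["spec"], include_treatment=False,
               compute_vcov=False)


@pytest.fixture(scope="session")
def binary_cohort():
    """Binary-outcome cohort for the logistic-regression reduction."""
    rng = np.random.default_rng(2)
    n = 300
    x = rng.integers(0, 2, n)
    # P(Y = 0 | x) = expit(-0.3 + 0.8 x)
    y = (rng.random(n) >= 1.0 / (1.0 + np.exp(0.3 - 0.8 * x))).astype(int)
    table = CohortTable(baseline=np.zeros(n), outcome=y,
                        stratum=np.array(["all"] * n, dtype=object), arm=x)
    spec = TransformationSpec(scale=OrdinalScale(1), strata_levels=("all",),
                              n_params=2, baseline_varying=False)
    return table, spec
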