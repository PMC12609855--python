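import numpy as np
import pandas as pd
import pytest

from lipidval import cohort, models


def make_labelled_cohort(n, drift_intercept=0.0, drift_slope=1.0,
                         model=models.NONHDL_MODEL, seed=0):
    """Synthetic cohort with outcomes drawn under known calibration drift."""
    spec = cohort.CohortSpec(n=n, seed=seed)
    df = cohort.generate_cohort(spec)
    sim = cohort.OutcomeSimSpec(
        true_model=model, drift_intercept=drift_intercept,
        drift_slope=drift_slope, seed=seed + 1,
    )
    return cohort.simulate_outcomes(df, sim)


@pytest.fixture(scope="session")
def calibrated_cohort_20k():
    """Perfectly calibrated non-HDL-C cohort, n=20,000."""
    return make_labelled_cohort(20_000, seed=11)


@pytest.fixture(scope="session")
def drifted_cohort_20k():
    """Cohort with planted miscalibration (slope 0.71), n=20,000."""
    return make_labelled_cohort(20_000, drift_slope=0.71, seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    """Unlabelled cohort of 500 for schema/plumbing tests."""
    return cohort.generate_cohort(cohort.CohortSpec(n=500, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
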