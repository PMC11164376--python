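import numpy as np
import pytest

from tonelearn.behavior_metrics import trim_rt
from tonelearn.synthetic_cohort import (
    CohortConfig,
    sample_cohort,
    simulate_cohort_ospan,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic participants with default study conditions."""
    return sample_cohort(6, CohortConfig(), rng_seed=9)


@pytest.fixture(scope="session")
def small_trials(small_cohort):
    """Full three-session trial table for the small cohort."""
    return simulate_experiment(small_cohort, rng_seed=10)


@pytest.fixture(scope="session")
def small_ospan(small_cohort):
    trials, scores = simulate_cohort_ospan(small_cohort, rng_seed=11)
    return trials, scores


@pytest.fixture(scope="session")
def session1_trimmed(small_trials):
    return trim_rt(small_trials[small_trials["session"] == 1])


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
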