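import warnings

import numpy as np
import pytest

from eegsel.features import build_feature_table
from eegsel.montage import standard_montage
from eegsel.synthetic import CohortSpec, simulate_cohort


@pytest.fixture(scope="session")
def montage():
    return standard_montage()


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale cohort spec reused by evaluation/search tests."""
    return CohortSpec(n_per_group=4, epochs_per_subject=3, fs=125.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    subjects, labels = simulate_cohort(small_spec)
    return subjects, labels


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Full 1500-column feature table of the small cohort."""
    subjects, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return build_feature_table(subjects)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
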