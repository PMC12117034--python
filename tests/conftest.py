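import numpy as np
import pytest

from rilipred.synthetic import CohortConfig, sample_feature_table


@pytest.fixture(scope="session")
def default_cohort():
    """A full-size synthetic cohort (129 no-RILI / 113 RILI), fixed seed."""
    return sample_feature_table(CohortConfig(seed=20250527))


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled cohort for fast model-fitting tests."""
    return sample_feature_table(CohortConfig(n_rili=40, n_no_rili=45, seed=11))


@pytest.fixture(scope="session")
def train_cohort_159():
    """A 159-row cohort in the published 74:85 stratified proportions."""
    return sample_feature_table(CohortConfig(n_rili=74, n_no_rili=85, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
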