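import numpy as np
import pandas as pd
import pytest

from harmalloc.choice_model import SubjectParams, simulate_choices
from harmalloc.synthetic_data import generate_cohort
from harmalloc.task_design import DesignConfig, sample_design


@pytest.fixture(scope="session")
def design_150():
    """A standard 150-trial session design (50 pairs x 3 default conditions)."""
    return sample_design(DesignConfig(seed=7))


@pytest.fixture(scope="session")
def small_cohort(design_150):
    """8-subject synthetic cohort with known truths, shared across tests."""
    params, cohort = generate_cohort(n_subjects=8, design=design_150, seed=31)
    return params, cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(20259)
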