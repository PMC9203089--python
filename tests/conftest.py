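import numpy as np
import pytest

from biliphone import (
    CohortConfig,
    CohortFeatures,
    generate_cohort_memory,
    noiseless,
    process_capture_set,
)
from biliphone.synth import recovery_cohort_config


@pytest.fixture(scope="session")
def small_noiseless_cohort():
    """20-patient noiseless cohort: metadata, capture sets, calibrated images, truth."""
    config = noiseless(CohortConfig(n_patients=20, seed=5))
    patients, captures, truth = generate_cohort_memory(config)
    images = {pid: process_capture_set(c) for pid, c in captures.items()}
    return patients, captures, images, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """Fixed-pigmentation low-noise n=60 cohort for end-to-end recovery checks."""
    config = recovery_cohort_config()
    patients, captures, truth = generate_cohort_memory(config)
    images = {pid: process_capture_set(c) for pid, c in captures.items()}
    cohort = CohortFeatures(patients, images)
    return patients, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
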