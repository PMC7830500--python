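import numpy as np
import pytest

from neuroexpertise.fnirs_prep import preprocess_cohort
from neuroexpertise.synthdata import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A 30-trial cohort with a strong class effect, shared across tests."""
    return CohortConfig(
        n_participants=6, class_counts=(2, 2, 2), n_trials=5,
        effect_size=2.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_preprocessed(small_cohort):
    return preprocess_cohort(small_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
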