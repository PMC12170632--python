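import numpy as np
import pytest

from musclesyn import SynthConfig, generate_cohort, make_ground_truth


@pytest.fixture(scope="session")
def default_config():
    return SynthConfig()


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 3 subjects x 4 trials, otherwise study defaults."""
    return SynthConfig(n_subjects=3, n_trials=4, seed=7)


@pytest.fixture(scope="session")
def ground_truth(default_config):
    return make_ground_truth(default_config)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def emg_trials(small_cohort):
    return [t for t in small_cohort if t.modality == "emg" and t.subject_id == "S00"]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
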