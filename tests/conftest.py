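import numpy as np
import pytest

from choughs.core_io import StudyConfig, derive_seed
from choughs.synthetic_data import default_calibration, generate_bundle


@pytest.fixture(scope="session")
def study() -> StudyConfig:
    return StudyConfig()


@pytest.fixture(scope="session")
def fast_study() -> StudyConfig:
    """Study config with small Monte-Carlo budgets for quick tests."""
    return StudyConfig(reps_mixed_null=500, reps_chisq=500)


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def bundle(study, calibration):
    """One packaged-calibration synthetic study, generated once per session."""
    return generate_bundle(study, calibration, derive_seed(1, "generate"))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
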