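import numpy as np
import pytest

from fcbench import GeneratorConfig, make_folds
from fcbench.synthetic import generate_cohort, generate_full_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully realistic cohort (FC + SC + cognition), shared across
    unit tests: 30 subjects, 16 parcels, 400 time points."""
    cfg = GeneratorConfig(n_subjects=30, atlas="toy16", T=400, rho_target=0.65, seed=42)
    return generate_full_cohort(cfg)


@pytest.fixture(scope="session")
def small_folds(small_cohort):
    return make_folds(len(small_cohort), 5, seed=7)


@pytest.fixture(scope="session")
def dk_cohort():
    """Cohort at the anatomical-atlas study conditions: 100 subjects,
    68 parcels, T=1000, inter-eFC calibrated to 0.70."""
    cfg = GeneratorConfig(n_subjects=100, atlas="dk_like", T=1000, rho_target=0.70, seed=1)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def dk_folds(dk_cohort):
    return make_folds(len(dk_cohort), 10, seed=1)
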