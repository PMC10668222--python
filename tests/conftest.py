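import numpy as np
import pytest

from tooltouch.behavior import ParticipantPriors, StudyDesign, generate_cohort
from tooltouch.network import build_network
from tooltouch.rod_modes import build_feature_space


@pytest.fixture(scope="session")
def feature_space():
    """Motif table on the 1% grid (shared; construction is cheap but repeated)."""
    return build_feature_space()


@pytest.fixture(scope="session")
def network():
    """Fully built network with solved decoder weights (expensive; share it)."""
    return build_network()


@pytest.fixture(scope="session")
def small_cohort():
    """A small trilateration-generated cohort with its true parameters."""
    design = StudyDesign(n_participants=6)
    df, roster = generate_cohort(design, ParticipantPriors(), seed=123)
    return design, df, roster


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
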