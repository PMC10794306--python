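import numpy as np
import pytest

from eegtda import StudyConfig
from eegtda.workflows import profiles_frame, study_features

# Full-effect recovery study: the cohort imbalance of a realistic pilot
# (10 healthy / 13 impaired), 2 sessions per subject to keep the suite
# fast, full 2-s epochs. Shared session-wide because feature extraction
# dominates the suite's runtime.
RECOVERY_CONFIG = StudyConfig(n_subjects=23, n_mci=13, n_sessions=2,
                              effect_size=1.0, master_seed=11)


@pytest.fixture(scope="session")
def recovery_study():
    """(profiles DataFrame, per-epoch feature table) at effect_size=1."""
    profiles, table = study_features(RECOVERY_CONFIG)
    return profiles_frame(profiles), table


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
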