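import numpy as np
import pytest

from kinedecode import synth
from kinedecode.kinematics import zscore_within_responder


@pytest.fixture(scope="session")
def small_cohort():
    """5 synthetic responders, 2 sessions, planted idiosyncratic effects.

    Returns (trials_df, X_zscored, profiles).
    """
    profiles = synth.make_cohort(5, 7, effect_scale=0.8)
    trials, X = synth.simulate_dataset(profiles, 2, 8)
    Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())
    return trials, Xz, profiles


@pytest.fixture(scope="session")
def null_cohort():
    """3 zero-signal responders (no kinematics-label association)."""
    profiles = synth.make_cohort(3, 21, effect_scale=0.0)
    trials, X = synth.simulate_dataset(profiles, 2, 22)
    Xz, _ = zscore_within_responder(X, trials["responder"].to_numpy())
    return trials, Xz, profiles


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
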