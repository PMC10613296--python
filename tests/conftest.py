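import numpy as np
import pandas as pd
import pytest

from ambinet.datasets import BehavioralSession
from ambinet.simulate import (
    BehaviorTruth,
    EEGTruth,
    SpikeTruth,
    gen_behavior,
    gen_eeg_epochs,
    gen_spikes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def behavior_session():
    """Moderate-size simulated participant with known psychometric truth."""
    return gen_behavior(BehaviorTruth(n_trials_per_level=200, seed=7))


@pytest.fixture(scope="session")
def small_spikes():
    """Small two-condition-modulated spike dataset (ambiguity-preferring)."""
    return gen_spikes(
        SpikeTruth(
            n_neurons=5,
            baseline_rate=5.0,
            modulation_per_level=3.0,
            onset_latency_s=0.2,
            n_trials_per_level=40,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def default_epochs():
    """Default synthetic EEG epochs (coherence gradient + CFC gradient)."""
    return gen_eeg_epochs(EEGTruth(n_trials_per_condition=40, seed=5))


def make_session(morph, choice, rt, participant_id="p0", **extra):
    trials = pd.DataFrame(
        {"morph_pct": morph, "choice": choice, "rt_s": rt, **extra}
    )
    return BehavioralSession(participant_id, trials)
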