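import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import pdscreen as pds

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def vowel_default():
    """One simulated vowel (defaults: 150 Hz, 1% jitter, 3% shimmer, 25 dB HNR)."""
    rec, truth = pds.simulate_vowel(pds.VowelSimSpec(seed=1))
    return rec, truth


@pytest.fixture(scope="session")
def vowel_preprocessed(vowel_default):
    rec, truth = vowel_default
    return pds.preprocess_voice(rec), truth


@pytest.fixture(scope="session")
def vowel_track(vowel_preprocessed):
    rec, _ = vowel_preprocessed
    return pds.estimate_f0_track(rec)


@pytest.fixture(scope="session")
def vowel_features(vowel_preprocessed, vowel_track):
    rec, _ = vowel_preprocessed
    return pds.compute_voice_features(rec, track=vowel_track)


@pytest.fixture()
def sine_recording():
    """10 s pure 5 Hz acceleration sine along x at 100 Hz, amplitude 9.8696."""
    t = np.arange(0, 10, 0.01)
    a = 9.8696 * np.sin(2 * np.pi * 5 * t)
    zero = np.zeros_like(a)
    return pds.AccelRecording(a, zero.copy(), zero.copy(), fs=100.0)
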