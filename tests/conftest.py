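import numpy as np
import pytest

import epwv


@pytest.fixture(scope="session")
def presets():
    return epwv.default_presets()


@pytest.fixture(scope="session")
def model():
    return epwv.calibrate_models()


@pytest.fixture(scope="session")
def agbresa_subject(presets):
    """One fixed bedrest-preset subject used across signal tests."""
    rng = np.random.default_rng(11)
    return epwv.draw_cohort(presets["agbresa"], seed=None, rng=rng).subjects()[0]


@pytest.fixture(scope="session")
def clean_bundle(agbresa_subject):
    """Noise-free 1 kHz recording of the fixed subject."""
    return epwv.synthesize_recording(
        agbresa_subject, rng=np.random.default_rng(12),
        config=epwv.SignalConfig(noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_bundle(agbresa_subject):
    """Default-noise (2%) recording of the fixed subject."""
    return epwv.synthesize_recording(
        agbresa_subject, rng=np.random.default_rng(13),
        config=epwv.SignalConfig(noise_sd=0.02))


def truth_errors(bundle, fset):
    """Per-beat detection-minus-truth errors (seconds) for valid beats."""
    truth = {a.beat_index: a for a in bundle.truth}
    valid = fset.valid
    idx = valid["beat_index"].to_numpy()
    return {
        "r": valid["t_r_hat"].to_numpy() - np.array([truth[i].t_r for i in idx]),
        "valve": valid["t_valve_hat"].to_numpy() - np.array([truth[i].t_valve for i in idx]),
        "foot": valid["t_foot_hat"].to_numpy() - np.array([truth[i].t_foot for i in idx]),
    }
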