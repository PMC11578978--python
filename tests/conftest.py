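import numpy as np
import pytest

from adhdm import SignalGenConfig, SubjectSpec, simulate_subject_signals
from adhdm.model import published_model


@pytest.fixture(scope="session")
def model():
    return published_model()


@pytest.fixture(scope="session")
def clean_subject_signals():
    """One noiseless simulated subject with gentle autonomic modulation."""
    spec = SubjectSpec("S001", "TD", "female", 9, seed=7)
    cfg = SignalGenConfig(baseline_s=180.0, stress_s=120.0,
                          mean_hr_bpm=90.0, lf_amp_s=0.01, hf_amp_s=0.02,
                          resp_freq_hz=0.3, pat_ms=200.0)
    return cfg, simulate_subject_signals(spec, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
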