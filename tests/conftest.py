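import numpy as np
import pytest

from patflow.config import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Short noise-free session config for fast deterministic chains."""
    return SynthConfig(
        session_duration=120.0,
        mean_hr=60.0,
        rsa_amplitude=0.0,
        pat_jitter_sd=0.0,
        bp_noise_sd=0.0,
        artifact_rate=0.0,
        ecg_noise_sd=0.0,
        ppg_noise_sd=0.0,
    )
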