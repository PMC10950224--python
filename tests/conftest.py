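import numpy as np
import pytest

from heartmil import SimConfig, synth_recording

RATE = 2000.0


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def clean_recording():
    """Murmur-free recording, 80 bpm, light noise."""
    return synth_recording(SimConfig(heart_rate=80.0, seed=42))


@pytest.fixture(scope="session")
def murmur_recording():
    """Systolic diamond murmur at +6 dB in the 200-450 Hz band."""
    return synth_recording(SimConfig(heart_rate=80.0, murmur_present=True,
                                     murmur_snr=6.0, seed=43))
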