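import numpy as np
import pytest

from aspids import BandSpec, DEFAULT_BAND, self_noise_baseline
from aspids.synth import synth_self_noise

RATE = 44100.0


@pytest.fixture(scope="session")
def band():
    return DEFAULT_BAND


@pytest.fixture(scope="session")
def legacy_band():
    return BandSpec(500.0, 6000.0)


@pytest.fixture(scope="session")
def reference_recording():
    """A 5 s, 5-channel (4 piezo + external mic) self-noise reference."""
    rng = np.random.default_rng(42)
    return synth_self_noise(5.0, RATE, rng, rms_scale=1e-3, n_channels=5)


@pytest.fixture(scope="session")
def baseline(reference_recording, band):
    return self_noise_baseline(reference_recording, band)
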