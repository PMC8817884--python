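import numpy as np
import pytest

from anesdepth.preprocess import RawRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """Pure 10 Hz tone, 12 s at 125 Hz."""
    fs = 125.0
    t = np.arange(int(12 * fs)) / fs
    return RawRecording(np.sin(2 * np.pi * 10 * t), fs, subject_id="tone")


@pytest.fixture
def noise_recording(rng):
    fs = 125.0
    return RawRecording(rng.standard_normal(int(20 * fs)), fs, subject_id="noise")
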