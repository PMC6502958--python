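import numpy as np
import pytest

from pupilrqa import RawPupilRecording, SynthesisParams, generate_recording


@pytest.fixture(scope="session")
def clean_recording():
    """Noiseless, blink-free synthetic recording (one LF + one HF tone)."""
    params = SynthesisParams(
        duration=300.0, fs=240.0,
        lf_components=[(0.05, 1.5, 0.0)], hf_components=[(0.30, 0.8, 0.4)],
        noise_sd=0.0, blink_rate=0.0, spike_rate=0.0, drift_amplitude=0.0,
        seed=0)
    return generate_recording(params)


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-condition recording: blinks, spikes, drift and noise."""
    params = SynthesisParams(duration=300.0, seed=11,
                             lf_components=[(0.05, 1.5, 0.0)],
                             hf_components=[(0.30, 0.8, 0.4)])
    return generate_recording(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(diameter, fs=240.0):
    d = np.asarray(diameter, dtype=float)
    return RawPupilRecording(np.arange(d.size) / fs, d, fs)
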