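import numpy as np
import pytest

from brainstates.preprocess import ParcelRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tone(freq, fs=250.0, duration=8.0, n_parcels=1, amplitude=1.0, phase=0.0):
    """Recording whose parcels all carry one pure sinusoid."""
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(amplitude * np.sin(2 * np.pi * freq * t + phase), (n_parcels, 1))
    return ParcelRecording("tone", data, fs)


def make_noise(rng, fs=250.0, duration=8.0, n_parcels=3, sd=1.0):
    data = rng.normal(0.0, sd, size=(n_parcels, int(duration * fs)))
    return ParcelRecording("noise", data, fs)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
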