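import numpy as np
import pytest

from sinkindex.io import CANONICAL_19, Recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_recording(rng):
    """19-channel white-noise recording, 20 s at 250 Hz."""
    data = rng.normal(0.0, 10.0, (19, 5000))
    return Recording("noise", list(CANONICAL_19), 250.0, data)


def sine_recording(freq_hz, fs=250.0, duration_s=20.0, amplitude=1.0, n_channels=19):
    t = np.arange(int(duration_s * fs)) / fs
    wave = amplitude * np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(wave, (n_channels, 1))
    return Recording(f"sine{freq_hz:g}", list(CANONICAL_19[:n_channels]), fs, data)
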