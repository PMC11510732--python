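import numpy as np
import pytest

from aleewr.io import TEN_TWENTY_19, Epoch, Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_tone():
    """sin(2*pi*5t) + sin(2*pi*40t) at 250 Hz, 5000 samples (20 s)."""
    fs = 250.0
    t = np.arange(5000) / fs
    return np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 40 * t), fs


@pytest.fixture
def noise_epoch(rng):
    """A 19-channel seeded noise epoch of 5000 samples at 250 Hz."""
    data = rng.standard_normal((19, 5000))
    return Epoch(data=data, fs=250.0, label="healthy", subject_id="s1",
                 channel_labels=TEN_TWENTY_19)


@pytest.fixture
def small_recording(rng):
    """2-channel 100-sample recording for IO round trips."""
    return Recording(data=rng.standard_normal((2, 100)), fs=250.0,
                     channel_labels=("ch1", "ch2"))


def ar2(rng, n, f0, radius, fs):
    """Tiny AR(2) resonator helper shared by a few tests."""
    from scipy.signal import lfilter

    theta = 2 * np.pi * f0 / fs
    b, a = [1.0], [1.0, -2 * radius * np.cos(theta), radius ** 2]
    x = lfilter(b, a, rng.standard_normal(n + 200))[200:]
    return x / x.std()
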