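import numpy as np
import pytest
from hypothesis import settings

from hhteeg.io_stream import Signal

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

RATE = 128.0
EPOCH_N = 1024  # 8 s at 128 Hz


@pytest.fixture(scope="session")
def t8():
    """Time axis of one 8-s epoch at 128 Hz."""
    return np.arange(EPOCH_N) / RATE


@pytest.fixture
def tone_signal(t8):
    """Factory for pure-tone epochs."""

    def make(freq, amp=1.0, phase=0.0, rate=RATE):
        return Signal(amp * np.cos(2 * np.pi * freq * t8 + phase), rate=rate)

    return make


def interior(n, frac=0.8):
    """Slice selecting the central ``frac`` of ``n`` samples."""
    k = int(n * (1 - frac) / 2)
    return slice(k, n - k)
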