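import numpy as np
import pytest

from sleepsift.tqwt import TQWTParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params_osc():
    """High-Q preset (Q=5.5, r=3) at a moderate depth."""
    return TQWTParams.from_q(5.5, 3.0, 12)


@pytest.fixture
def params_trans():
    """Low-Q preset (Q=1, r=3)."""
    return TQWTParams.from_q(1.0, 3.0, 8)


def make_tone(freq: float, dur_s: float, fs: float, amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(dur_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def make_biphasic(dur_s: float, trough: float, fs: float) -> np.ndarray:
    """Negative then half-amplitude positive squared-sine lobes."""
    n = int(dur_s * fs)
    half = n // 2
    t1 = np.arange(half) / half
    t2 = np.arange(n - half) / (n - half)
    return np.concatenate(
        [trough * np.sin(np.pi * t1) ** 2, 0.5 * abs(trough) * np.sin(np.pi * t2) ** 2]
    )
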