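"""K-complex detection on the transient component.

The transient component is band-pass filtered (0.5-5 Hz, zero-phase FIR),
its strict local minima are thresholded at a negative amplitude, minima
closer than 2 s are resolved in favour of the deeper trough, and events are
grown from zero crossings around each retained trough.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.signal import filtfilt, firwin

from .errors import ParameterError, SamplingError
from .events import Event

__all__ = [
    "KCDetectorConfig",
    "bandpass_fir",
    "local_minima_1d",
    "detect_kcomplexes",
]

MIN_KC_DURATION_S = 0.5
FALLBACK_HALF_EXTENT_S = 0.75


@dataclass
class KCDetectorConfig:
    band_low: float = 0.5
    band_high: float = 5.0
    threshold: float = -70.0
    min_separation_s: float = 2.0
    filter_order: int | None = None  # taps; default ~= 3 * fs / band_low

    def __post_init__(self) -> None:
        if self.threshold >= 0:
            raise ParameterError(f"threshold must be negative, got {self.threshold}")
        if self.min_separation_s < 0:
            raise ParameterError("min_separation_s must be >= 0")
        if not 0 < self.band_low < self.band_high:
            raise ParameterError("need 0 < band_low < band_high")

    def taps(self, fs: float) -> int:
        n = self.filter_order if self.filter_order else int(round(3 * fs / self.band_low))
        return n + 1 - n % 2  # odd tap count for a symmetric type-I FIR


def bandpass_fir(x: Sequence[float], fs: float, cfg: KCDetectorConfig) -> np.ndarray:
    """Zero-phase windowed-sinc band-pass; output length equals input length."""
    if fs <= 2 * cfg.band_high:
        raise SamplingError(
            f"fs={fs} too low for band edge {cfg.band_high} Hz"
        )
    x = np.asarray(x, dtype=float)
    taps = firwin(cfg.taps(fs), [cfg.band_low, cfg.band_high], pass_zero=False, fs=fs)
    padlen = min(3 * len(taps), x.size - 1)
    return filtfilt(taps, 1.0, x, padlen=padlen)


def local_minima_1d(x: Sequence[float]) -> List[tuple[int, float]]:
    """Strict local minima: x[i] < x[i-1] and x[i] < x[i+1]."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return []
    c = x[1:-1]
    mask = (c < x[:-2]) & (c < x[2:])
    idx = np.nonzero(mask)[0] + 1
    return [(int(i), float(x[i])) for i in idx]


def _event_extent(
    y: np.ndarray, fs: float, trough: int
) -> tuple[float, float]:
    """Extent from the zero crossing before the trough to the first zero
    crossing after the subsequent positive peak, with a +-0.75 s fallback."""
    n = y.size
    # last non-negative sample before the trough
    start = None
    for i in range(trough - 1, -1, -1):
        if y[i] >= 0:
            start = i
            break
    # first upward zero crossing after the trough
    up = None
    for i in range(trough + 1, n):
        if y[i] >= 0:
            up = i
            break
    end = None
    if up is not None:
        # ride to the positive peak, then to the next downward crossing
        i = up
        while i + 1 < n and y[i + 1] >= y[i]:
            i += 1
        for k in range(i + 1, n):
            if y[k] <= 0:
                end = k
                break
        if end is None and i < n - 1:
            end = n - 1

    t = trough / fs
    start_s = start / fs if start is not None else t - FALLBACK_HALF_EXTENT_S
    end_s = end / fs if end is not None else t + FALLBACK_HALF_EXTENT_S
    # duration floor: extend symmetrically around the trough
    if end_s - start_s < MIN_KC_DURATION_S:
        deficit = MIN_KC_DURATION_S - (end_s - start_s)
        start_s -= deficit / 2
        end_s += deficit / 2
    return max(start_s, 0.0), min(end_s, (n - 1) / fs + 1.0 / fs)


def detect_kcomplexes(
    transient_filtered: Sequence[float],
    fs: float,
    cfg: KCDetectorConfig,
    segment_id: int = 0,
) -> List[Event]:
    """Threshold the filtered transient's local minima into K-complex events.

    Minima with value <= cfg.threshold are candidates; among any pair of
    candidates closer than cfg.min_separation_s the deeper trough wins.
    Events are then required to be mutually >= min_separation_s apart
    onset-to-onset (again resolved by depth).
    """
    y = np.asarray(transient_filtered, dtype=float)
    minima = [(i, v) for i, v in local_minima_1d(y) if v <= cfg.threshold]
    if not minima:
        return []

    # deeper troughs claim their 2-s neighbourhood first
    min_gap = cfg.min_separation_s * fs
    kept: List[tuple[int, float]] = []
    for i, v in sorted(minima, key=lambda m: m[1]):
        if all(abs(i - j) >= min_gap for j, _ in kept):
            kept.append((i, v))

    events = []
    for i, v in sorted(kept):
        start_s, end_s = _event_extent(y, fs, i)
        events.append(
            Event(
                kind="kcomplex",
                segment_id=segment_id,
                start_s=start_s,
                end_s=end_s,
                peak_value=v,
                peak_time_s=i / fs,
            )
        )

    # extents may stretch onsets closer together than the trough spacing
    final: List[Event] = []
    for ev in sorted(events, key=lambda e: e.peak_value):
        if all(
            abs(ev.start_s - other.start_s) >= cfg.min_separation_s for other in final
        ):
            final.append(ev)
    final.sort(key=lambda e: e.start_s)
    return final
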