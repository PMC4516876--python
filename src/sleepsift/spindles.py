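"""Sleep spindle detection on the oscillatory component.

A continuous wavelet transform with a complex frequency B-spline mother
wavelet produces a time-frequency map restricted to the 11-16 Hz spindle
band; strict 8-neighbour local maxima of the squared magnitude are
thresholded (in uV^2) and grown into events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import InputError, ParameterError, SamplingError
from .events import Event

__all__ = [
    "FbspParams",
    "TFMap",
    "fbsp_wavelet",
    "cwt_tfmap",
    "local_maxima_2d",
    "detect_spindles",
    "waveform_crosscorr",
    "default_freq_grid",
]

SPINDLE_BAND = (11.0, 16.0)
MIN_SPINDLE_DURATION_S = 0.5
DEFAULT_FREQ_STEP_HZ = 0.25
#: event extent: contiguous time span where the per-time band maximum stays
#: above this fraction of the triggering peak (25%: a 50% cut truncates
#: tapered bursts below the 0.5 s duration floor)
EXTENT_DROP_FRACTION = 0.25
MERGE_GAP_S = 0.25


@dataclass(frozen=True)
class FbspParams:
    """Order, bandwidth and centre-frequency of the B-spline wavelet."""

    m: int = 25
    fb: float = 1.0
    fc: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ParameterError(f"m must be an integer >= 1, got {self.m}")
        if self.fb <= 0 or self.fc <= 0:
            raise ParameterError("fb and fc must be positive")


@dataclass
class TFMap:
    """Squared CWT magnitude (uV^2), frequency rows by time columns."""

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    segment_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != (len(self.freqs), len(self.times)):
            raise InputError("values shape must be (n_freqs, n_times)")


def default_freq_grid(step: float = DEFAULT_FREQ_STEP_HZ) -> np.ndarray:
    lo, hi = SPINDLE_BAND
    return np.arange(lo, hi + step / 2, step)


def fbsp_wavelet(t: Sequence[float], params: FbspParams) -> np.ndarray:
    """fb * sinc(t*fb/m)^m * exp(2j*pi*fc*t) with sinc(0) = 1."""
    t = np.asarray(t, dtype=float)
    env = params.fb * np.sinc(t * params.fb / params.m) ** params.m
    return env * np.exp(2j * np.pi * params.fc * t)


def _scaled_wavelet(freq: float, fs: float, params: FbspParams) -> np.ndarray:
    """Wavelet resampled so its pseudo-frequency fc*fs/scale equals `freq`.

    Normalised so that a pure sinusoid of amplitude A at `freq` yields a
    squared-magnitude response of A^2 (i.e. map units are uV^2 of envelope
    amplitude squared).
    """
    scale = params.fc * fs / freq
    # support out to the first zero of the sinc envelope: |t| <= m/fb
    half = int(np.ceil(scale * params.m / params.fb))
    n = np.arange(-half, half + 1)
    psi = fbsp_wavelet(n / scale, params)
    return psi * (2.0 / np.sum(np.abs(psi)))


def cwt_tfmap(
    osc: Sequence[float],
    fs: float,
    freq_grid: Sequence[float] | None = None,
    params: FbspParams = FbspParams(),
    segment_id: int = 0,
) -> TFMap:
    """Time-frequency map of the oscillatory component over the spindle band."""
    x = np.asarray(osc, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("osc must be a non-empty 1-D array")
    if fs <= 32.0:
        raise SamplingError(f"fs must exceed 32 Hz, got {fs}")
    freqs = default_freq_grid() if freq_grid is None else np.asarray(freq_grid, float)
    lo, hi = SPINDLE_BAND
    if np.any(freqs < lo) or np.any(freqs > hi):
        raise ParameterError(f"frequency grid must lie within [{lo}, {hi}] Hz")
    freqs = np.sort(freqs)

    rows = np.empty((len(freqs), x.size))
    for i, f in enumerate(freqs):
        psi = _scaled_wavelet(f, fs, params)
        coef = fftconvolve(x.astype(complex), np.conj(psi[::-1]), mode="same")
        rows[i] = np.abs(coef) ** 2
    times = np.arange(x.size) / fs
    return TFMap(values=rows, freqs=freqs, times=times, segment_id=segment_id)


def local_maxima_2d(tfmap: TFMap) -> List[tuple[int, int, float]]:
    """Strict 8-neighbour maxima of the interior, sorted by descending value.

    Returns (time index, frequency index, value) triples.  Border cells are
    excluded since they lack a full neighbourhood; plateaus yield nothing.
    """
    v = tfmap.values
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise InputError("map must be at least 3x3")
    c = v[1:-1, 1:-1]
    mask = (
        (c > v[:-2, :-2]) & (c > v[:-2, 1:-1]) & (c > v[:-2, 2:])
        & (c > v[1:-1, :-2]) & (c > v[1:-1, 2:])
        & (c > v[2:, :-2]) & (c > v[2:, 1:-1]) & (c > v[2:, 2:])
    )
    fi, ti = np.nonzero(mask)
    fi += 1
    ti += 1
    vals = v[fi, ti]
    order = np.argsort(-vals)
    return [(int(ti[k]), int(fi[k]), float(vals[k])) for k in order]


def detect_spindles(
    tfmap: TFMap,
    threshold: float,
    max_duration_s: float | None = None,
) -> List[Event]:
    """Threshold T-F maxima and grow them into spindle events.

    Around each supra-threshold maximum the event spans the contiguous time
    interval where the per-time maximum across frequencies stays above
    EXTENT_DROP_FRACTION of the triggering peak.  Overlapping events or
    events separated by less than MERGE_GAP_S are merged; events shorter
    than 0.5 s are discarded.
    """
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    maxima = local_maxima_2d(tfmap)
    col_max = tfmap.values.max(axis=0)
    times = tfmap.times
    n = len(times)
    dt = float(times[1] - times[0]) if n > 1 else 1.0

    intervals: List[tuple[int, int, float, float]] = []  # i0, i1, peak, t_peak
    for ti, fi, val in maxima:
        if val <= threshold:
            break  # maxima sorted descending
        floor = EXTENT_DROP_FRACTION * val
        i0 = ti
        while i0 > 0 and col_max[i0 - 1] >= floor:
            i0 -= 1
        i1 = ti
        while i1 < n - 1 and col_max[i1 + 1] >= floor:
            i1 += 1
        intervals.append((i0, i1, val, float(times[ti])))

    if not intervals:
        return []
    intervals.sort(key=lambda iv: iv[0])
    gap = int(round(MERGE_GAP_S / dt))
    merged = [list(intervals[0])]
    for i0, i1, val, tp in intervals[1:]:
        last = merged[-1]
        if i0 <= last[1] + gap:
            last[1] = max(last[1], i1)
            if val > last[2]:
                last[2], last[3] = val, tp
        else:
            merged.append([i0, i1, val, tp])

    events = []
    for i0, i1, val, tp in merged:
        start = float(times[i0])
        end = float(times[i1]) + dt
        dur = end - start
        if dur < MIN_SPINDLE_DURATION_S:
            continue
        if max_duration_s is not None and dur > max_duration_s:
            continue
        events.append(
            Event(
                kind="spindle",
                segment_id=tfmap.segment_id,
                start_s=start,
                end_s=end,
                peak_value=val,
                peak_time_s=tp,
            )
        )
    return events


def waveform_crosscorr(
    waveforms: Sequence[Sequence[float]],
    candidates: dict[str, np.ndarray] | None = None,
    fs: float = 200.0,
) -> dict[str, dict[str, object]]:
    """Peak normalised cross-correlation of snippets against candidate wavelets.

    For each snippet and each candidate waveform, the maximum of the
    normalised cross-correlation (in [-1, 1]) is recorded; per-candidate
    median and max summarise the distribution.
    """
    if len(waveforms) == 0:
        raise InputError("need at least one waveform snippet")
    if candidates is None:
        candidates = standard_wavelet_set(fs)

    out: dict[str, dict[str, object]] = {}
    for name, w in candidates.items():
        w = np.asarray(w, dtype=float)
        wn = w / np.linalg.norm(w)
        peaks = []
        for snip in waveforms:
            s = np.asarray(snip, dtype=float)
            if len(s) < 2:
                raise InputError("snippets must have at least 2 samples")
            sn = s / np.linalg.norm(s)
            # unit-norm inputs bound the sliding correlation by Cauchy-Schwarz
            cc = np.correlate(sn, wn, mode="full")
            peaks.append(float(np.max(np.abs(cc))))
        peaks = np.clip(peaks, -1.0, 1.0)
        out[name] = {
            "peaks": np.asarray(peaks),
            "median": float(np.median(peaks)),
            "max": float(np.max(peaks)),
        }
    return out


def standard_wavelet_set(fs: float, centre_hz: float = 13.0) -> dict[str, np.ndarray]:
    """Real parts of the candidate mother wavelets tuned to the spindle band."""
    params = FbspParams()
    fbsp = _scaled_wavelet(centre_hz, fs, params).real

    # complex Morlet, Shannon and Gaussian-derivative counterparts
    dur = len(fbsp) / fs
    t = (np.arange(len(fbsp)) - len(fbsp) // 2) / fs
    morlet = np.cos(2 * np.pi * centre_hz * t) * np.exp(-0.5 * (t / (dur / 8)) ** 2)
    shannon = np.cos(2 * np.pi * centre_hz * t) * np.sinc(t * 4.0)
    gauss = -t / (dur / 8) ** 2 * np.exp(-0.5 * (t / (dur / 8)) ** 2)
    return {"fbsp": fbsp, "cmor": morlet, "shan": shannon, "gauss": gauss}
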