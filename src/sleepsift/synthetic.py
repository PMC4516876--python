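"""Synthetic sleep-EEG-like recordings with exact ground-truth annotations.

Background is 1/f^gamma Gaussian noise; spindle bursts are Gaussian-windowed
11-16 Hz sinusoids and K-complexes are smooth biphasic waves (negative lobe
followed by a half-amplitude positive lobe).  Everything is deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np

from .errors import ParameterError, PlacementError
from .events import Event

__all__ = [
    "SimulationConfig",
    "SyntheticRecording",
    "generate_background",
    "spindle_template",
    "kcomplex_template",
    "generate_recording",
]

SEGMENT_LENGTH_S = 30.0
KC_GUARD_S = 2.0
EDGE_MARGIN_S = 1.0


@dataclass(frozen=True)
class SimulationConfig:
    fs: float = 200.0
    n_segments: int = 10
    spindle_rate: float = 1.0  # expected events per 30-s segment
    kc_rate: float = 1.0
    spindle_freq_range: tuple[float, float] = (11.0, 16.0)
    spindle_dur_range: tuple[float, float] = (0.5, 2.0)
    spindle_amp_range: tuple[float, float] = (20.0, 40.0)  # uV peak envelope
    kc_trough_range: tuple[float, float] = (-120.0, -80.0)  # uV, negative
    kc_dur_range: tuple[float, float] = (0.5, 1.5)
    background_gamma: float = 1.0
    noise_scale: float = 5.0  # uV RMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs < 100:
            raise ParameterError("fs must be >= 100 Hz")
        if self.spindle_rate < 0 or self.kc_rate < 0:
            raise ParameterError("rates must be >= 0")
        for name in (
            "spindle_freq_range",
            "spindle_dur_range",
            "spindle_amp_range",
            "kc_trough_range",
            "kc_dur_range",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.kc_trough_range[1] >= 0:
            raise ParameterError("kc_trough_range must be negative")
        if self.noise_scale < 0:
            raise ParameterError("noise_scale must be >= 0")


@dataclass
class SyntheticRecording:
    signal: np.ndarray
    fs: float
    truth: List[Event]
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def n_segments(self) -> int:
        return int(len(self.signal) / (SEGMENT_LENGTH_S * self.fs))

    def segment(self, i: int) -> np.ndarray:
        n = int(SEGMENT_LENGTH_S * self.fs)
        return self.signal[i * n : (i + 1) * n]

    def truth_for_segment(self, i: int, kind: str | None = None) -> List[Event]:
        """Truth events of segment i, re-timed to segment-local seconds."""
        out = []
        for e in self.truth:
            if e.segment_id == i and (kind is None or e.kind == kind):
                out.append(e.shifted(-i * SEGMENT_LENGTH_S))
        return out


def generate_background(
    n_samples: int,
    fs: float,
    gamma: float = 1.0,
    noise_scale: float = 5.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """1/f^gamma Gaussian noise scaled to `noise_scale` RMS."""
    if n_samples < 2:
        raise ParameterError("n_samples must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    if noise_scale == 0:
        return np.zeros(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    spec[0] = 0.0
    spec[1:] = spec[1:] / freqs[1:] ** (gamma / 2.0)
    x = np.fft.irfft(spec, n_samples)
    return x * (noise_scale / np.sqrt(np.mean(x**2)))


def spindle_template(dur: float, freq: float, amp: float, fs: float) -> np.ndarray:
    """Gaussian-windowed sinusoid with peak envelope `amp` and duration `dur`."""
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    centre = dur / 2.0
    env = amp * np.exp(-0.5 * ((t - centre) / (dur / 5.0)) ** 2)
    return env * np.cos(2 * np.pi * freq * (t - centre))


NEGATIVE_LOBE_FRACTION = 0.4


def kcomplex_template(dur: float, trough_amp: float, fs: float) -> np.ndarray:
    """Smooth biphasic wave: a sharp negative lobe then a slower positive
    lobe at half depth.

    Both lobes are squared-sine bumps (C1-continuous at the junctions); the
    minimum equals `trough_amp` and precedes the maximum.  The negative lobe
    takes 40% of the duration, mirroring the sharp-wave-then-rebound shape.
    """
    if trough_amp >= 0:
        raise ParameterError("trough_amp must be negative")
    n = int(round(dur * fs))
    half = max(int(n * NEGATIVE_LOBE_FRACTION), 1)
    t1 = np.arange(half) / half
    t2 = np.arange(n - half) / max(n - half, 1)
    neg = trough_amp * np.sin(np.pi * t1) ** 2
    pos = 0.5 * abs(trough_amp) * np.sin(np.pi * t2) ** 2
    return np.concatenate([neg, pos])


def _place_events(
    rng: np.random.Generator, cfg: SimulationConfig, seg: int
) -> List[tuple[str, float, float]]:
    """Choose (kind, start_s, dur) placements for one segment.

    Events never overlap; K-complex troughs keep a 2-s guard between each
    other.  Positions are drawn uniformly with rejection; an infeasible
    draw raises PlacementError.
    """
    n_sp = rng.poisson(cfg.spindle_rate)
    n_kc = rng.poisson(cfg.kc_rate)
    placed: List[tuple[str, float, float]] = []

    def fits(kind: str, start: float, dur: float) -> bool:
        for k2, s2, d2 in placed:
            gap = KC_GUARD_S if (kind == "kcomplex" and k2 == "kcomplex") else 0.0
            if start < s2 + d2 + gap and s2 < start + dur + gap:
                return False
        return True

    for kind, count, dur_range in (
        ("kcomplex", n_kc, cfg.kc_dur_range),
        ("spindle", n_sp, cfg.spindle_dur_range),
    ):
        for _ in range(count):
            dur = float(rng.uniform(*dur_range))
            ok = False
            for _attempt in range(200):
                start = float(
                    rng.uniform(
                        EDGE_MARGIN_S, SEGMENT_LENGTH_S - EDGE_MARGIN_S - dur
                    )
                )
                if fits(kind, start, dur):
                    placed.append((kind, start, dur))
                    ok = True
                    break
            if not ok:
                raise PlacementError(
                    f"could not place {kind} in segment {seg} under spacing rules"
                )
    return placed


def generate_recording(cfg: SimulationConfig) -> SyntheticRecording:
    """Background plus injected events, with an exact truth list."""
    rng = np.random.default_rng(cfg.seed)
    seg_n = int(SEGMENT_LENGTH_S * cfg.fs)
    total_n = seg_n * cfg.n_segments
    signal = generate_background(
        total_n, cfg.fs, cfg.background_gamma, cfg.noise_scale, rng
    )

    truth: List[Event] = []
    for seg in range(cfg.n_segments):
        for kind, start, dur in _place_events(rng, cfg, seg):
            t0 = seg * SEGMENT_LENGTH_S + start
            i0 = int(round(t0 * cfg.fs))
            if kind == "spindle":
                freq = float(rng.uniform(*cfg.spindle_freq_range))
                amp = float(rng.uniform(*cfg.spindle_amp_range))
                wave = spindle_template(dur, freq, amp, cfg.fs)
                peak_t = t0 + dur / 2.0
                peak_v = amp
            else:
                trough = float(rng.uniform(*cfg.kc_trough_range))
                wave = kcomplex_template(dur, trough, cfg.fs)
                peak_t = t0 + (np.argmin(wave) / cfg.fs)
                peak_v = trough
            i1 = min(i0 + len(wave), total_n)
            signal[i0:i1] += wave[: i1 - i0]
            truth.append(
                Event(
                    kind=kind,
                    segment_id=seg,
                    start_s=t0,
                    end_s=t0 + dur,
                    peak_value=peak_v,
                    peak_time_s=peak_t,
                )
            )
    truth.sort(key=lambda e: e.start_s)
    return SyntheticRecording(signal=signal, fs=cfg.fs, truth=truth, config=cfg)
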