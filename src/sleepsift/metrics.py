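"""Evaluation and training: event matching, sensitivity/FDR, threshold
sweeps with argmax(Sen - FDR) selection, inter-annotator agreement, and the
RMS baseline spindle detector used for comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Sequence

import numpy as np
from scipy.signal import filtfilt, firwin

from .errors import InputError, ParameterError, UndefinedMetricError
from .events import Event

__all__ = [
    "MatchResult",
    "ThresholdCurve",
    "AgreementReport",
    "match_events",
    "sensitivity",
    "fdr",
    "threshold_sweep",
    "optimal_threshold",
    "agreement",
    "rms_baseline_detect",
]


@dataclass
class MatchResult:
    TP: int
    FP: int
    FN: int
    matched_pairs: List[tuple[Event, Event]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ParameterError("counts must be nonnegative")
        if self.TP != len(self.matched_pairs) and self.matched_pairs:
            raise ParameterError("TP must equal the number of matched pairs")

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            TP=self.TP + other.TP,
            FP=self.FP + other.FP,
            FN=self.FN + other.FN,
            matched_pairs=self.matched_pairs + other.matched_pairs,
        )


def match_events(
    detected: Sequence[Event],
    annotated: Sequence[Event],
    criterion: str = "any-overlap",
) -> MatchResult:
    """Greedy one-to-one matching by largest temporal overlap.

    Any positive overlap qualifies under the default criterion.  Each
    detected event matches at most one annotated event and vice versa.
    """
    if criterion != "any-overlap":
        raise ParameterError(f"unknown matching criterion {criterion!r}")
    ann = sorted(annotated, key=lambda e: e.start_s)
    for a, b in zip(ann, ann[1:]):
        if a.overlap_s(b) > 0:
            warnings.warn("overlapping duplicate annotations; keeping both")
            break

    candidates = []
    for di, d in enumerate(detected):
        for ai, a in enumerate(ann):
            ov = d.overlap_s(a)
            if ov > 0:
                candidates.append((ov, di, ai))
    candidates.sort(key=lambda c: -c[0])

    used_d: set[int] = set()
    used_a: set[int] = set()
    pairs: List[tuple[Event, Event]] = []
    for ov, di, ai in candidates:
        if di in used_d or ai in used_a:
            continue
        used_d.add(di)
        used_a.add(ai)
        pairs.append((detected[di], ann[ai]))

    tp = len(pairs)
    return MatchResult(
        TP=tp, FP=len(detected) - tp, FN=len(ann) - tp, matched_pairs=pairs
    )


def sensitivity(m: MatchResult) -> float:
    """TP / (TP + FN)."""
    if m.TP + m.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no annotated events")
    return m.TP / (m.TP + m.FN)


def fdr(m: MatchResult) -> float:
    """FP / (FP + TP)."""
    if m.TP + m.FP == 0:
        raise UndefinedMetricError("FDR undefined: no detections")
    return m.FP / (m.FP + m.TP)


@dataclass
class ThresholdCurve:
    """Swept thresholds with pooled sensitivity and FDR (NaN = undefined)."""

    thresholds: np.ndarray
    sens: np.ndarray
    fdr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sens = np.asarray(self.sens, dtype=float)
        self.fdr = np.asarray(self.fdr, dtype=float)
        if not len(self.thresholds) == len(self.sens) == len(self.fdr):
            raise InputError("curve arrays must have equal lengths")

    @property
    def best_index(self) -> int:
        diff = self.sens - self.fdr
        if np.all(np.isnan(diff)):
            raise UndefinedMetricError("no threshold with defined Sen and FDR")
        return int(np.nanargmax(diff))  # first index wins ties


def threshold_sweep(
    segments: Sequence,
    annotations: Sequence[Sequence[Event]],
    detector: Callable[[object, float], List[Event]],
    thresholds: Sequence[float],
) -> ThresholdCurve:
    """Pooled Sen/FDR over segments for each threshold value.

    ``detector(segment, threshold)`` returns the events for one segment;
    annotations is the parallel list of ground-truth events.
    """
    if len(segments) != len(annotations):
        raise InputError("segments and annotations must be parallel")
    n_annotated = sum(len(a) for a in annotations)
    if n_annotated == 0:
        raise UndefinedMetricError("threshold sweep needs at least one annotated event")

    thr = np.asarray(list(thresholds), dtype=float)
    sens_v = np.empty(len(thr))
    fdr_v = np.empty(len(thr))
    for k, t in enumerate(thr):
        total = MatchResult(0, 0, 0)
        for seg, ann in zip(segments, annotations):
            total = total + match_events(detector(seg, float(t)), ann)
        sens_v[k] = sensitivity(total)
        try:
            fdr_v[k] = fdr(total)
        except UndefinedMetricError:
            fdr_v[k] = np.nan
    return ThresholdCurve(thresholds=thr, sens=sens_v, fdr=fdr_v)


def optimal_threshold(curve: ThresholdCurve) -> float:
    """Threshold maximising Sen - FDR (first index on ties)."""
    if len(curve.thresholds) == 0:
        raise InputError("empty curve")
    return float(curve.thresholds[curve.best_index])


@dataclass
class AgreementReport:
    percent_agreement: float
    kappa: float


def agreement(
    annotA: Sequence[Event],
    annotB: Sequence[Event],
    segment_ids: Sequence[int],
    kind: str | None = None,
) -> AgreementReport:
    """Percent agreement and Cohen's kappa on per-segment presence/absence.

    Each segment contributes one binary observation per annotator: does it
    contain at least one event (of `kind`, if given)?
    """
    seg_ids = list(segment_ids)
    if not seg_ids:
        raise InputError("need at least one segment")

    def presence(events: Sequence[Event]) -> np.ndarray:
        marked = {e.segment_id for e in events if kind is None or e.kind == kind}
        return np.array([sid in marked for sid in seg_ids], dtype=bool)

    a = presence(annotA)
    b = presence(annotB)
    n = len(seg_ids)
    p_o = float(np.mean(a == b))
    p_yes_a = float(np.mean(a))
    p_yes_b = float(np.mean(b))
    p_e = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    if p_e == 1.0:
        raise UndefinedMetricError("chance agreement is 1; kappa undefined")
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementReport(percent_agreement=100.0 * p_o, kappa=kappa)


def rms_baseline_detect(
    eeg: Sequence[float],
    fs: float,
    T: float,
    band: tuple[float, float] = (12.0, 15.0),
    window_s: float = 0.1,
    duration_s: tuple[float, float] = (0.5, 3.0),
    segment_id: int = 0,
) -> List[Event]:
    """Standard RMS spindle detector used as the comparison baseline.

    Band-pass the EEG, compute the RMS of consecutive 100-ms intervals and
    return maximal runs of RMS values above T whose duration falls within
    [0.5, 3] s.
    """
    if T <= 0:
        raise ParameterError("T must be positive")
    x = np.asarray(eeg, dtype=float)
    # the 3-Hz-wide passband needs a narrow transition: ~2 s of taps
    ntaps = int(round(2 * fs)) | 1
    taps = firwin(ntaps, list(band), pass_zero=False, fs=fs)
    padlen = min(3 * ntaps, x.size - 1)
    y = filtfilt(taps, 1.0, x, padlen=padlen)

    block = int(round(window_s * fs))
    nblocks = x.size // block
    if nblocks == 0:
        return []
    rms = np.sqrt(
        np.mean(y[: nblocks * block].reshape(nblocks, block) ** 2, axis=1)
    )
    above = rms > T

    events = []
    i = 0
    while i < nblocks:
        if above[i]:
            j = i
            while j + 1 < nblocks and above[j + 1]:
                j += 1
            dur = (j - i + 1) * window_s
            if duration_s[0] <= dur <= duration_s[1]:
                k = i + int(np.argmax(rms[i : j + 1]))
                events.append(
                    Event(
                        kind="spindle",
                        segment_id=segment_id,
                        start_s=i * window_s,
                        end_s=(j + 1) * window_s,
                        peak_value=float(rms[k]),
                        peak_time_s=(k + 0.5) * window_s,
                    )
                )
            i = j + 1
        else:
            i += 1
    return events
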