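"""End-to-end detection pipeline.

Per 30-s segment: band-pass preprocessing (0.2-40 Hz), dual-Q morphological
decomposition, spindle detection on the time-frequency map of the
oscillatory component and K-complex detection on the FIR-filtered transient
component.  A `--no-mca` ablation mode skips the decomposition and detects
directly on the preprocessed signal.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import mca as _mca
from .errors import InputError
from .events import Event
from .io import Recording
from .kcomplexes import KCDetectorConfig, bandpass_fir, detect_kcomplexes
from .metrics import ThresholdCurve, optimal_threshold, threshold_sweep
from .spindles import FbspParams, TFMap, cwt_tfmap, detect_spindles

__all__ = [
    "PipelineConfig",
    "SegmentAnalysis",
    "preprocess",
    "preprocess_array",
    "analyze_segment",
    "analyze_recording",
    "run_pipeline",
    "train_thresholds",
]

log = logging.getLogger("sleepsift")

PREPROCESS_BAND = (0.2, 40.0)
SPINDLE_SWEEP_STEP = 10.0  # uV^2
KC_SWEEP_STEP = -2.0  # uV
KC_SWEEP_FLOOR = -200.0


@dataclass
class PipelineConfig:
    """Detection settings; thresholds are normally produced by training."""

    spindle_threshold: float = 100.0  # uV^2 on the T-F map
    kc_threshold: float = -70.0  # uV on the filtered transient
    use_mca: bool = True
    n_iterations: int = _mca.DEFAULT_ITERATIONS
    theta_osc: float = _mca.DEFAULT_THETA
    theta_trans: float = _mca.DEFAULT_THETA
    osc_lowpass_boost: float = _mca.DEFAULT_LOWPASS_BOOST
    osc_min_freq_hz: float = _mca.DEFAULT_OSC_MIN_FREQ_HZ
    fbsp: FbspParams = field(default_factory=FbspParams)
    freq_step_hz: float = 0.25
    max_spindle_duration_s: float | None = None
    kc_band: tuple[float, float] = (0.5, 5.0)
    kc_min_separation_s: float = 2.0

    def kc_config(self, threshold: float | None = None) -> KCDetectorConfig:
        return KCDetectorConfig(
            band_low=self.kc_band[0],
            band_high=self.kc_band[1],
            threshold=self.kc_threshold if threshold is None else threshold,
            min_separation_s=self.kc_min_separation_s,
        )


@dataclass
class SegmentAnalysis:
    """Cached per-segment products so threshold sweeps are cheap."""

    segment_id: int
    fs: float
    x1: np.ndarray  # oscillatory component (or preprocessed signal, no-MCA)
    x2: np.ndarray  # transient component (ditto)
    tfmap: TFMap
    kc_filtered: np.ndarray


def preprocess_array(x: Sequence[float], fs: float) -> np.ndarray:
    """Zero-phase 0.2-40 Hz band-pass; length preserved."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 10:
        raise InputError("need a 1-D signal of at least 10 samples")
    sos = butter(6, PREPROCESS_BAND, btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, x)


def preprocess(rec: Recording) -> Recording:
    return Recording(
        samples=preprocess_array(rec.samples, rec.fs),
        fs=rec.fs,
        channel_label=rec.channel_label,
        segment_length_s=rec.segment_length_s,
    )


def analyze_segment(
    seg: Sequence[float],
    fs: float,
    config: PipelineConfig | None = None,
    segment_id: int = 0,
) -> SegmentAnalysis:
    config = config or PipelineConfig()
    x = preprocess_array(seg, fs)

    if config.use_mca:
        scale = float(np.sqrt(np.mean(x**2)))
        if scale > 0:
            problem = _mca.paper_preset(
                len(x),
                scale,
                fs=fs,
                n_iterations=config.n_iterations,
                theta_osc=config.theta_osc,
                theta_trans=config.theta_trans,
                osc_lowpass_boost=config.osc_lowpass_boost,
                osc_min_freq_hz=config.osc_min_freq_hz,
            )
            result = _mca.dual_q_decompose(x, problem)
            x1, x2 = result.x1, result.x2
        else:
            x1 = np.zeros_like(x)
            x2 = np.zeros_like(x)
    else:
        # ablation: spindle detection on the CWT of the raw signal,
        # K-complex detection on the raw signal itself
        x1 = x
        x2 = x

    freqs = np.arange(11.0, 16.0 + config.freq_step_hz / 2, config.freq_step_hz)
    tfmap = cwt_tfmap(x1, fs, freqs, config.fbsp, segment_id=segment_id)
    kc_filtered = bandpass_fir(x2, fs, config.kc_config())
    return SegmentAnalysis(
        segment_id=segment_id, fs=fs, x1=x1, x2=x2,
        tfmap=tfmap, kc_filtered=kc_filtered,
    )


def analyze_recording(
    rec: Recording, config: PipelineConfig | None = None
) -> List[SegmentAnalysis]:
    analyses = []
    for i in range(rec.n_segments):
        t0 = time.perf_counter()
        a = analyze_segment(rec.segment(i), rec.fs, config, segment_id=i)
        log.info(
            "segment=%d stage=analyze elapsed=%.2fs", i, time.perf_counter() - t0
        )
        analyses.append(a)
    return analyses


def _detect_both(
    analysis: SegmentAnalysis, config: PipelineConfig
) -> tuple[List[Event], List[Event]]:
    spindles = detect_spindles(
        analysis.tfmap,
        config.spindle_threshold,
        max_duration_s=config.max_spindle_duration_s,
    )
    kcs = detect_kcomplexes(
        analysis.kc_filtered,
        analysis.fs,
        config.kc_config(),
        segment_id=analysis.segment_id,
    )
    return spindles, kcs


def run_pipeline(
    rec: Recording,
    config: PipelineConfig | None = None,
    analyses: Sequence[SegmentAnalysis] | None = None,
) -> tuple[List[Event], List[Event], dict]:
    """Detect spindles and K-complexes over all complete 30-s segments.

    Returns events re-indexed to recording time plus a JSON-serialisable
    report.  Precomputed analyses may be passed to avoid re-decomposition.
    """
    config = config or PipelineConfig()
    if analyses is None:
        analyses = analyze_recording(rec, config)

    all_sp: List[Event] = []
    all_kc: List[Event] = []
    per_segment = []
    for a in analyses:
        sp, kc = _detect_both(a, config)
        offset = a.segment_id * rec.segment_length_s
        all_sp.extend(e.shifted(offset) for e in sp)
        all_kc.extend(e.shifted(offset) for e in kc)
        per_segment.append(
            {"segment": a.segment_id, "spindles": len(sp), "kcomplexes": len(kc)}
        )
        log.info(
            "segment=%d stage=detect spindles=%d kcomplexes=%d",
            a.segment_id, len(sp), len(kc),
        )

    report = {
        "n_segments": len(analyses),
        "fs": rec.fs,
        "settings": {
            "spindle_threshold_uV2": config.spindle_threshold,
            "kc_threshold_uV": config.kc_threshold,
            "use_mca": config.use_mca,
            "n_iterations": config.n_iterations,
        },
        "totals": {"spindles": len(all_sp), "kcomplexes": len(all_kc)},
        "per_segment": per_segment,
    }
    return all_sp, all_kc, report


def train_thresholds(
    analyses: Sequence[SegmentAnalysis],
    spindle_truth: Sequence[Sequence[Event]],
    kc_truth: Sequence[Sequence[Event]],
    config: PipelineConfig | None = None,
) -> tuple[float, float, ThresholdCurve, ThresholdCurve]:
    """Sweep both detector thresholds and pick argmax(Sen - FDR) for each.

    Spindle thresholds go from one step up to twice the largest map value
    in steps of 10 uV^2; K-complex thresholds from -2 to -200 uV in -2 uV
    steps.
    """
    config = config or PipelineConfig()

    peak = max(float(a.tfmap.values.max()) for a in analyses)
    sp_thresholds = np.arange(
        SPINDLE_SWEEP_STEP, max(2 * peak, 2 * SPINDLE_SWEEP_STEP), SPINDLE_SWEEP_STEP
    )

    def sp_detector(a: SegmentAnalysis, t: float) -> List[Event]:
        return detect_spindles(a.tfmap, t, max_duration_s=config.max_spindle_duration_s)

    sp_curve = threshold_sweep(analyses, spindle_truth, sp_detector, sp_thresholds)
    sp_best = optimal_threshold(sp_curve)

    kc_thresholds = np.arange(KC_SWEEP_STEP, KC_SWEEP_FLOOR + KC_SWEEP_STEP, KC_SWEEP_STEP)

    def kc_detector(a: SegmentAnalysis, t: float) -> List[Event]:
        return detect_kcomplexes(a.kc_filtered, a.fs, config.kc_config(t),
                                 segment_id=a.segment_id)

    kc_curve = threshold_sweep(analyses, kc_truth, kc_detector, kc_thresholds)
    kc_best = optimal_threshold(kc_curve)
    return sp_best, kc_best, sp_curve, kc_curve
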