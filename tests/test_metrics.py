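import itertools

import numpy as np
import pytest

from sleepsift.errors import InputError, ParameterError, UndefinedMetricError
from sleepsift.events import Event
from sleepsift.metrics import (
    MatchResult,
    ThresholdCurve,
    agreement,
    fdr,
    match_events,
    optimal_threshold,
    rms_baseline_detect,
    sensitivity,
    threshold_sweep,
)

FS = 200.0


def ev(start, end, kind="spindle", seg=0):
    return Event(kind=kind, segment_id=seg, start_s=start, end_s=end)


def brute_force_max_matching(detected, annotated):
    """Exhaustive assignment oracle: max number of one-to-one overlap pairs."""
    overlaps = [
        (di, ai)
        for di, d in enumerate(detected)
        for ai, a in enumerate(annotated)
        if d.overlap_s(a) > 0
    ]
    best = 0
    for k in range(min(len(detected), len(annotated)), 0, -1):
        for combo in itertools.combinations(overlaps, k):
            ds = [c[0] for c in combo]
            as_ = [c[1] for c in combo]
            if len(set(ds)) == k and len(set(as_)) == k:
                return k
    return best


class TestMatchEvents:
    def test_identical_lists(self):
        events = [ev(i, i + 1.0) for i in range(0, 10, 2)]
        m = match_events(events, events)
        assert (m.TP, m.FP, m.FN) == (5, 0, 0)

    def test_disjoint(self):
        det = [ev(i, i + 0.5) for i in (0.0, 2.0, 4.0)]
        ann = [ev(i, i + 0.5) for i in (1.0, 3.0, 5.0, 7.0)]
        m = match_events(det, ann)
        assert (m.TP, m.FP, m.FN) == (0, 3, 4)

    def test_one_to_one(self):
        # one long detection overlapping two annotations matches only one
        det = [ev(0.0, 5.0)]
        ann = [ev(0.5, 1.5), ev(3.0, 4.0)]
        m = match_events(det, ann)
        assert (m.TP, m.FP, m.FN) == (1, 0, 1)

    @pytest.mark.filterwarnings("ignore:overlapping duplicate annotations")
    def test_counts_invariants(self, rng):
        for _ in range(20):
            det = [ev(s, s + rng.uniform(0.3, 1.5))
                   for s in np.sort(rng.uniform(0, 50, rng.integers(1, 12)))]
            ann = [ev(s, s + rng.uniform(0.3, 1.5))
                   for s in np.sort(rng.uniform(0, 50, rng.integers(1, 12)))]
            m = match_events(det, ann)
            assert m.TP == len(m.matched_pairs)
            assert m.TP + m.FN == len(ann)
            assert m.TP + m.FP == len(det)

    def test_against_exhaustive_assignment(self, rng):
        """On well-separated fixtures greedy equals the exhaustive optimum."""
        for trial in range(10):
            starts = np.arange(8) * 5.0 + rng.uniform(-0.5, 0.5, 8)
            det = [ev(s, s + 1.0) for s in starts[rng.random(8) > 0.3]]
            ann = [ev(s + rng.uniform(-0.3, 0.3), s + 1.2) for s in starts[rng.random(8) > 0.3]]
            m = match_events(det, ann)
            assert m.TP == brute_force_max_matching(det, ann)

    def test_duplicate_annotation_warns(self):
        ann = [ev(0.0, 2.0), ev(1.0, 3.0)]
        with pytest.warns(UserWarning):
            match_events([ev(0.5, 1.5)], ann)

    def test_unknown_criterion(self):
        with pytest.raises(ParameterError):
            match_events([], [], criterion="iou>0.5")


class TestBasicMetrics:
    @pytest.mark.parametrize(
        "tp,fn,expected", [(5, 5, 0.5), (0, 7, 0.0), (7, 0, 1.0)]
    )
    def test_sensitivity(self, tp, fn, expected):
        assert sensitivity(MatchResult(TP=tp, FP=0, FN=fn)) == expected

    @pytest.mark.parametrize(
        "tp,fp,expected", [(3, 1, 0.25), (5, 0, 0.0), (0, 4, 1.0)]
    )
    def test_fdr(self, tp, fp, expected):
        assert fdr(MatchResult(TP=tp, FP=fp, FN=0)) == expected

    def test_undefined_signals(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(MatchResult(TP=0, FP=3, FN=0))
        with pytest.raises(UndefinedMetricError):
            fdr(MatchResult(TP=0, FP=0, FN=3))


class TestOptimalThreshold:
    def test_example(self):
        c = ThresholdCurve(
            thresholds=np.array([10.0, 20.0, 30.0]),
            sens=np.array([1.0, 1.0, 0.5]),
            fdr=np.array([0.9, 0.2, 0.1]),
        )
        assert c.best_index == 1
        assert optimal_threshold(c) == 20.0

    def test_tie_takes_first(self):
        c = ThresholdCurve(
            thresholds=np.array([1.0, 2.0, 3.0]),
            sens=np.array([0.8, 0.8, 0.8]),
            fdr=np.array([0.3, 0.3, 0.3]),
        )
        assert optimal_threshold(c) == 1.0

    def test_against_brute_force(self, rng):
        for _ in range(50):
            n = rng.integers(2, 30)
            c = ThresholdCurve(
                thresholds=np.sort(rng.uniform(0, 100, n)),
                sens=rng.random(n),
                fdr=rng.random(n),
            )
            brute = max(range(n), key=lambda i: (c.sens[i] - c.fdr[i], -i))
            assert c.best_index == brute

    def test_empty_curve(self):
        c = ThresholdCurve(np.array([]), np.array([]), np.array([]))
        with pytest.raises(InputError):
            optimal_threshold(c)


class TestThresholdSweep:
    @staticmethod
    def _detector(segment, threshold):
        """Segment = list of (peak, start); detect all peaks above threshold."""
        return [
            ev(s, s + 1.0) for p, s in segment if p > threshold
        ]

    def test_high_snr_full_sensitivity(self, rng):
        segments, annotations = [], []
        for i in range(5):
            peaks = [(100.0 + rng.uniform(0, 5), 3.0 * k) for k in range(3)]
            segments.append(peaks)
            annotations.append([ev(s, s + 1.0) for _, s in peaks])
        curve = threshold_sweep(segments, annotations, self._detector,
                               np.arange(10, 90, 10.0))
        assert np.all(curve.sens == 1.0)
        assert np.all(curve.fdr == 0.0)

    def test_overlapping_distributions(self):
        """Selected threshold lands between event and background means."""
        rng = np.random.default_rng(7)
        segments, annotations = [], []
        for i in range(40):
            events = [(float(rng.normal(8.0, 2.0)), 2.0), (float(rng.normal(8.0, 2.0)), 10.0)]
            background = [(float(rng.normal(4.0, 2.0)), 6.0), (float(rng.normal(4.0, 2.0)), 15.0)]
            segments.append(events + background)
            annotations.append([ev(s, s + 1.0) for _, s in events])
        thresholds = np.arange(0.0, 16.0, 0.5)
        curve = threshold_sweep(segments, annotations, self._detector, thresholds)
        best = optimal_threshold(curve)
        assert 4.0 < best < 8.0

    def test_count_monotonicity(self, rng):
        segment = [(float(rng.uniform(0, 100)), 2.0 * k) for k in range(20)]
        counts = [
            len(self._detector(segment, t)) for t in np.arange(0, 110, 5.0)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_no_annotations(self):
        with pytest.raises(UndefinedMetricError):
            threshold_sweep([[]], [[]], self._detector, [1.0])

    def test_sweep_consistency(self, rng):
        """Re-applying the chosen threshold reproduces the curve's best point."""
        segments, annotations = [], []
        for i in range(10):
            events = [(float(rng.normal(8, 2)), 2.0)]
            noise = [(float(rng.normal(4, 2)), 8.0)]
            segments.append(events + noise)
            annotations.append([ev(s, s + 1.0) for _, s in events])
        thresholds = np.arange(0.0, 14.0, 1.0)
        curve = threshold_sweep(segments, annotations, self._detector, thresholds)
        best = optimal_threshold(curve)
        total = MatchResult(0, 0, 0)
        for seg, ann in zip(segments, annotations):
            total = total + match_events(self._detector(seg, best), ann)
        i = curve.best_index
        assert sensitivity(total) == curve.sens[i]
        assert fdr(total) == curve.fdr[i]


class TestAgreement:
    def test_identical(self):
        events = [ev(1.0, 2.0, seg=i) for i in range(0, 10, 2)]
        rep = agreement(events, list(events), range(10))
        assert rep.percent_agreement == 100.0
        assert rep.kappa == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # a=40 both, b=10 A-only, c=10 B-only, d=40 neither -> kappa = 0.6
        a_events = [ev(0.0, 1.0, seg=i) for i in range(50)]
        b_events = [ev(0.0, 1.0, seg=i) for i in list(range(40)) + list(range(50, 60))]
        rep = agreement(a_events, b_events, range(100))
        assert rep.percent_agreement == pytest.approx(80.0)
        assert rep.kappa == pytest.approx(0.6)

    def test_independent_random_near_zero(self):
        rng = np.random.default_rng(3)
        n = 1000
        a = [ev(0.0, 1.0, seg=i) for i in range(n) if rng.random() < 0.5]
        b = [ev(0.0, 1.0, seg=i) for i in range(n) if rng.random() < 0.5]
        rep = agreement(a, b, range(n))
        assert abs(rep.kappa) <= 0.1

    def test_kappa_one_iff_identical(self, rng):
        n = 50
        a = [ev(0.0, 1.0, seg=i) for i in range(n) if rng.random() < 0.4]
        b = a[:-1] if len(a) > 1 else a
        rep = agreement(a, b, range(n))
        assert rep.kappa < 1.0

    def test_empty_universe(self):
        with pytest.raises(InputError):
            agreement([], [], [])


class TestRmsBaseline:
    def test_flat_zero(self):
        assert rms_baseline_detect(np.zeros(4000), FS, T=10.0) == []

    def test_injected_burst(self):
        # 1 s, 13 Hz, amplitude 30 -> RMS = 30/sqrt(2) = 21.2 > T = 10
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = np.zeros(n)
        sel = (t >= 4.0) & (t < 5.0)
        x[sel] = 30.0 * np.sin(2 * np.pi * 13.0 * t[sel])
        events = rms_baseline_detect(x, FS, T=10.0)
        assert len(events) == 1
        ev_ = events[0]
        assert ev_.duration_s == pytest.approx(1.0, abs=0.2)
        assert ev_.start_s == pytest.approx(4.0, abs=0.15)

    def test_long_run_rejected(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = np.zeros(n)
        sel = (t >= 2.0) & (t < 6.0)  # 4 s > 3 s cap
        x[sel] = 30.0 * np.sin(2 * np.pi * 13.0 * t[sel])
        assert rms_baseline_detect(x, FS, T=10.0) == []

    def test_threshold_positive(self):
        with pytest.raises(ParameterError):
            rms_baseline_detect(np.zeros(1000), FS, T=0.0)

    def test_identity_metrics(self):
        n = int(10 * FS)
        t = np.arange(n) / FS
        x = np.zeros(n)
        sel = (t >= 4.0) & (t < 5.0)
        x[sel] = 30.0 * np.sin(2 * np.pi * 13.0 * t[sel])
        events = rms_baseline_detect(x, FS, T=10.0)
        m = match_events(events, events)
        assert sensitivity(m) == 1.0
        assert fdr(m) == 0.0
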