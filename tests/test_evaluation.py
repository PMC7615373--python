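from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import brute_force_match
from seizmon import (
    AnnotationInterval,
    AnnotationSet,
    ClassifierConfig,
    Envelope,
    EventLog,
    SampleLabels,
    Transition,
    compute_metrics,
    f1_score,
    match_events,
    percent_difference,
    percent_error,
    roc_curve,
    sample_confusion,
)
from seizmon.evaluation import rasterize_annotations, round1


def onset_log(times: list[float]) -> EventLog:
    log = EventLog(capacity=1200)
    entering = True
    for t in times:
        log.append(Transition(time_s=float(np.floor(t)),
                              from_program="P0" if entering else "P1",
                              to_program="P1" if entering else "P0",
                              raw_time_s=t))
        entering = not entering
    return log


class TestSampleConfusion:
    def _labels(self, mask, fs=100.0):
        return SampleLabels(np.asarray(mask, dtype=bool), fs)

    def test_perfect_agreement(self):
        ann = AnnotationSet([AnnotationInterval(1.0, 2.0, "seizure")])
        truth = rasterize_annotations(ann, 400, 100.0)
        tpr, fpr = sample_confusion(self._labels(truth), ann)
        assert (tpr, fpr) == (1.0, 0.0)

    def test_all_negative_predictions(self):
        ann = AnnotationSet([AnnotationInterval(1.0, 2.0, "seizure")])
        tpr, fpr = sample_confusion(self._labels(np.zeros(400)), ann)
        assert (tpr, fpr) == (0.0, 0.0)

    def test_half_half(self):
        ann = AnnotationSet([AnnotationInterval(0.0, 2.0, "seizure")])
        pred = np.zeros(400, dtype=bool)
        pred[:100] = True   # half the positives
        pred[200:300] = True  # half the negatives
        tpr, fpr = sample_confusion(self._labels(pred), ann)
        assert (tpr, fpr) == (0.5, 0.5)

    def test_empty_class_warns_and_returns_nan(self):
        ann = AnnotationSet([])  # no positives anywhere
        with pytest.warns(UserWarning, match="TPR undefined"):
            tpr, fpr = sample_confusion(self._labels(np.zeros(100)), ann)
        assert np.isnan(tpr)
        assert fpr == 0.0


class TestRocCurve:
    def _scene(self, seed=0, fs=125.0, duration=120.0):
        rng = np.random.default_rng(seed)
        base = np.abs(rng.standard_normal(int(duration * fs)))
        ann = AnnotationSet([
            AnnotationInterval(20, 30, "seizure"),
            AnnotationInterval(70, 85, "seizure"),
        ])
        mask = rasterize_annotations(ann, base.size, fs)
        base[mask] += 8.0  # seizure envelope sits far above background
        return Envelope(base, fs), ann

    def test_endpoints(self):
        env, ann = self._scene()
        roc = roc_curve(env, ann)
        assert (roc.fpr[0], roc.tpr[0]) == (0.0, 0.0)
        assert roc.thresholds[0] == np.inf
        assert (roc.fpr[-1], roc.tpr[-1]) == (1.0, 1.0)
        assert roc.thresholds[-1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_monotone_as_threshold_decreases(self, seed):
        env, ann = self._scene(seed)
        roc = roc_curve(env, ann)
        assert np.all(np.diff(roc.tpr) >= 0)
        assert np.all(np.diff(roc.fpr) >= 0)

    def test_zero_envelope_flat_at_origin(self):
        env = Envelope(np.zeros(1000), 100.0)
        ann = AnnotationSet([AnnotationInterval(1.0, 3.0, "seizure")])
        roc = roc_curve(env, ann, thresholds=np.array([1.0, 5.0]))
        interior_t, tpr, fpr = roc.interior
        assert np.all(tpr == 0.0)
        assert np.all(fpr == 0.0)

    def test_separable_scene_has_good_operating_point(self):
        env, ann = self._scene()
        roc = roc_curve(env, ann)
        _, tpr, fpr = roc.interior
        assert np.any((tpr > 0.95) & (fpr < 0.05))

    def test_single_threshold_grid(self):
        env, ann = self._scene()
        roc = roc_curve(env, ann, thresholds=np.array([5.0]))
        assert roc.thresholds.size == 3  # one interior point + 2 endpoints

    def test_debounced_mode_runs_state_machine(self):
        env, ann = self._scene()
        cfg = ClassifierConfig(threshold_uv=1.0, debounce_s=2.0)
        roc = roc_curve(env, ann, cfg=cfg, thresholds=np.array([2.0, 8.0]),
                        debounce=True)
        _, tpr, _ = roc.interior
        assert np.all((tpr >= 0) & (tpr <= 1))


class TestMatchEvents:
    @pytest.mark.parametrize(
        "onset,expected",
        [
            (12.0, (1, 0, 0)),   # inside the event
            (22.5, (1, 0, 0)),   # within 3 s after the event
            (23.0, (1, 0, 0)),   # tie at exactly 3 s counts
            (30.0, (0, 1, 1)),   # 10 s late: unmatched
            (8.0, (0, 1, 1)),    # before onset: unmatched
        ],
    )
    def test_single_event_window_rule(self, onset, expected):
        ann = AnnotationSet([AnnotationInterval(10.0, 20.0, "seizure")])
        assert match_events(onset_log([onset]), ann) == expected

    def test_retriggering_counts_once(self):
        ann = AnnotationSet([AnnotationInterval(10.0, 30.0, "seizure")])
        log = onset_log([12.0, 18.0, 25.0])  # P0->P1 at 12 and 25, P1->P0 at 18
        tp, fp, fn = match_events(log, ann)
        assert (tp, fp, fn) == (1, 0, 0)

    def test_attribution_to_most_recent_event(self):
        ann = AnnotationSet([
            AnnotationInterval(10.0, 20.0, "seizure"),
            AnnotationInterval(21.0, 25.0, "seizure"),
        ])
        # 22: inside event 2 (also within 3 s of event 1) -> event 2 detected
        tp, fp, fn = match_events(onset_log([22.0]), ann)
        assert (tp, fp, fn) == (1, 0, 1)

    @given(
        seed=st.integers(0, 5_000),
        n_events=st.integers(0, 5),
        n_onsets=st.integers(0, 8),
    )
    @settings(max_examples=150)
    def test_agrees_with_pairwise_enumeration_oracle(self, seed, n_events, n_onsets):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.uniform(0, 200, n_events))
        events = []
        for k, s in enumerate(starts):
            e = s + rng.uniform(4, 10)
            if events and s < events[-1][1]:
                continue
            events.append((float(s), float(e)))
        raw = np.unique(np.round(rng.uniform(0, 220, n_onsets), 2))
        onsets = [t for t in raw if all(abs(t - u) > 0.1 or t == u for u in raw)]
        # interleave an exit right after each detection so the log alternates
        times = [v for t in onsets for v in (t, t + 0.05)]
        ann = AnnotationSet([AnnotationInterval(s, e, "seizure") for s, e in events])
        got = match_events(onset_log(times), ann)
        assert got == brute_force_match(list(onsets), events, 3.0)
        tp, fp, fn = got
        assert tp + fn == len(events)

    @given(seed=st.integers(0, 5_000))
    @settings(max_examples=50)
    def test_tp_monotone_in_window(self, seed):
        rng = np.random.default_rng(seed)
        events = [(10.0, 20.0), (50.0, 60.0)]
        onsets = sorted(rng.uniform(0, 80, 4))
        ann = AnnotationSet([AnnotationInterval(s, e, "seizure") for s, e in events])
        tp0, _, _ = match_events(onset_log(list(onsets)), ann, window_s=0.0)
        tp3, _, _ = match_events(onset_log(list(onsets)), ann, window_s=3.0)
        assert tp0 <= tp3


class TestComputeMetrics:
    def test_reported_performance_consistency(self):
        # published precision/recall pairs and the F1 they imply
        assert f1_score(86.8, 85.5) == 86.1
        assert f1_score(78.6, 100.0) == 88.0

    def test_perfect_detection(self):
        m = compute_metrics(tp=5, fp=0, fn=0)
        assert (m.precision, m.recall, m.f1) == (100.0, 100.0, 100.0)

    def test_f1_between_precision_and_recall(self):
        for tp, fp, fn in [(8, 2, 3), (1, 5, 0), (10, 0, 4)]:
            m = compute_metrics(tp, fp, fn)
            assert min(m.precision, m.recall) - 0.05 <= m.f1 <= max(m.precision, m.recall) + 0.05

    def test_undefined_precision_warns(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = compute_metrics(tp=0, fp=0, fn=3)
        assert np.isnan(m.precision)
        assert np.isnan(m.f1)

    def test_event_count_invariant_enforced(self):
        m = compute_metrics(tp=7, fp=1, fn=3)
        assert m.tp + m.fn == m.n_annotated == 10


class TestPercentHelpers:
    @pytest.mark.parametrize(
        "ref,meas,expected",
        [(45.25, 46.22, 2.1), (36.46, 36.71, 0.7), (32.21, 32.41, 0.6),
         (10.0, 10.0, 0.0)],
    )
    def test_percent_error_calibration_pairs(self, ref, meas, expected):
        assert percent_error(ref, meas) == expected

    @pytest.mark.parametrize(
        "ref,meas,expected", [(134, 144, 7.5), (138, 144, 4.3), (50, 50, 0.0)]
    )
    def test_percent_difference_trigger_pairs(self, ref, meas, expected):
        assert percent_difference(ref, meas) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_error(0.0, 1.0)
        with pytest.raises(ValueError):
            percent_difference(0, 1)

    def test_rounding_half_away_from_zero(self):
        assert round1(0.25) == 0.3
        assert round1(-0.25) == -0.3
        assert round1(2.149999) == 2.1
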