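"""Classifier scoring against clinician annotations.

Two complementary views are computed:

* **sample-wise** — annotation intervals are rasterized onto the envelope's
  sample grid and compared with per-sample predictions, yielding the
  true/false positive rates that make up the ROC curve used for threshold
  selection;
* **event-wise** — each P0 -> P1 transition (a positive classification) is
  matched to annotated seizure events with a 3 s lookback window: a
  classification at time ``t`` is a true positive when annotated seizure
  activity lies within ``[t - 3 s, t]``, otherwise a false positive.  An
  annotated event detected by at least one classification counts once;
  undetected events are false negatives.  Precision, recall and F1 are
  reported as percentages rounded half-away-from-zero to one decimal.

Trigger counts (transitions in both directions) and the percent-error /
percent-difference helpers used for replay-calibration and trigger-rate
comparisons also live here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .classifier import ClassifierConfig, EventLog, SampleLabels, classify_stream
from .io_ingest import AnnotationSet, interval_to_slice
from .signal_chain import Envelope

__all__ = [
    "RocCurve",
    "EventMetrics",
    "rasterize_annotations",
    "sample_confusion",
    "roc_curve",
    "default_threshold_grid",
    "match_events",
    "compute_metrics",
    "f1_score",
    "percent_error",
    "percent_difference",
    "round1",
]

DEFAULT_MATCH_WINDOW_S = 3.0


def round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (matches reported metrics)."""
    if math.isnan(x):
        return x
    return math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)


@dataclass
class RocCurve:
    """Sample-wise ROC: thresholds in descending order with TPR/FPR per point.

    Endpoints are always included: (fpr, tpr) = (0, 0) at threshold +inf and
    (1, 1) at threshold 0.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.tpr = np.asarray(self.tpr, dtype=np.float64)
        self.fpr = np.asarray(self.fpr, dtype=np.float64)
        if not (self.thresholds.size == self.tpr.size == self.fpr.size):
            raise ValueError("thresholds, tpr, fpr must have equal length")
        if np.any(np.diff(self.thresholds) > 0):
            raise ValueError("thresholds must be in descending order")

    @property
    def interior(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The finite, positive threshold grid without the two endpoints."""
        m = np.isfinite(self.thresholds) & (self.thresholds > 0)
        return self.thresholds[m], self.tpr[m], self.fpr[m]


@dataclass
class EventMetrics:
    """Event-matched performance: counts plus percentages (1 decimal)."""

    n_annotated: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    triggers: int = 0

    def __post_init__(self) -> None:
        if self.tp + self.fn != self.n_annotated:
            raise ValueError(
                f"tp + fn ({self.tp} + {self.fn}) must equal annotated events "
                f"({self.n_annotated})"
            )


def rasterize_annotations(ann: AnnotationSet, n_samples: int, fs: float) -> np.ndarray:
    """Boolean per-sample mask, True inside annotated seizure intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for iv in ann.seizure_intervals:
        sl = interval_to_slice(iv.start_s, iv.end_s, fs)
        mask[sl.start : min(sl.stop, n_samples)] = True
    return mask


def sample_confusion(
    pred: SampleLabels, ann: AnnotationSet
) -> tuple[float, float]:
    """Sample-wise (TPR, FPR) of predictions vs the annotation raster.

    If either class is empty the corresponding rate is NaN (with a warning),
    never silently zero.
    """
    truth = rasterize_annotations(ann, pred.values.size, pred.sampling_rate)
    pos = int(truth.sum())
    neg = int(truth.size - pos)
    tp = int(np.count_nonzero(pred.values & truth))
    fp = int(np.count_nonzero(pred.values & ~truth))
    if pos == 0:
        warnings.warn("no annotated-positive samples; TPR undefined", stacklevel=2)
        tpr = float("nan")
    else:
        tpr = tp / pos
    if neg == 0:
        warnings.warn("no annotated-negative samples; FPR undefined", stacklevel=2)
        fpr = float("nan")
    else:
        fpr = fp / neg
    return tpr, fpr


def default_threshold_grid(env: Envelope, n: int = 100) -> np.ndarray:
    """Logarithmic grid spanning the [1st, 99.9th] percentile of the envelope."""
    lo = float(np.percentile(env.values, 1))
    hi = float(np.percentile(env.values, 99.9))
    if hi <= 0:
        return np.array([1.0])
    lo = max(lo, hi * 1e-6)
    if hi <= lo:
        return np.array([hi])
    return np.geomspace(lo, hi, n)


def roc_curve(
    env: Envelope,
    ann: AnnotationSet,
    cfg: ClassifierConfig | None = None,
    thresholds: np.ndarray | None = None,
    debounce: bool = False,
) -> RocCurve:
    """Sweep detection thresholds and collect sample-wise TPR/FPR.

    By default each grid threshold is applied directly to the envelope
    samples, which guarantees the ROC is monotone by construction.  With
    ``debounce=True`` the full state machine (requiring ``cfg``) is run at
    every threshold instead, predicting the labels the device itself would
    produce; debounce hold-times can then perturb strict monotonicity.
    """
    if thresholds is None:
        thresholds = default_threshold_grid(env)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size == 0 or np.any(thresholds <= 0):
        raise ValueError("threshold grid must be non-empty and positive")
    order = np.argsort(thresholds)[::-1]
    grid = thresholds[order]

    truth = rasterize_annotations(ann, env.n_samples, env.sampling_rate)
    pos = int(truth.sum())
    neg = int(truth.size - pos)
    if pos == 0:
        warnings.warn("no annotated-positive samples; TPR undefined", stacklevel=2)
    if neg == 0:
        warnings.warn("no annotated-negative samples; FPR undefined", stacklevel=2)

    if debounce:
        if cfg is None:
            raise ValueError("debounce=True requires a ClassifierConfig")
        tprs, fprs = [], []
        for th in grid:
            c = ClassifierConfig(
                threshold_uv=float(th),
                debounce_s=cfg.debounce_s,
                program_nonevent=cfg.program_nonevent,
                program_event=cfg.program_event,
                log_resolution_s=cfg.log_resolution_s,
                log_capacity=cfg.log_capacity,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels, _ = classify_stream(env, c)
                t, f = sample_confusion(labels, ann)
            tprs.append(t)
            fprs.append(f)
        tpr = np.array(tprs)
        fpr = np.array(fprs)
    else:
        # counting view: TPR(th) = #(positive samples with env >= th) / #positives
        pos_sorted = np.sort(env.values[truth])
        neg_sorted = np.sort(env.values[~truth])
        n_tp = pos_sorted.size - np.searchsorted(pos_sorted, grid, side="left")
        n_fp = neg_sorted.size - np.searchsorted(neg_sorted, grid, side="left")
        tpr = n_tp / pos if pos else np.full(grid.size, np.nan)
        fpr = n_fp / neg if neg else np.full(grid.size, np.nan)

    thr = np.concatenate(([np.inf], grid, [0.0]))
    tpr = np.concatenate(([0.0], tpr, [1.0]))
    fpr = np.concatenate(([0.0], fpr, [1.0]))
    return RocCurve(thr, tpr, fpr)


def match_events(
    log: EventLog,
    ann: AnnotationSet,
    window_s: float = DEFAULT_MATCH_WINDOW_S,
) -> tuple[int, int, int]:
    """Match positive classifications to annotated events with a lookback window.

    A P0 -> P1 transition at exact time ``t`` is a true positive when some
    annotated seizure event satisfies ``start <= t <= end + window_s`` (the
    lookback window is closed, so a tie at exactly ``window_s`` counts).  It
    is attributed to the most recent such event; repeated detections of one
    event count once toward recall and are never false positives.

    Returns ``(tp, fp, fn)`` with ``tp`` = detected events, ``fp`` =
    unmatched classifications, ``fn`` = undetected events, so that
    ``tp + fn`` equals the number of annotated events.
    """
    if window_s < 0:
        raise ValueError("window_s must be >= 0")
    events = sorted(ann.seizure_intervals, key=lambda iv: iv.start_s)
    detected: set[int] = set()
    fp = 0
    for t in log.onset_times(raw=True):
        candidates = [
            k for k, iv in enumerate(events)
            if iv.start_s <= t <= iv.end_s + window_s
        ]
        if candidates:
            detected.add(max(candidates, key=lambda k: events[k].start_s))
        else:
            fp += 1
    tp = len(detected)
    return tp, fp, len(events) - tp


def f1_score(precision_pct: float, recall_pct: float) -> float:
    """F1 (as a percentage, 1 decimal) from precision/recall percentages."""
    if math.isnan(precision_pct) or math.isnan(recall_pct):
        return float("nan")
    if precision_pct + recall_pct == 0:
        return 0.0
    return round1(2 * precision_pct * recall_pct / (precision_pct + recall_pct))


def compute_metrics(
    tp: int, fp: int, fn: int, triggers: int = 0, n_annotated: int | None = None
) -> EventMetrics:
    """Assemble precision/recall/F1 (percent, 1 decimal) from event counts."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if n_annotated is None:
        n_annotated = tp + fn
    if tp + fp == 0:
        warnings.warn("no positive classifications; precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = round1(100 * tp / (tp + fp))
    if tp + fn == 0:
        warnings.warn("no annotated events; recall undefined", stacklevel=2)
        recall = float("nan")
    else:
        recall = round1(100 * tp / (tp + fn))
    return EventMetrics(
        n_annotated=n_annotated,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        f1=f1_score(precision, recall),
        triggers=triggers,
    )


def percent_error(reference: float, measured: float) -> float:
    """Signed percent error of a measured value vs its reference, 1 decimal."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return round1(100 * (measured - reference) / reference)


def percent_difference(reference_count: float, measured_count: float) -> float:
    """Signed percent difference between two counts vs the reference, 1 decimal."""
    if reference_count <= 0:
        raise ValueError("reference_count must be positive")
    return round1(100 * (measured_count - reference_count) / reference_count)
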