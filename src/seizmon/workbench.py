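"""End-to-end configuration workflow: simulate, select a threshold, report.

This module strings the pieces together the way the interactive
configuration tool does: compute the envelope for a candidate filter chain,
sweep an ROC, pick an operating threshold under a false-positive-rate
budget, simulate the embedded monitor, and score it against the clinician
annotations.  It also runs the gain-perturbation experiment that mirrors
replaying a dataset through a test bench whose calibration is only accurate
to a few percent.

The "annotated transitions" statistic equals twice the number of annotated
seizure events: entering and leaving each event would each be one program
transition on the device, which is the convention trigger counts are
compared under.  Note this differs from the event count itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, EventLog, classify_stream, count_triggers
from .evaluation import (
    EventMetrics,
    RocCurve,
    compute_metrics,
    match_events,
    percent_difference,
    roc_curve,
)
from .io_ingest import AnnotationSet, Recording
from .signal_chain import FilterChainConfig, compute_envelope
from .synthetic_data import apply_gain

__all__ = [
    "WorkbenchReport",
    "run_in_silico",
    "select_threshold",
    "gain_sensitivity",
    "run_workflow",
    "DEFAULT_MAX_FPR",
]

#: Default sample-wise false-positive-rate budget for threshold selection.
DEFAULT_MAX_FPR = 0.05


@dataclass
class WorkbenchReport:
    """Everything one simulation run produces, ready for JSON/text export."""

    duration_s: float
    n_events: int
    threshold_uv: float
    metrics: EventMetrics
    annotated_transitions: int
    triggers: int
    log: EventLog
    roc: RocCurve | None = None
    gain_table: pd.DataFrame | None = None
    config_path: str | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "duration_s": self.duration_s,
            "annotated_events": self.n_events,
            "threshold_uv": self.threshold_uv,
            "annotated_transitions": self.annotated_transitions,
            "triggers": self.triggers,
            "tp": self.metrics.tp,
            "fp": self.metrics.fp,
            "fn": self.metrics.fn,
            "precision_pct": self.metrics.precision,
            "recall_pct": self.metrics.recall,
            "f1_pct": self.metrics.f1,
        }
        if self.gain_table is not None:
            d["gain_table"] = self.gain_table.to_dict("records")
        if self.config_path:
            d["config_path"] = self.config_path
        if self.meta:
            d["meta"] = self.meta
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        m = self.metrics
        lines = [
            f"Dataset duration (s)     {self.duration_s:.1f}",
            f"Annotated events         {self.n_events}",
            f"Classifier threshold     {self.threshold_uv:.4g} uV",
            f"Classifier triggers      {self.triggers}",
            f"Annotated transitions    {self.annotated_transitions}",
            f"TP / FP / FN             {m.tp} / {m.fp} / {m.fn}",
            f"Precision (%)            {m.precision}",
            f"Recall (%)               {m.recall}",
            f"F1 score (%)             {m.f1}",
        ]
        return "\n".join(lines)


def run_in_silico(
    rec: Recording,
    ann: AnnotationSet,
    chain: FilterChainConfig,
    clf: ClassifierConfig,
) -> WorkbenchReport:
    """Simulate the embedded monitor on a recording and score it.

    Deterministic composition: envelope -> debounced classification ->
    3 s event matching -> precision/recall/F1 -> trigger count.
    """
    env = compute_envelope(rec, chain)
    _, log = classify_stream(env, clf)
    tp, fp, fn = match_events(log, ann)
    n_events = ann.n_seizures
    metrics = compute_metrics(
        tp, fp, fn, triggers=count_triggers(log), n_annotated=n_events
    )
    return WorkbenchReport(
        duration_s=rec.duration_s,
        n_events=n_events,
        threshold_uv=clf.threshold_uv,
        metrics=metrics,
        annotated_transitions=2 * n_events,
        triggers=count_triggers(log),
        log=log,
    )


def select_threshold(roc: RocCurve, max_fpr: float = DEFAULT_MAX_FPR) -> float:
    """Operating threshold: maximal TPR subject to FPR <= ``max_fpr``.

    Ties in TPR are broken toward the higher threshold (the more
    conservative operating point).  Only the finite grid thresholds are
    eligible, never the +inf/0 endpoints.
    """
    if not 0 < max_fpr < 1:
        raise ValueError("max_fpr must lie in (0, 1)")
    thr, tpr, fpr = roc.interior
    ok = np.isfinite(fpr) & (fpr <= max_fpr) & np.isfinite(tpr)
    if not np.any(ok):
        raise ValueError(f"no threshold achieves FPR <= {max_fpr}")
    best_tpr = tpr[ok].max()
    candidates = ok & (tpr == best_tpr)
    return float(thr[candidates].max())


def gain_sensitivity(
    rec: Recording,
    ann: AnnotationSet,
    chain: FilterChainConfig,
    clf: ClassifierConfig,
    gains: list[float],
) -> pd.DataFrame:
    """Trigger counts under input-gain perturbations, vs the gain-1 baseline.

    Returns a DataFrame with columns ``gain``, ``triggers`` and
    ``percent_difference`` (relative to the unperturbed run).
    """
    if any(g <= 0 for g in gains):
        raise ValueError("gains must be positive")
    baseline = run_in_silico(rec, ann, chain, clf).triggers
    rows = []
    for g in gains:
        rep = run_in_silico(apply_gain(rec, g), ann, chain, clf)
        pct = (
            percent_difference(baseline, rep.triggers)
            if baseline > 0
            else float("nan")
        )
        rows.append({"gain": g, "triggers": rep.triggers, "percent_difference": pct})
    return pd.DataFrame(rows)


def run_workflow(
    rec: Recording,
    ann: AnnotationSet,
    chain: FilterChainConfig,
    max_fpr: float = DEFAULT_MAX_FPR,
    threshold_uv: float | None = None,
    clf_template: ClassifierConfig | None = None,
) -> WorkbenchReport:
    """Full workflow: ROC sweep, threshold selection, simulation, report.

    ``threshold_uv`` overrides the ROC-based choice (the workbench's
    "user-supplied threshold" path).  ``clf_template`` carries debounce,
    log and program settings; only its threshold is replaced.
    """
    env = compute_envelope(rec, chain)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        roc = roc_curve(env, ann)
    if threshold_uv is None:
        threshold_uv = select_threshold(roc, max_fpr)
    if clf_template is None:
        clf = ClassifierConfig(threshold_uv=threshold_uv)
    else:
        clf = ClassifierConfig(
            threshold_uv=threshold_uv,
            debounce_s=clf_template.debounce_s,
            program_nonevent=clf_template.program_nonevent,
            program_event=clf_template.program_event,
            log_resolution_s=clf_template.log_resolution_s,
            log_capacity=clf_template.log_capacity,
        )
    report = run_in_silico(rec, ann, chain, clf)
    report.roc = roc
    return report
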