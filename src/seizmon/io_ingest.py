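"""Recording and annotation ingestion plus dataset preprocessing.

Recordings are single-channel local field potential (LFP) traces in
microvolts on a uniform time grid.  Annotations are clinician-style labeled
intervals (``seizure`` / ``interictal``) in seconds on the recording's time
base.  The preprocessing mirrors the monitor-configuration workflow: resample
to the device rate (625 Hz), keep a peri-event window of +/- 30 s around each
annotated seizure, and concatenate the kept windows into one training
dataset.

Time conventions: 0-based seconds, intervals half-open ``[start, end)``.
Sample ``i`` of a recording covers time ``i / fs``, so the samples belonging
to an interval are ``ceil(start * fs) <= i < ceil(end * fs)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "Recording",
    "AnnotationInterval",
    "AnnotationSet",
    "read_recording",
    "read_annotations",
    "apply_duration_rule",
    "resample",
    "segment_and_concatenate",
    "save_dataset",
    "load_dataset",
    "interval_to_slice",
]

VALID_LABELS = frozenset({"seizure", "interictal"})

#: Device sampling rate in Hz; all classifier configuration happens at this rate.
DEVICE_FS = 625.0

#: Peri-event context kept around each annotated seizure, seconds.
DEFAULT_PAD_S = 30.0

#: Electrographic-seizure duration criterion, seconds: epileptiform activity
#: must last strictly longer than this to count as a seizure event; shorter
#: discharges are interictal.
MIN_SEIZURE_S = 3.0

_EPS = 1e-9


@dataclass
class Recording:
    """A uniformly sampled amplitude series in microvolts."""

    samples: np.ndarray
    sampling_rate: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if not self.sampling_rate > 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the start of the recording."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class AnnotationInterval:
    """A labeled half-open time interval ``[start_s, end_s)`` in seconds."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"interval end ({self.end_s}) must be after start ({self.start_s})"
            )
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; expected one of {sorted(VALID_LABELS)}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationSet:
    """An ordered collection of annotation intervals, sorted by start time."""

    intervals: list[AnnotationInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.start_s, iv.end_s))
        for label in VALID_LABELS:
            prev_end = -math.inf
            for iv in self.intervals:
                if iv.label != label:
                    continue
                if iv.start_s < prev_end - _EPS:
                    raise ValueError(
                        f"overlapping {label!r} intervals at {iv.start_s:.3f} s"
                    )
                prev_end = iv.end_s

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    @property
    def seizure_intervals(self) -> list[AnnotationInterval]:
        return [iv for iv in self.intervals if iv.label == "seizure"]

    @property
    def n_seizures(self) -> int:
        return len(self.seizure_intervals)

    def check_within(self, rec: Recording) -> None:
        """Raise if any interval extends beyond the recording duration."""
        for iv in self.intervals:
            if iv.start_s < 0 or iv.end_s > rec.duration_s + _EPS:
                raise ValueError(
                    f"interval ({iv.start_s}, {iv.end_s}) outside recording "
                    f"of duration {rec.duration_s:.3f} s"
                )


def interval_to_slice(start_s: float, end_s: float, fs: float) -> slice:
    """Sample slice covering the half-open interval ``[start_s, end_s)``."""
    i0 = int(math.ceil(start_s * fs - _EPS))
    i1 = int(math.ceil(end_s * fs - _EPS))
    return slice(max(i0, 0), max(i1, 0))


def read_recording(
    path: str | Path,
    format: str | None = None,
    channel: str | None = None,
) -> Recording:
    """Read a recording from an EDF file or a time/amplitude CSV.

    CSV files must have columns ``time_s`` and ``amplitude_uv`` with a
    strictly increasing, uniform time grid (any step deviating from the
    median step by more than 1 % is an error).  EDF amplitudes are converted
    to microvolts; ``channel`` selects the signal by its EDF label.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        return _read_edf(path, channel)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown recording format {format!r}")


def _read_edf(path: Path, channel: str | None) -> Recording:
    import mne  # deferred: heavy import, only needed for EDF input

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channel is None:
        if len(raw.ch_names) != 1:
            raise ValueError(
                f"EDF has {len(raw.ch_names)} channels; specify one of {raw.ch_names}"
            )
        channel = raw.ch_names[0]
    if channel not in raw.ch_names:
        raise KeyError(f"channel {channel!r} not in EDF (has {raw.ch_names})")
    data = raw.get_data(picks=[channel], units="uV")[0]
    return Recording(samples=data, sampling_rate=float(raw.info["sfreq"]), label=channel)


def _read_csv(path: Path) -> Recording:
    df = pd.read_csv(path)
    missing = {"time_s", "amplitude_uv"} - set(df.columns)
    if missing:
        raise ValueError(f"CSV {path} missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    x = df["amplitude_uv"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("CSV must contain at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("non-uniform sampling: time column not strictly increasing")
    step = float(np.median(dt))
    if np.max(np.abs(dt - step)) > 0.01 * step:
        raise ValueError("non-uniform sampling: time steps deviate >1% from median")
    return Recording(samples=x, sampling_rate=1.0 / step, label=path.stem, t0=float(t[0]))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read labeled intervals from a CSV (start_s, end_s, label) or a JSON list."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text() or "[]")
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            return AnnotationSet([])
        missing = {"start_s", "end_s", "label"} - set(df.columns)
        if missing:
            raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
        records = df.to_dict("records")
    intervals = [
        AnnotationInterval(
            start_s=float(r["start_s"]),
            end_s=float(r["end_s"]),
            label=str(r["label"]).strip().lower(),
        )
        for r in records
    ]
    return AnnotationSet(intervals)


def apply_duration_rule(
    ann: AnnotationSet, min_seizure_s: float = MIN_SEIZURE_S
) -> AnnotationSet:
    """Enforce the electrographic-seizure duration criterion.

    Epileptiform intervals lasting strictly longer than ``min_seizure_s``
    are labeled ``seizure``; shorter discharges are interictal activity and
    never counted as events downstream.
    """
    relabeled = [
        replace(iv, label="seizure" if iv.duration_s > min_seizure_s else "interictal")
        for iv in ann
    ]
    return AnnotationSet(relabeled)


def resample(rec: Recording, target_fs: float = DEVICE_FS) -> Recording:
    """Resample to ``target_fs`` with polyphase rational resampling.

    An anti-alias lowpass is applied implicitly by the polyphase filter when
    downsampling.  Resampling to the recording's own rate is an exact
    identity.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    if target_fs == rec.sampling_rate:
        return Recording(rec.samples.copy(), rec.sampling_rate, rec.label, rec.t0)
    ratio = Fraction(target_fs / rec.sampling_rate).limit_denominator(10_000)
    y = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    actual_fs = rec.sampling_rate * ratio.numerator / ratio.denominator
    return Recording(y, actual_fs, rec.label, rec.t0)


def _merged_windows(
    ann: AnnotationSet, duration_s: float, pad_s: float
) -> list[tuple[float, float]]:
    seizures = ann.seizure_intervals
    if not seizures:
        raise ValueError("no seizure intervals to segment around")
    windows = sorted(
        (max(0.0, iv.start_s - pad_s), min(duration_s, iv.end_s + pad_s))
        for iv in seizures
    )
    merged: list[tuple[float, float]] = []
    for lo, hi in windows:
        if merged and lo <= merged[-1][1] + _EPS:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def segment_and_concatenate(
    rec: Recording, ann: AnnotationSet, pad_s: float = DEFAULT_PAD_S
) -> tuple[Recording, AnnotationSet]:
    """Extract +/- ``pad_s`` context around each annotated seizure and concatenate.

    Overlapping peri-event windows are merged (set union) before extraction
    so that no sample is duplicated.  All annotation intervals intersecting a
    kept window are remapped onto the concatenated time base; seizures are
    always fully contained in their own window, so their durations are
    preserved exactly.
    """
    if pad_s < 0:
        raise ValueError("pad_s must be non-negative")
    ann.check_within(rec)
    fs = rec.sampling_rate
    merged = _merged_windows(ann, rec.duration_s, pad_s)

    pieces = []
    offsets_s = []  # start time of each window in the output
    total = 0
    for lo, hi in merged:
        sl = interval_to_slice(lo, hi, fs)
        pieces.append(rec.samples[sl.start : min(sl.stop, rec.n_samples)])
        offsets_s.append(total / fs)
        total += len(pieces[-1])

    remapped: list[AnnotationInterval] = []
    for iv in ann:
        for (lo, hi), off in zip(merged, offsets_s):
            a = max(iv.start_s, lo)
            b = min(iv.end_s, hi)
            if b - a > _EPS:
                remapped.append(
                    AnnotationInterval(off + (a - lo), off + (b - lo), iv.label)
                )
    out = Recording(
        np.concatenate(pieces), fs, label=(rec.label + " (segmented)").strip()
    )
    return out, AnnotationSet(remapped)


def save_dataset(path: str | Path, rec: Recording, ann: AnnotationSet) -> None:
    """Write a preprocessed (recording, annotations) pair to a lossless .npz."""
    np.savez(
        path,
        samples=rec.samples,
        sampling_rate=np.float64(rec.sampling_rate),
        t0=np.float64(rec.t0),
        label=np.str_(rec.label),
        ann_start=np.array([iv.start_s for iv in ann], dtype=np.float64),
        ann_end=np.array([iv.end_s for iv in ann], dtype=np.float64),
        ann_label=np.array([iv.label for iv in ann], dtype=np.str_),
    )


def load_dataset(path: str | Path) -> tuple[Recording, AnnotationSet]:
    with np.load(path, allow_pickle=False) as z:
        rec = Recording(
            samples=z["samples"],
            sampling_rate=float(z["sampling_rate"]),
            label=str(z["label"]),
            t0=float(z["t0"]),
        )
        ann = AnnotationSet(
            [
                AnnotationInterval(float(s), float(e), str(l))
                for s, e, l in zip(z["ann_start"], z["ann_end"], z["ann_label"])
            ]
        )
    return rec, ann
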