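"""Embedded event monitor: debounced threshold classifier and event log.

The monitor is a two-state machine driving two stimulation programs: P0
(non-event) and P1 (event).  At each envelope sample it may switch state
when the amplitude crosses the configured threshold, but never sooner than
the debounce period (2 s on the device) after the previous switch — in
either direction, which also guarantees a minimum stimulation duration once
a program is entered.  Every program transition is recorded in a bounded
rolling event log with timestamps quantized to the log resolution (1-2 s).

Semantics of :func:`classify_stream` (single pass, no lookahead):

* the machine boots in P0 and the debounce timer counts as elapsed;
* in P0, the first sample with ``envelope >= threshold`` at or after the
  debounce expiry switches to P1; in P1, the first sample with
  ``envelope < threshold`` switches back;
* the per-sample label is the post-update state (P1 -> True).

Transitions keep their exact (unquantized) sample time alongside the
quantized log timestamp; evaluation matches events on the exact times and
only the exported log is quantized.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .signal_chain import Envelope

__all__ = [
    "StimProgram",
    "ClassifierConfig",
    "Transition",
    "EventLog",
    "SampleLabels",
    "classify_stream",
    "quantize_time",
    "append_with_capacity",
    "count_triggers",
    "default_programs",
]


@dataclass(frozen=True)
class StimProgram:
    """A stimulation parameter set; metadata only, no pulses are synthesized."""

    id: str
    amplitude_ma: float
    frequency_hz: float = 125.0
    pulse_width_us: float = 90.0
    recharge: str = "active"

    def __post_init__(self) -> None:
        if self.id not in ("P0", "P1"):
            raise ValueError(f"program id must be 'P0' or 'P1', got {self.id!r}")
        if self.amplitude_ma < 0:
            raise ValueError("stimulation amplitude must be >= 0 mA")
        if self.frequency_hz <= 0:
            raise ValueError("stimulation frequency must be positive")
        if self.pulse_width_us <= 0:
            raise ValueError("pulse width must be positive")
        if self.recharge not in ("active", "passive"):
            raise ValueError(f"recharge must be 'active' or 'passive', got {self.recharge!r}")


def default_programs() -> tuple[StimProgram, StimProgram]:
    """Default non-event / event programs (1 mA and 3 mA, 125 Hz, 90 us)."""
    return (
        StimProgram("P0", amplitude_ma=1.0),
        StimProgram("P1", amplitude_ma=3.0),
    )


@dataclass
class ClassifierConfig:
    """Threshold, debounce and logging settings of the embedded monitor.

    In seizure-diary mode the two programs carry identical settings; the
    monitor still logs every state transition.
    """

    threshold_uv: float
    debounce_s: float = 2.0
    program_nonevent: StimProgram = field(
        default_factory=lambda: default_programs()[0]
    )
    program_event: StimProgram = field(default_factory=lambda: default_programs()[1])
    log_resolution_s: float = 1.0
    log_capacity: int = 1200

    def __post_init__(self) -> None:
        if not self.threshold_uv > 0:
            raise ValueError("threshold_uv must be positive")
        if not self.debounce_s > 0:
            raise ValueError("debounce_s must be positive")
        if not 1.0 <= self.log_resolution_s <= 2.0:
            raise ValueError("log_resolution_s must lie in [1, 2] seconds")
        if self.log_capacity < 1:
            raise ValueError("log_capacity must be >= 1")
        if self.program_nonevent.id != "P0" or self.program_event.id != "P1":
            raise ValueError("program_nonevent must be P0 and program_event P1")


@dataclass(frozen=True)
class Transition:
    """One stimulation-program switch.

    ``time_s`` is the logged (quantized) timestamp; ``raw_time_s`` keeps the
    exact envelope-sample time used for event matching.
    """

    time_s: float
    from_program: str
    to_program: str
    raw_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.from_program == self.to_program:
            raise ValueError("a transition must change program")


@dataclass
class EventLog:
    """Bounded rolling memory of program transitions (oldest evicted first)."""

    capacity: int = 1200
    transitions: list[Transition] = field(default_factory=list)
    n_total: int = 0  # transitions ever recorded, including evicted ones

    def __post_init__(self) -> None:
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.n_total = max(self.n_total, len(self.transitions))

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def append(self, tr: Transition) -> None:
        if self.transitions:
            last = self.transitions[-1]
            if tr.time_s < last.time_s:
                raise ValueError(
                    f"out-of-order transition: {tr.time_s} s after {last.time_s} s"
                )
            if tr.from_program != last.to_program:
                raise ValueError("transitions must alternate direction")
        self.transitions.append(tr)
        self.n_total += 1
        if len(self.transitions) > self.capacity:
            del self.transitions[0]

    def onset_times(self, raw: bool = True) -> list[float]:
        """Times of P0 -> P1 transitions (detections)."""
        return [
            (tr.raw_time_s if raw and tr.raw_time_s is not None else tr.time_s)
            for tr in self.transitions
            if tr.to_program == "P1"
        ]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time_s,from_program,to_program\n")
            for tr in self.transitions:
                fh.write(f"{tr.time_s},{tr.from_program},{tr.to_program}\n")

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"time_s": tr.time_s, "from_program": tr.from_program,
             "to_program": tr.to_program}
            for tr in self.transitions
        ]
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SampleLabels:
    """Per-sample classifier state (True while the event program is active)."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")


def quantize_time(t: float, resolution_s: float) -> float:
    """Quantize a timestamp to the log resolution: floor(t / res) * res."""
    if not 1.0 <= resolution_s <= 2.0:
        raise ValueError("resolution_s must lie in [1, 2] seconds")
    return math.floor(t / resolution_s) * resolution_s


def append_with_capacity(log: EventLog, tr: Transition) -> EventLog:
    """Append a transition, evicting the oldest entry beyond capacity."""
    log.append(tr)
    return log


def count_triggers(log: EventLog) -> int:
    """Total program transitions recorded, both directions, including evicted."""
    return log.n_total


def _debounce_samples(debounce_s: float, fs: float) -> int:
    # minimal integer sample gap so that gap / fs >= debounce_s
    return int(math.ceil(round(debounce_s * fs, 9)))


def classify_stream(
    env: Envelope, cfg: ClassifierConfig
) -> tuple[SampleLabels, EventLog]:
    """Run the debounced threshold state machine over an envelope.

    Implemented by jumping between threshold crossings (equivalent to, but
    much faster than, a per-sample loop; the equivalence is part of the test
    suite's contract against an independent per-sample reference).
    """
    x = env.values
    fs = env.sampling_rate
    n = x.size
    above = x >= cfg.threshold_uv
    idx_above = np.flatnonzero(above)
    idx_below = np.flatnonzero(~above)
    gap = _debounce_samples(cfg.debounce_s, fs)

    log = EventLog(capacity=cfg.log_capacity)
    labels = np.zeros(n, dtype=bool)
    state_event = False
    i_allow = 0
    switch_samples: list[int] = []
    while True:
        pool = idx_above if not state_event else idx_below
        j = int(np.searchsorted(pool, i_allow))
        if j >= pool.size:
            break
        i = int(pool[j])
        state_event = not state_event
        switch_samples.append(i)
        i_allow = i + gap

    for k, i in enumerate(switch_samples):
        entering = k % 2 == 0  # transitions alternate, starting with P0 -> P1
        j_end = switch_samples[k + 1] if k + 1 < len(switch_samples) else n
        if entering:
            labels[i:j_end] = True
        raw_t = i / fs
        log.append(
            Transition(
                time_s=quantize_time(raw_t, cfg.log_resolution_s),
                from_program="P0" if entering else "P1",
                to_program="P1" if entering else "P0",
                raw_time_s=raw_t,
            )
        )
    return SampleLabels(labels, fs), log
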