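"""Independent reference implementations used as oracles by the test suite.

These are deliberately written in the most literal way possible (per-sample
loops, pairwise enumeration) and share no code with the package internals
they check.
"""

from __future__ import annotations

import numpy as np


def reference_classify(
    values: np.ndarray, fs: float, threshold: float, debounce_s: float
) -> tuple[np.ndarray, list[tuple[int, bool]]]:
    """Whole-array per-sample state machine: the streaming rules, literally.

    Returns (labels, transitions) where transitions are (sample_index,
    entered_event_state) pairs.
    """
    n = len(values)
    labels = np.zeros(n, dtype=bool)
    in_event = False
    last_switch: int | None = None
    transitions: list[tuple[int, bool]] = []
    for i in range(n):
        elapsed = last_switch is None or (i - last_switch) / fs >= debounce_s
        if not in_event and values[i] >= threshold and elapsed:
            in_event = True
            last_switch = i
            transitions.append((i, True))
        elif in_event and values[i] < threshold and elapsed:
            in_event = False
            last_switch = i
            transitions.append((i, False))
        labels[i] = in_event
    return labels, transitions


def brute_force_match(
    onsets: list[float],
    events: list[tuple[float, float]],
    window_s: float,
) -> tuple[int, int, int]:
    """Enumerate all (classification, event) pairs and count TP/FP/FN."""
    detected = set()
    fp = 0
    for t in onsets:
        hits = [
            k for k, (s, e) in enumerate(events) if s <= t <= e + window_s
        ]
        if hits:
            # attribute to the most recent overlapping event
            detected.add(max(hits, key=lambda k: events[k][0]))
        else:
            fp += 1
    return len(detected), fp, len(events) - len(detected)


def interval_union(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Brute-force union of closed intervals, sorted and merged."""
    out: list[tuple[float, float]] = []
    for lo, hi in sorted(intervals):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out
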