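"""Synthetic LFP generator with seizure ground truth.

Real patient recordings behind this class of monitor are not publicly
deposited, so every other module is exercised against surrogate data that
reproduces the *spectral contrast* the detector relies on: a 1/f^alpha
Gaussian background, and seizure epochs that add (a) a band-limited noise
"bump" (9-14 Hz by default) and (b) a broadband 0-22 Hz power increase,
both with 1 s raised-cosine on/off ramps so that event edges do not leak
broadband energy that would make detection artificially easy.

Gain semantics: an added component is scaled so its RMS equals
``(gain - 1)`` times its reference RMS (the background's in-band RMS for the
bump, the whole-background RMS for the broadband component).  ``gain = 1``
therefore adds nothing (the null case), and the in-band RMS during an event
is ``sqrt(1 + (gain - 1)^2)`` times background since independent noises add
in quadrature.

Default amplitudes: background RMS 10 uV and bump gain 10, which puts
seizure envelopes near the tens-of-microvolt thresholds typical of the
monitor's operating range; the generator is deterministic per seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_ingest import AnnotationInterval, AnnotationSet, Recording

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_background",
    "generate_seizure_component",
    "generate_dataset",
    "apply_gain",
]

#: Minimum start-to-start spacing between placed events (seconds) so that
#: +/- 30 s peri-event windows do not merge unless a test asks them to.
DEFAULT_EVENT_SPACING_S = 60.0

RAMP_S = 1.0  # raised-cosine on/off ramp length for seizure components


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic recording.

    Events are given either explicitly as ``seizure_times`` (start, duration)
    pairs, or drawn at ``seizure_rate_per_hour`` with durations uniform in
    ``event_duration_s``.
    """

    duration_s: float
    sampling_rate: float = 625.0
    background_rms_uv: float = 10.0
    spectral_exponent: float = 1.0
    seizure_times: list[tuple[float, float]] | None = None
    seizure_rate_per_hour: float = 60.0
    event_duration_s: tuple[float, float] = (8.0, 15.0)
    bump_band_hz: tuple[float, float] = (9.0, 14.0)
    bump_gain: float = 10.0
    broadband_band_hz: tuple[float, float] = (0.0, 22.0)
    broadband_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if self.background_rms_uv <= 0:
            raise ValueError("background_rms_uv must be positive")
        if self.bump_gain < 1 or self.broadband_gain < 1:
            raise ValueError("gains must be >= 1")
        nyq = self.sampling_rate / 2
        for name, (lo, hi) in (
            ("bump_band_hz", self.bump_band_hz),
            ("broadband_band_hz", self.broadband_band_hz),
        ):
            if not (0 <= lo < hi <= nyq):
                raise ValueError(f"{name} {lo, hi} invalid for Nyquist {nyq} Hz")
        if self.seizure_times is not None:
            prev_end = -math.inf
            for start, dur in sorted(self.seizure_times):
                if dur <= 0:
                    raise ValueError("event durations must be positive")
                if start < 0 or start + dur > self.duration_s:
                    raise ValueError(
                        f"event ({start}, {start + dur}) outside recording"
                    )
                if start < prev_end:
                    raise ValueError("seizure events must not overlap")
                prev_end = start + dur

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))


@dataclass
class GroundTruth:
    """Annotations plus the expected in-band amplitude of each event."""

    annotations: AnnotationSet
    event_band_rms_uv: list[float] = field(default_factory=list)


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """Unit-less Gaussian noise with power spectrum ~ 1/f^alpha, zero mean."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-alpha / 2.0)
    return np.fft.irfft(spec * shape, n=n)


def _to_rms(x: np.ndarray, target_rms: float) -> np.ndarray:
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0:
        return x
    return x * (target_rms / rms)


def inband_fraction(spec: SyntheticSpec, low_hz: float, high_hz: float) -> float:
    """Fraction of background power inside a band, from the 1/f^alpha model."""
    f = np.fft.rfftfreq(spec.n_samples, d=1.0 / spec.sampling_rate)[1:]
    p = f ** (-spec.spectral_exponent)
    mask = (f >= low_hz) & (f <= high_hz)
    return float(p[mask].sum() / p.sum())


def background_inband_rms(spec: SyntheticSpec, low_hz: float, high_hz: float) -> float:
    """Expected background RMS inside a band, in microvolts."""
    return spec.background_rms_uv * math.sqrt(
        inband_fraction(spec, max(low_hz, 1e-9), high_hz)
    )


def generate_background(spec: SyntheticSpec) -> Recording:
    """Seeded 1/f^alpha Gaussian background scaled to the requested RMS."""
    rng = np.random.default_rng(spec.seed)
    x = _shaped_noise(rng, spec.n_samples, spec.sampling_rate, spec.spectral_exponent)
    x = _to_rms(x, spec.background_rms_uv)
    return Recording(x, spec.sampling_rate, label="synthetic background")


def _band_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """White noise band-limited with a zero-phase Butterworth (order 4)."""
    white = rng.standard_normal(n)
    if lo <= 0:
        sos = signal.butter(4, hi, btype="lowpass", fs=fs, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def _ramp_window(n: int, fs: float, ramp_s: float = RAMP_S) -> np.ndarray:
    """Unit plateau with raised-cosine on/off ramps (shortened if needed)."""
    nr = int(round(min(ramp_s, n / fs / 2) * fs))
    w = np.ones(n)
    if nr > 0:
        up = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        w[:nr] = up
        w[n - nr :] = up[::-1]
    return w


def generate_seizure_component(
    spec: SyntheticSpec,
    event: tuple[float, float],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """The additive seizure signal for one ``(start_s, duration_s)`` event.

    Returns an array of the event's length (to be added onto the background
    at the event location): band-limited bump noise plus broadband noise,
    each scaled by its ``(gain - 1) x`` reference RMS, under the ramp window.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    start, dur = event
    if start < 0 or start + dur > spec.duration_s:
        raise ValueError(f"event ({start}, {start + dur}) outside recording")
    n = int(round(dur * spec.sampling_rate))
    fs = spec.sampling_rate

    bump_ref = background_inband_rms(spec, *spec.bump_band_hz)
    bump = _to_rms(
        _band_noise(rng, n, fs, *spec.bump_band_hz),
        (spec.bump_gain - 1.0) * bump_ref,
    ) if spec.bump_gain > 1 else np.zeros(n)

    broad = _to_rms(
        _band_noise(rng, n, fs, *spec.broadband_band_hz),
        (spec.broadband_gain - 1.0) * spec.background_rms_uv,
    ) if spec.broadband_gain > 1 else np.zeros(n)

    return (bump + broad) * _ramp_window(n, fs)


def _place_events(
    spec: SyntheticSpec, rng: np.random.Generator
) -> list[tuple[float, float]]:
    if spec.seizure_times is not None:
        return sorted(spec.seizure_times)
    n_events = int(round(spec.seizure_rate_per_hour * spec.duration_s / 3600.0))
    if n_events == 0:
        return []
    lo_d, hi_d = spec.event_duration_s
    durations = rng.uniform(lo_d, hi_d, size=n_events)
    # greedy placement on a jittered regular grid with minimum spacing
    slot = spec.duration_s / n_events
    if slot < DEFAULT_EVENT_SPACING_S and n_events > 1:
        raise ValueError(
            f"cannot place {n_events} events with "
            f"{DEFAULT_EVENT_SPACING_S} s spacing in {spec.duration_s} s"
        )
    events = []
    for k, dur in enumerate(durations):
        margin = slot - dur - 2.0
        if margin <= 0:
            raise ValueError("event durations too long for the requested rate")
        start = k * slot + 1.0 + rng.uniform(0, margin)
        events.append((float(start), float(dur)))
    return events


def generate_dataset(spec: SyntheticSpec) -> tuple[Recording, GroundTruth]:
    """Background plus seizure components, with ground-truth annotations.

    Events longer than 3 s are labeled ``seizure``; shorter bursts (only
    present if the caller asks for them) are interictal discharges.
    """
    rng = np.random.default_rng(spec.seed)
    x = _shaped_noise(rng, spec.n_samples, spec.sampling_rate, spec.spectral_exponent)
    x = _to_rms(x, spec.background_rms_uv)

    events = _place_events(spec, rng)
    intervals = []
    band_rms_truth = []
    bump_ref = background_inband_rms(spec, *spec.bump_band_hz)
    for start, dur in events:
        comp = generate_seizure_component(spec, (start, dur), rng)
        i0 = int(round(start * spec.sampling_rate))
        x[i0 : i0 + comp.size] += comp
        label = "seizure" if dur > 3.0 else "interictal"
        intervals.append(AnnotationInterval(start, start + dur, label))
        band_rms_truth.append(math.hypot(1.0, spec.bump_gain - 1.0) * bump_ref)

    rec = Recording(x, spec.sampling_rate, label="synthetic dataset")
    return rec, GroundTruth(AnnotationSet(intervals), band_rms_truth)


def apply_gain(rec: Recording, gain: float) -> Recording:
    """Scale every sample; models test-bench replay calibration error."""
    if not gain > 0:
        raise ValueError("gain must be positive")
    return Recording(rec.samples * gain, rec.sampling_rate, rec.label, rec.t0)
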