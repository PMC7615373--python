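"""Device filter-chain design and amplitude-envelope computation.

The embedded monitor thresholds a band-power amplitude envelope.  The chain
emulated here is: causal highpass (drift removal) -> causal bandpass
(patient-specific seizure band) -> full-wave rectifier -> causal "smoothing"
lowpass.  All stages are Butterworth IIR sections run in direct streaming
form (``sosfilt``); no zero-phase filtering is used anywhere in the chain,
because the device processes samples as they arrive.

Defaults correspond to a 9-14 Hz seizure band (centered on 11.5 Hz) with a
6.8 Hz highpass and 1 Hz smoothing lowpass at a 625 Hz sampling rate.

The module also provides the spectral utilities used during band selection:
Welch PSD estimates for annotated segments, the seizure-vs-background PSD
contrast, and band-limited RMS measurement (7-15 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_ingest import AnnotationInterval, AnnotationSet, Recording, interval_to_slice

__all__ = [
    "FilterChainConfig",
    "ChainCoefficients",
    "Envelope",
    "PsdEstimate",
    "design_chain",
    "compute_envelope",
    "band_rms",
    "compute_psd",
    "compare_state_psd",
    "band_power",
]


@dataclass
class FilterChainConfig:
    """Cutoff frequencies and per-stage order of the device signal chain.

    ``band_center_hz`` documents the design intent; the realized bandpass is
    fully determined by ``band_low_hz`` / ``band_high_hz``.
    """

    sampling_rate: float = 625.0
    highpass_hz: float = 6.8
    band_low_hz: float = 9.0
    band_center_hz: float = 11.5
    band_high_hz: float = 14.0
    smoothing_hz: float = 1.0
    order: int = 2

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not (0 < self.highpass_hz < self.band_low_hz):
            raise ValueError(
                f"highpass ({self.highpass_hz} Hz) must lie below the band "
                f"low cutoff ({self.band_low_hz} Hz)"
            )
        if not (self.band_low_hz < self.band_center_hz < self.band_high_hz):
            raise ValueError(
                f"band cutoffs must be ordered low < center < high, got "
                f"{self.band_low_hz}/{self.band_center_hz}/{self.band_high_hz} Hz"
            )
        if not self.band_high_hz < nyq:
            raise ValueError(
                f"band high cutoff {self.band_high_hz} Hz at or above Nyquist {nyq} Hz"
            )
        if not (0 < self.smoothing_hz < self.band_low_hz):
            raise ValueError(
                f"smoothing cutoff ({self.smoothing_hz} Hz) must lie below the "
                f"band low cutoff ({self.band_low_hz} Hz)"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass
class ChainCoefficients:
    """Designed second-order sections for each stage of the chain."""

    highpass_sos: np.ndarray
    bandpass_sos: np.ndarray
    smoothing_sos: np.ndarray
    sampling_rate: float

    def stages(self) -> dict[str, np.ndarray]:
        return {
            "highpass": self.highpass_sos,
            "bandpass": self.bandpass_sos,
            "smoothing": self.smoothing_sos,
        }

    def pole_radii(self) -> dict[str, float]:
        """Largest pole magnitude per stage (< 1 means stable)."""
        out = {}
        for name, sos in self.stages().items():
            _, p, _ = signal.sos2zpk(sos)
            out[name] = float(np.max(np.abs(p))) if p.size else 0.0
        return out

    def is_stable(self) -> bool:
        return all(r < 1.0 for r in self.pole_radii().values())

    def pre_rectifier_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response of highpass+bandpass (the linear part of the chain)."""
        w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / self.sampling_rate
        _, h1 = signal.sosfreqz(self.highpass_sos, worN=w)
        _, h2 = signal.sosfreqz(self.bandpass_sos, worN=w)
        return h1 * h2


@dataclass
class Envelope:
    """Non-negative amplitude envelope in microvolts, the thresholded quantity."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class PsdEstimate:
    """Welch power spectral density: power in uV^2/Hz on a frequency grid."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.asarray(self.power, dtype=np.float64)
        if np.any(self.power < 0):
            raise ValueError("PSD power must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def design_chain(cfg: FilterChainConfig) -> ChainCoefficients:
    """Design the three Butterworth stages and verify their stability."""
    fs = cfg.sampling_rate
    hp = signal.butter(cfg.order, cfg.highpass_hz, btype="highpass", fs=fs, output="sos")
    bp = signal.butter(
        cfg.order, [cfg.band_low_hz, cfg.band_high_hz], btype="bandpass", fs=fs,
        output="sos",
    )
    lp = signal.butter(cfg.order, cfg.smoothing_hz, btype="lowpass", fs=fs, output="sos")
    chain = ChainCoefficients(hp, bp, lp, fs)
    radii = chain.pole_radii()
    if any(r >= 1.0 for r in radii.values()):
        raise RuntimeError(f"designed chain is unstable: pole radii {radii}")
    return chain


def compute_envelope(rec: Recording, cfg: FilterChainConfig) -> Envelope:
    """Run the full causal chain: highpass -> bandpass -> |.| -> smoothing lowpass.

    The smoothing lowpass of a rectified signal can undershoot slightly at
    sharp amplitude drops; the envelope is clamped at zero, matching a
    physical detector whose output is a magnitude.
    """
    if rec.sampling_rate != cfg.sampling_rate:
        raise ValueError(
            f"recording rate {rec.sampling_rate} Hz != chain rate "
            f"{cfg.sampling_rate} Hz; resample first"
        )
    chain = design_chain(cfg)
    y = signal.sosfilt(chain.highpass_sos, rec.samples)
    y = signal.sosfilt(chain.bandpass_sos, y)
    y = np.abs(y)
    y = signal.sosfilt(chain.smoothing_sos, y)
    return Envelope(np.maximum(y, 0.0), rec.sampling_rate)


def band_rms(
    rec: Recording,
    low_hz: float = 7.0,
    high_hz: float = 15.0,
    interval: AnnotationInterval | tuple[float, float] | None = None,
) -> float:
    """RMS of the band-limited signal over an interval, in microvolts.

    Uses a zero-phase 4th-order Butterworth bandpass so the measurement
    window is not biased by filter delay; this is an analysis metric, not
    part of the streaming device chain.
    """
    fs = rec.sampling_rate
    if not (0 < low_hz < high_hz < fs / 2):
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz invalid for fs={fs} Hz")
    if interval is None:
        lo, hi = 0.0, rec.duration_s
    elif isinstance(interval, AnnotationInterval):
        lo, hi = interval.start_s, interval.end_s
    else:
        lo, hi = interval
    sl = interval_to_slice(lo, hi, fs)
    if sl.stop <= sl.start or sl.start >= rec.n_samples:
        raise ValueError(f"empty interval ({lo}, {hi}) s")
    sos = signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, rec.samples)
    seg = y[sl.start : min(sl.stop, rec.n_samples)]
    return float(np.sqrt(np.mean(seg**2)))


_PSD_SEGMENT_S = 2.0  # Welch segment length; 50% overlap, Hann window


def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray, int]:
    nperseg = int(round(_PSD_SEGMENT_S * fs))
    f, p = signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2,
        detrend="constant",
    )
    n_segments = max(1, 1 + (x.size - nperseg) // (nperseg - nperseg // 2))
    return f, p, n_segments


def compute_psd(
    rec: Recording,
    interval: AnnotationInterval | tuple[float, float] | None = None,
) -> PsdEstimate:
    """Welch PSD of an annotated segment (2 s Hann segments, 50 % overlap)."""
    fs = rec.sampling_rate
    if interval is None:
        lo, hi = 0.0, rec.duration_s
    elif isinstance(interval, AnnotationInterval):
        lo, hi = interval.start_s, interval.end_s
    else:
        lo, hi = interval
    sl = interval_to_slice(lo, hi, fs)
    x = rec.samples[sl.start : min(sl.stop, rec.n_samples)]
    if x.size < int(round(_PSD_SEGMENT_S * fs)):
        raise ValueError(
            f"interval ({lo}, {hi}) s shorter than the {_PSD_SEGMENT_S} s "
            "PSD segment length"
        )
    f, p, n = _welch(x, fs)
    # drop the DC bin so the grid is strictly positive band content
    return PsdEstimate(f[1:], p[1:], n)


def compare_state_psd(
    rec: Recording, ann: AnnotationSet
) -> tuple[PsdEstimate, PsdEstimate]:
    """Average PSDs separately over seizure intervals and their complement.

    Each state's PSD is the segment-count-weighted average of per-interval
    Welch estimates; intervals shorter than one PSD segment are skipped.
    """
    fs = rec.sampling_rate
    seizures = ann.seizure_intervals
    if not seizures:
        raise ValueError("no seizure intervals annotated")
    complement: list[tuple[float, float]] = []
    cursor = 0.0
    for iv in sorted(seizures, key=lambda iv: iv.start_s):
        if iv.start_s > cursor:
            complement.append((cursor, iv.start_s))
        cursor = max(cursor, iv.end_s)
    if rec.duration_s > cursor:
        complement.append((cursor, rec.duration_s))

    def averaged(pieces: list[tuple[float, float]], what: str) -> PsdEstimate:
        nmin = int(round(_PSD_SEGMENT_S * fs))
        acc = None
        freqs = None
        total = 0
        for lo, hi in pieces:
            sl = interval_to_slice(lo, hi, fs)
            x = rec.samples[sl.start : min(sl.stop, rec.n_samples)]
            if x.size < nmin:
                continue
            f, p, n = _welch(x, fs)
            freqs = f
            acc = p * n if acc is None else acc + p * n
            total += n
        if acc is None:
            raise ValueError(f"insufficient data ({what}): no piece spans "
                             f"{_PSD_SEGMENT_S} s")
        return PsdEstimate(freqs[1:], (acc / total)[1:], total)

    seiz = averaged([(iv.start_s, iv.end_s) for iv in seizures], "seizure")
    bg = averaged(complement, "background")
    return seiz, bg


def band_power(psd: PsdEstimate, low_hz: float, high_hz: float) -> float:
    """Integrated power (uV^2) in ``[low_hz, high_hz]`` by trapezoidal rule."""
    mask = (psd.frequencies >= low_hz) & (psd.frequencies <= high_hz)
    if mask.sum() < 2:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz covers <2 PSD bins")
    return float(np.trapezoid(psd.power[mask], psd.frequencies[mask]))
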