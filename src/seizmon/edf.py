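"""Minimal EDF (European Data Format) writer for single-channel LFP exports.

Only writing is implemented here; reading goes through MNE (see
:func:`seizmon.io_ingest.read_recording`).  The writer targets the simplest
valid EDF: one signal, 1-second data records, 16-bit samples with a
symmetric physical range in microvolts.  The last record is zero-padded when
the recording is not a whole number of seconds, so a round trip through an
EDF file preserves the signal but may extend it to the next full second.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

__all__ = ["write_edf"]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    samples_uv: np.ndarray,
    sampling_rate: float,
    channel: str = "LFP",
) -> None:
    """Write one channel of microvolt samples as an EDF file.

    ``sampling_rate`` must be a whole number of Hz (one data record per
    second).  The physical range is set just beyond the data extrema, so
    amplitude quantization error is at most ``phys_max / 32767``.
    """
    x = np.asarray(samples_uv, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("samples must be 1-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("samples contain non-finite values")
    fs = float(sampling_rate)
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record

    n_records = max(1, math.ceil(x.size / spr))
    padded = np.zeros(n_records * spr, dtype=np.float64)
    padded[: x.size] = x

    peak = float(np.max(np.abs(padded)))
    peak = peak if peak > 0 else 1.0
    # Format the physical range into <=7 ascii chars ("-" + value must fit 8),
    # then reparse so the header and the digital scaling agree exactly.
    for prec in (6, 5, 4, 3, 2, 1):
        s = f"{peak * 1.001:.{prec}g}"
        if len(s) <= 7 and float(s) >= peak:
            break
    else:
        raise ValueError(f"physical range {peak} not representable in EDF header")
    phys_max = float(s)
    dig_max = 32767
    digital = np.clip(
        np.round(padded / phys_max * dig_max), -dig_max, dig_max
    ).astype("<i2")

    header = b"".join(
        [
            _field("0", 8),  # version
            _field("X X X X", 80),  # local patient id (anonymous)
            _field("Startdate X X X X", 80),  # local recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(256 * 2), 8),  # header bytes: fixed + 1 signal
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),  # record duration, seconds
            _field("1", 4),  # number of signals
            # per-signal fields
            _field(channel, 16),
            _field("", 80),  # transducer
            _field("uV", 8),
            _field("-" + s, 8),
            _field(s, 8),
            _field(str(-dig_max), 8),
            _field(str(dig_max), 8),
            _field("", 80),  # prefiltering
            _field(str(spr), 8),
            _field("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
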