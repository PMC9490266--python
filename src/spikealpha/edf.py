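"""Minimal EDF (European Data Format) writer for 16-bit continuous EEG.

Writing covers exactly what the package needs: one continuous recording,
1-second data records, microvolt physical units.  Reading goes through
:mod:`mne` (see :func:`spikealpha.io.read_recording`), which also serves as an
independent check on files produced here.
"""

from __future__ import annotations

import datetime as _dt
import os

import numpy as np

from .core import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def read_samples_per_record(path: str | os.PathLike) -> list[int]:
    """Per-signal samples-per-record counts from an EDF header.

    Used to detect mixed sampling rates, which this package's montage does
    not allow.
    """
    with open(path, "rb") as fh:
        header = fh.read(256)
        ns = int(header[252:256].decode("ascii").strip())
        per_signal = fh.read(256 * ns)
    # field order: label(16) transducer(80) dim(8) pmin(8) pmax(8) dmin(8)
    # dmax(8) prefilter(80) samples(8) reserved(32) -- each repeated ns times
    offset = ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    field = per_signal[offset : offset + 8 * ns]
    return [int(field[i * 8 : (i + 1) * 8].decode("ascii").strip()) for i in range(ns)]


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as 16-bit EDF with 1-s data records.

    The signal is padded with zeros to a whole number of records.  Physical
    range is symmetric around zero, sized from the data; quantization error is
    bounded by (physical range)/65535 per sample.
    """
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    ns = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    sig = np.zeros((ns, n_rec * spr))
    sig[:, : rec.n_samples] = rec.signal

    pmax = max(1.0, float(np.abs(sig).max()) * 1.0001)
    # digitize with the header's (string-rounded) range so readers rescale
    # back exactly; the header field is 8 ascii chars
    pmax = float(f"{pmax:.6g}")
    pmin = -pmax
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.round((sig - pmin) * scale + _DIG_MIN).astype("<i2")

    start = _dt.datetime(1970, 1, 1) + _dt.timedelta(milliseconds=rec.start_time)
    header = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),
            _field("Startdate X X X X", 80),
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(str(256 * (1 + ns)), 8),
            _field("", 44),
            _field(str(n_rec), 8),
            _field("1", 8),
            _field(str(ns), 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_field(name, 16) for name in rec.channel_names),
            b"".join(_field("AgCl electrode", 80) for _ in range(ns)),
            b"".join(_field("uV", 8) for _ in range(ns)),
            b"".join(_field(f"{pmin:.6g}", 8) for _ in range(ns)),
            b"".join(_field(f"{pmax:.6g}", 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MIN), 8) for _ in range(ns)),
            b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
            b"".join(_field("", 80) for _ in range(ns)),
            b"".join(_field(str(spr), 8) for _ in range(ns)),
            b"".join(_field("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        # data records: per record, all samples of signal 1, then signal 2, ...
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
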