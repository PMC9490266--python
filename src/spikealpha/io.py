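"""File I/O: recordings (CSV / EDF), trial event tables (TSV), score sheets (CSV).

Dialects
--------
Recording CSV: one header row of channel names, then one row per sample,
values in microvolts.  Events TSV: columns ``trial_id, task,
fixation_onset_ms, response_ms, correct``.  Scores CSV: columns
``participant_id, score``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    EEGRecording,
    MontageError,
    OpennessLevel,
    OpennessRecord,
    Task,
    TrialEvent,
    classify_openness,
    validate_montage,
)
from .edf import write_edf

__all__ = [
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "read_scores",
    "write_scores",
    "label_scores",
]


def _read_csv_recording(
    path: Path, sample_rate: float, start_time: float
) -> EEGRecording:
    frame = pd.read_csv(path)
    validate_montage(list(frame.columns))
    # reorder columns to canonical montage order (case-insensitive match)
    by_upper = {c.strip().upper(): c for c in frame.columns}
    ordered = validate_montage(list(frame.columns))
    data = frame[[by_upper[c] for c in ordered]].to_numpy(dtype=float).T
    return EEGRecording(ordered, sample_rate, data, start_time)


def _read_edf_recording(path: Path, start_time: float | None) -> EEGRecording:
    import mne

    from .edf import read_samples_per_record

    if len(set(read_samples_per_record(path))) != 1:
        raise ValueError(f"non-uniform sample rate across EDF signals in {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = validate_montage(raw.ch_names)
    by_upper = {c.strip().upper(): c for c in raw.ch_names}
    picks = [raw.ch_names.index(by_upper[c]) for c in names]
    data_uv = raw.get_data()[picks] * 1e6  # mne returns Volts
    if start_time is None:
        meas = raw.info.get("meas_date")
        start_time = 0.0 if meas is None else meas.timestamp() * 1000.0
    return EEGRecording(names, float(raw.info["sfreq"]), data_uv, start_time)


def read_recording(
    path: str | os.PathLike,
    format: str | None = None,
    *,
    sample_rate: float = 128.0,
    start_time: float | None = None,
) -> EEGRecording:
    """Read a 14-channel recording from CSV or EDF.

    ``format`` is inferred from the suffix when omitted.  CSV carries no
    metadata, so ``sample_rate`` (default 128 Hz) and ``start_time`` apply;
    EDF supplies its own rate and start date.  Channel labels are matched
    case-insensitively against the montage and returned in canonical order.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv_recording(path, sample_rate, start_time or 0.0)
    if fmt == "edf":
        return _read_edf_recording(path, start_time)
    raise ValueError(f"unknown recording format {fmt!r} (expected csv or edf)")


def write_recording(
    rec: EEGRecording, path: str | os.PathLike, format: str | None = None
) -> None:
    """Write a recording as CSV (header + one row per sample) or EDF."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        frame = pd.DataFrame(rec.signal.T, columns=list(rec.channel_names))
        frame.to_csv(path, index=False, float_format="%.4f")
    elif fmt == "edf":
        write_edf(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r} (expected csv or edf)")


def read_events(path: str | os.PathLike) -> list[TrialEvent]:
    """Read a trial event table (TSV) into :class:`TrialEvent` objects."""
    frame = pd.read_csv(path, sep="\t")
    required = {"trial_id", "task", "fixation_onset_ms", "response_ms", "correct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    events = []
    for row in frame.itertuples(index=False):
        events.append(
            TrialEvent(
                trial_id=int(row.trial_id),
                task=Task(str(row.task)),
                fixation_onset=float(row.fixation_onset_ms),
                response_time=float(row.response_ms),
                correct=bool(row.correct),
            )
        )
    return events


def write_events(events: list[TrialEvent], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        {
            "trial_id": [e.trial_id for e in events],
            "task": [e.task.value for e in events],
            "fixation_onset_ms": [e.fixation_onset for e in events],
            "response_ms": [e.response_time for e in events],
            "correct": [e.correct for e in events],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def read_scores(path: str | os.PathLike) -> pd.DataFrame:
    """Read a questionnaire score sheet (participant_id, score)."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    if not {"participant_id", "score"} <= set(frame.columns):
        raise ValueError("scores file needs columns participant_id, score")
    return frame


def write_scores(records: list[OpennessRecord], path: str | os.PathLike) -> None:
    frame = pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "score": [r.score for r in records],
        }
    )
    frame.to_csv(path, index=False)


def label_scores(
    scores: pd.DataFrame, mu: float | None = None, sigma: float | None = None
) -> list[OpennessRecord]:
    """Ternarize a score sheet at mu +/- sigma.

    When ``mu``/``sigma`` are omitted they are estimated from the sample
    itself (mean and SD of the score column), which is how the population
    cutoffs are defined.
    """
    vals = scores["score"].to_numpy(dtype=float)
    mu = float(np.mean(vals)) if mu is None else mu
    sigma = float(np.std(vals, ddof=1)) if sigma is None else sigma
    return [
        OpennessRecord(str(pid), float(s), classify_openness(float(s), mu, sigma))
        for pid, s in zip(scores["participant_id"], vals)
    ]
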