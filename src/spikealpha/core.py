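"""Core domain types: recordings, trial events, epochs, openness labels.

The montage is the 14-sensor saline headset layout (10–20 positions), sampled
at 128 Hz.  A trial contributes two epochs: a 5-s *reference* interval covering
the pre-trial fixation cross and a 1-s *activation* interval immediately
preceding the participant's response.  Openness scores (1–6 Likert means) are
ternarized at mu ± sigma of the sampled population.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical electrode order of the 14-channel montage.
MONTAGE_14: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Bilateral channel pairs grouped into seven scalp areas.  Every montage
#: channel belongs to exactly one area.
BRAIN_AREAS: dict[str, tuple[str, str]] = {
    "anterior-frontal": ("AF3", "AF4"),
    "frontal-lateral": ("F7", "F8"),
    "frontal-medial": ("F3", "F4"),
    "fronto-central": ("FC5", "FC6"),
    "temporal": ("T7", "T8"),
    "parietal": ("P7", "P8"),
    "occipital": ("O1", "O2"),
}

#: Seconds of fixation used as the reference interval.
REFERENCE_SECONDS = 5.0
#: Seconds before the response used as the activation interval.
ACTIVATION_SECONDS = 1.0


class Task(str, enum.Enum):
    """Reasoning task type: symbolic (matrix items) or deductive (verbal items)."""

    SYMBOLIC = "symbolic"
    DEDUCTIVE = "deductive"


class EpochKind(str, enum.Enum):
    REFERENCE = "reference"
    ACTIVATION = "activation"


class OpennessLevel(enum.IntEnum):
    """Ternary openness level; integer values double as class indices."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2


class MontageError(ValueError):
    """Channel labels do not match the expected 14-channel montage."""


@dataclass
class EEGRecording:
    """Continuous multichannel EEG in microvolts.

    Parameters
    ----------
    channel_names : ordered channel labels (the 14-channel montage by default).
    sample_rate : sampling frequency in Hz.
    signal : channels x samples array, microvolts.
    start_time : Unix milliseconds of the first sample on the EEG host clock.
    """

    channel_names: tuple[str, ...]
    sample_rate: float
    signal: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D channels x samples array")
        if self.signal.shape[0] != len(self.channel_names):
            raise MontageError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class TrialEvent:
    """One reasoning trial on the behavioral host clock (milliseconds).

    ``fixation_onset`` marks the start of the 5-s pre-trial fixation cross;
    ``response_time`` the button press ending the trial.
    """

    trial_id: int
    task: Task
    fixation_onset: float
    response_time: float
    correct: bool

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if not self.response_time > self.fixation_onset:
            raise ValueError(
                f"trial {self.trial_id}: response_time must follow fixation_onset"
            )


@dataclass
class Epoch:
    """A fixed-length channels x time segment tagged reference or activation."""

    trial_id: int
    kind: EpochKind
    data: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.kind = EpochKind(self.kind)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        expect = (
            REFERENCE_SECONDS
            if self.kind is EpochKind.REFERENCE
            else ACTIVATION_SECONDS
        )
        n_expect = int(round(expect * self.sample_rate))
        if self.data.shape[1] != n_expect:
            raise ValueError(
                f"{self.kind.value} epoch must have {n_expect} samples at "
                f"{self.sample_rate} Hz, got {self.data.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class OpennessRecord:
    """A participant's questionnaire openness score and ternary level."""

    participant_id: str
    score: float
    level: OpennessLevel


def validate_montage(channel_names: list[str] | tuple[str, ...]) -> tuple[str, ...]:
    """Check labels against the 14-channel montage (case-insensitive).

    Returns the labels in canonical montage order.  Raises
    :class:`MontageError` naming missing and unexpected labels.
    """
    upper = {str(c).strip().upper(): str(c) for c in channel_names}
    missing = [c for c in MONTAGE_14 if c not in upper]
    extra = [orig for key, orig in upper.items() if key not in MONTAGE_14]
    if missing or extra or len(upper) != len(channel_names):
        raise MontageError(
            f"channel labels do not match the 14-channel montage: "
            f"missing={missing}, unexpected={extra}"
        )
    return MONTAGE_14


def align_clocks(t1: float, t2: float) -> float:
    """Clock offset between the EEG host and the behavioral host.

    ``t1`` is the Unix-ms timestamp of a shared event on the EEG host,
    ``t2`` the same event on the behavioral host.  The signed offset
    ``t2 - t1`` converts behavioral stamps to the EEG clock via
    :func:`behavioral_to_eeg`.
    """
    if t1 <= 0 or t2 <= 0:
        raise ValueError("timestamps must be positive Unix milliseconds")
    return float(t2) - float(t1)


def behavioral_to_eeg(stamp_ms: float, offset_ms: float) -> float:
    """Map a behavioral-clock stamp to the EEG clock: ``stamp + offset``."""
    return float(stamp_ms) + float(offset_ms)


def classify_openness(score: float, mu: float, sigma: float) -> OpennessLevel:
    """Ternarize an openness score at mu +/- sigma.

    Scores below ``mu - sigma`` are LOW, above ``mu + sigma`` HIGH, and the
    closed interval in between MEDIUM (boundary scores are MEDIUM).
    """
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    if not 1.0 <= score <= 6.0:
        raise ValueError(f"score {score} outside the 1-6 Likert range")
    if score < mu - sigma:
        return OpennessLevel.LOW
    if score > mu + sigma:
        return OpennessLevel.HIGH
    return OpennessLevel.MEDIUM


def openness_cutoffs(mu: float, sigma: float) -> tuple[float, float]:
    """The (low, high) score cutoffs ``mu - sigma`` and ``mu + sigma``."""
    return mu - sigma, mu + sigma


@dataclass
class EpochExtractionReport:
    """Epochs extracted from one recording plus per-trial skip reasons."""

    epochs: list[Epoch] = field(default_factory=list)
    skipped: dict[int, str] = field(default_factory=dict)


def extract_epochs(
    rec: EEGRecording,
    events: list[TrialEvent],
    offset_ms: float = 0.0,
    *,
    fixation_duration_ms: float = REFERENCE_SECONDS * 1000.0,
) -> EpochExtractionReport:
    """Cut reference and activation epochs for each trial.

    The reference epoch is the 5 s ending at fixation offset
    (``fixation_onset + fixation_duration``); the activation epoch is the
    1 s immediately before ``response_time``.  Behavioral stamps are mapped
    to the EEG clock with ``offset_ms`` before indexing into the recording.
    Trials whose intervals fall outside the recording are skipped with a
    logged warning rather than raising.
    """
    fs = rec.sample_rate
    report = EpochExtractionReport()

    def _cut(end_ms_eeg: float, seconds: float) -> np.ndarray | None:
        n = int(round(seconds * fs))
        stop = int(round((end_ms_eeg - rec.start_time) * fs / 1000.0))
        start = stop - n
        if start < 0 or stop > rec.n_samples:
            return None
        return rec.signal[:, start:stop]

    for ev in events:
        ref_end = behavioral_to_eeg(ev.fixation_onset + fixation_duration_ms, offset_ms)
        act_end = behavioral_to_eeg(ev.response_time, offset_ms)
        ref = _cut(ref_end, REFERENCE_SECONDS)
        act = _cut(act_end, ACTIVATION_SECONDS)
        if ref is None or act is None:
            which = "reference" if ref is None else "activation"
            msg = f"{which} interval outside recording"
            report.skipped[ev.trial_id] = msg
            logger.warning("trial %d skipped: %s", ev.trial_id, msg)
            continue
        report.epochs.append(Epoch(ev.trial_id, EpochKind.REFERENCE, ref, fs))
        report.epochs.append(Epoch(ev.trial_id, EpochKind.ACTIVATION, act, fs))
    return report
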