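"""Synthetic questionnaire scores and 14-channel EEG with programmed
task-related alpha effects.

Each simulated trial is 1/f (pink) background noise plus an upper-alpha
sinusoid plus white sensor noise on every channel.  The activation interval's
alpha amplitude on a channel is the reference amplitude times exp(Δ/2), where
Δ is the programmed log-power change for that channel's scalp area, the
participant's openness level and the task — so the programmed TRP equals Δ
exactly (power scales with amplitude squared).

The default effect template encodes the qualitative pattern the analysis
targets: in the symbolic task, high openness shows stronger frontal alpha
synchronization; in the deductive task the direction reverses (low openness
shows the stronger anterior-frontal/frontal synchronization).  Magnitudes are
free parameters.  ``separable_effect_template`` programs three mutually
distinct classes (low −Δ, medium 0, high +Δ on frontal areas) for classifier
learning checks, where the qualitative template would leave two classes
statistically identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .core import (
    BRAIN_AREAS,
    MONTAGE_14,
    EEGRecording,
    Epoch,
    EpochKind,
    OpennessLevel,
    OpennessRecord,
    Task,
    TrialEvent,
    classify_openness,
)
from . import io as spio

__all__ = [
    "SimParams",
    "SimDataset",
    "default_effect_template",
    "separable_effect_template",
    "pink_noise",
    "gen_scores",
    "gen_trial",
    "gen_dataset",
]

EffectTemplate = dict[tuple[OpennessLevel, Task], dict[str, float]]

_AREA_OF = {ch: area for area, pair in BRAIN_AREAS.items() for ch in pair}

_FRONTAL = ("frontal-lateral", "frontal-medial")
_ANT_FRONTAL = ("anterior-frontal", "frontal-lateral")


def default_effect_template(strong: float = 0.6, weak: float = 0.1) -> EffectTemplate:
    """Qualitative effect pattern: frontal synchronization strongest for high
    openness in the symbolic task and for low openness in the deductive task;
    all other areas null."""
    tpl: EffectTemplate = {}
    for level in OpennessLevel:
        sym = {a: (strong if level is OpennessLevel.HIGH else weak) for a in _FRONTAL}
        ded = {a: (strong if level is OpennessLevel.LOW else weak) for a in _ANT_FRONTAL}
        tpl[(level, Task.SYMBOLIC)] = sym
        tpl[(level, Task.DEDUCTIVE)] = ded
    return tpl


def separable_effect_template(
    delta: float = 0.8, areas: tuple[str, ...] = _FRONTAL
) -> EffectTemplate:
    """Three mutually distinct classes: low −delta, medium 0, high +delta on
    the given areas, identical in both tasks."""
    signs = {OpennessLevel.LOW: -1.0, OpennessLevel.MEDIUM: 0.0, OpennessLevel.HIGH: 1.0}
    return {
        (level, task): {a: signs[level] * delta for a in areas}
        for level in OpennessLevel
        for task in Task
    }


@dataclass
class SimParams:
    """Study-design and signal parameters of the generator.

    The design defaults mirror the experiment the analysis assumes: three
    openness levels, 7 participants per level, 4 blocks x 6 trials = 24
    trials each, 128 Hz; questionnaire scores Normal(3.75, 0.71) on the 1-6
    scale.  Signal amplitudes (μV) are set to plausible scalp-EEG magnitudes:
    8 μV RMS pink background, 10 μV reference alpha, 2 μV white sensor noise.
    """

    n_participants_per_level: int = 7
    trials_per_participant: int = 24
    sample_rate: float = 128.0
    score_mu: float = 3.75
    score_sigma: float = 0.71
    background_amp: float = 8.0
    alpha_amp: float = 10.0
    alpha_freq: float = 11.0
    noise_sd: float = 2.0
    pink_exponent: float = 1.0
    task: Task = Task.SYMBOLIC
    trp_effect: EffectTemplate = field(default_factory=default_effect_template)
    seed: int = 0

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        for amp in (self.background_amp, self.alpha_amp, self.noise_sd):
            if amp < 0:
                raise ValueError("amplitudes must be non-negative")
        if not 10.0 <= self.alpha_freq <= 12.0:
            raise ValueError("alpha_freq must lie in the 10-12 Hz upper alpha band")

    def channel_delta(self, level: OpennessLevel, task: Task) -> np.ndarray:
        """Per-channel programmed Δ, expanded from the area-keyed template."""
        key = (OpennessLevel(level), Task(task))
        if key not in self.trp_effect:
            raise KeyError(f"no programmed effect for {key}")
        area_delta = self.trp_effect[key]
        unknown = set(area_delta) - set(BRAIN_AREAS)
        if unknown:
            raise KeyError(f"unknown areas in effect template: {sorted(unknown)}")
        return np.array([area_delta.get(_AREA_OF[ch], 0.0) for ch in MONTAGE_14])


def pink_noise(
    n_samples: int,
    n_channels: int,
    rng: np.random.Generator,
    exponent: float = 1.0,
) -> np.ndarray:
    """1/f^exponent noise by spectral shaping of white noise, unit RMS rows."""
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spectrum * shape, n=n_samples, axis=1)
    rms = shaped.std(axis=1, keepdims=True)
    return shaped / np.where(rms > 0, rms, 1.0)


def gen_scores(
    n: int, p: SimParams | None = None, rng: np.random.Generator | None = None
) -> list[OpennessRecord]:
    """Draw n questionnaire scores Normal(mu, sigma) clipped to [1, 6] and
    label them with the sample's own mean and SD."""
    p = p or SimParams()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng or np.random.default_rng(p.seed)
    scores = np.clip(rng.normal(p.score_mu, p.score_sigma, size=n), 1.0, 6.0)
    mu = float(scores.mean())
    sigma = float(scores.std(ddof=1)) if n > 1 else max(p.score_sigma, 1e-9)
    sigma = max(sigma, 1e-9)
    return [
        OpennessRecord(f"P{i:03d}", float(s), classify_openness(float(s), mu, sigma))
        for i, s in enumerate(scores)
    ]


def _segment(
    n: int,
    alpha_amp_per_channel: np.ndarray,
    p: SimParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """One multichannel segment: pink background + alpha sinusoid + white noise."""
    t = np.arange(n) / p.sample_rate
    phase = rng.uniform(0, 2 * np.pi, size=(len(MONTAGE_14), 1))
    alpha = alpha_amp_per_channel[:, None] * np.sin(2 * np.pi * p.alpha_freq * t + phase)
    pink = p.background_amp * pink_noise(n, len(MONTAGE_14), rng, p.pink_exponent)
    white = p.noise_sd * rng.standard_normal((len(MONTAGE_14), n))
    return pink + alpha + white


def gen_trial(
    level: OpennessLevel,
    task: Task,
    p: SimParams,
    rng: np.random.Generator,
    trial_id: int = 0,
) -> tuple[Epoch, Epoch]:
    """One simulated trial: a 5-s reference epoch and a 1-s activation epoch.

    The activation alpha amplitude per channel is the reference amplitude
    times exp(Δ/2) with Δ from the effect template; a common per-trial
    amplitude factor (lognormal, σ=0.1) models trial-to-trial alpha
    variability and cancels exactly in the log-power change.
    """
    delta = p.channel_delta(level, task)
    trial_gain = float(np.exp(rng.normal(0.0, 0.1)))
    ref_amp = np.full(len(MONTAGE_14), p.alpha_amp) * trial_gain
    act_amp = ref_amp * np.exp(delta / 2.0)
    fs = p.sample_rate
    ref = _segment(int(round(5 * fs)), ref_amp, p, rng)
    act = _segment(int(round(1 * fs)), act_amp, p, rng)
    return (
        Epoch(trial_id, EpochKind.REFERENCE, ref, fs),
        Epoch(trial_id, EpochKind.ACTIVATION, act, fs),
    )


@dataclass
class SimDataset:
    """Generated dataset: epoch arrays for modeling plus per-participant files.

    X : activation epochs (n, 14, 128) — the classifier samples.
    X_ref : matching reference epochs (n, 14, 640).
    y : openness level per sample (0 low, 1 medium, 2 high).
    groups : participant index per sample (for subject-wise splitting).
    """

    X: np.ndarray
    X_ref: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    scores: list[OpennessRecord]
    recordings: dict[str, EEGRecording]
    events: dict[str, list[TrialEvent]]
    clock_offset_ms: float
    params: SimParams

    @property
    def n_samples(self) -> int:
        return len(self.X)


def _participant_score(
    level: OpennessLevel, p: SimParams, rng: np.random.Generator
) -> float:
    """Score drawn from the population normal truncated to the level's band."""
    lo, hi = {
        OpennessLevel.LOW: (1.0, p.score_mu - p.score_sigma - 1e-6),
        OpennessLevel.MEDIUM: (p.score_mu - p.score_sigma, p.score_mu + p.score_sigma),
        OpennessLevel.HIGH: (p.score_mu + p.score_sigma + 1e-6, 6.0),
    }[level]
    for _ in range(1000):
        s = rng.normal(p.score_mu, p.score_sigma)
        if lo <= s <= hi:
            return float(s)
    return float((lo + hi) / 2.0)


def gen_dataset(p: SimParams | None = None, out_dir: str | os.PathLike | None = None) -> SimDataset:
    """Generate the full dataset for one task; optionally write it to disk.

    Per participant a continuous recording is assembled from 24 trials of
    [5-s fixation][reasoning, 2.5-4 s, activation in its last second]
    [1.5-s feedback], with a trial event table on a behavioral clock offset
    from the EEG clock by a constant.  Sample count is
    3 levels x n_participants_per_level x trials_per_participant.

    When ``out_dir`` is given, recordings (CSV), events (TSV), scores (CSV)
    and the parameters (YAML) are written in the package's file dialects;
    identical seeds yield byte-identical files.
    """
    p = p or SimParams()
    rng = np.random.default_rng(p.seed)
    fs = p.sample_rate
    offset_ms = 250.0  # behavioral clock leads the EEG clock by a constant
    start_time = 1_700_000_000_000.0

    X, X_ref, y, groups = [], [], [], []
    scores: list[OpennessRecord] = []
    recordings: dict[str, EEGRecording] = {}
    events: dict[str, list[TrialEvent]] = {}

    pidx = 0
    for level in OpennessLevel:
        for _ in range(p.n_participants_per_level):
            pid = f"S{pidx:03d}"
            score = _participant_score(level, p, rng)
            scores.append(OpennessRecord(pid, score, level))
            delta = p.channel_delta(level, p.task)

            segments: list[np.ndarray] = []
            ev: list[TrialEvent] = []
            cursor = 0  # samples
            for trial in range(p.trials_per_participant):
                trial_gain = float(np.exp(rng.normal(0.0, 0.1)))
                ref_amp = np.full(len(MONTAGE_14), p.alpha_amp) * trial_gain
                act_amp = ref_amp * np.exp(delta / 2.0)

                n_fix = int(round(5 * fs))
                rt_s = rng.uniform(2.5, 4.0)
                n_task = int(round(rt_s * fs))
                n_act = int(round(1 * fs))
                n_feedback = int(round(1.5 * fs))

                fix = _segment(n_fix, ref_amp, p, rng)
                pre = _segment(n_task - n_act, ref_amp, p, rng)
                act = _segment(n_act, act_amp, p, rng)
                fb = _segment(n_feedback, ref_amp * 0.0, p, rng)

                eeg_fix_onset = start_time + cursor / fs * 1000.0
                eeg_response = start_time + (cursor + n_fix + n_task) / fs * 1000.0
                ev.append(
                    TrialEvent(
                        trial_id=trial,
                        task=p.task,
                        fixation_onset=eeg_fix_onset - offset_ms,
                        response_time=eeg_response - offset_ms,
                        correct=bool(rng.random() < 0.7),
                    )
                )
                segments += [fix, pre, act, fb]
                cursor += n_fix + n_task + n_feedback

                X.append(act)
                X_ref.append(fix)
                y.append(int(level))
                groups.append(pidx)

            rec = EEGRecording(MONTAGE_14, fs, np.concatenate(segments, axis=1), start_time)
            recordings[pid] = rec
            events[pid] = ev
            pidx += 1

    ds = SimDataset(
        X=np.asarray(X),
        X_ref=np.asarray(X_ref),
        y=np.asarray(y, dtype=int),
        groups=np.asarray(groups, dtype=int),
        scores=scores,
        recordings=recordings,
        events=events,
        clock_offset_ms=offset_ms,
        params=p,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SimDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for pid, rec in ds.recordings.items():
        spio.write_recording(rec, out_dir / f"{pid}.csv")
        spio.write_events(ds.events[pid], out_dir / f"{pid}_events.tsv")
    spio.write_scores(ds.scores, out_dir / "scores.csv")
    params = asdict(ds.params)
    params["task"] = ds.params.task.value
    params["trp_effect"] = {
        f"{level.name.lower()}/{task.value}": dict(sorted(areas.items()))
        for (level, task), areas in ds.params.trp_effect.items()
    }
    start_times = {rec.start_time for rec in ds.recordings.values()}
    with open(out_dir / "params.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "params": params,
                "clock_offset_ms": ds.clock_offset_ms,
                # CSV carries no clock metadata; readers need this to map
                # the event tables back onto the recordings
                "recording_start_time_ms": float(start_times.pop()),
            },
            fh,
            sort_keys=True,
        )
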