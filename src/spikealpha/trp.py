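"""Task-related power (TRP) of the upper alpha band.

The pipeline: zero-phase FIR bandpass (0.1–50 Hz) of the continuous
recording; per-epoch band power in the 10–12 Hz upper alpha band via an FFT
filter applied to 1000-ms Hanning windows with 900-ms overlap (power in μV²,
averaged per trial); then for each electrode i

    TRP(i) = log Pow_act(i) − log Pow_ref(i)

so positive TRP is alpha synchronization (power increase from the reference
fixation interval to the pre-response activation interval) and negative TRP
is desynchronization.  Trial TRPs are averaged per participant and channel,
and bilateral channel pairs are averaged into seven scalp areas.

Numerical choices documented in docs/methods.md: the FIR is designed by the
Hamming-window rule from the 0.35 Hz transition bandwidth with its tap mean
subtracted so DC is nulled exactly; window k of the Hanning grid starts at
round(k * 0.1 * fs) samples, realizing floor((N_ms − 1000)/100) + 1 windows;
alpha-band FFT bins are selected on the closed interval [10, 12] Hz,
symmetrically over negative frequencies.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import BRAIN_AREAS, MONTAGE_14, EEGRecording, Epoch

__all__ = [
    "FilterSpec",
    "BandPowerSeries",
    "TRPResult",
    "design_fir",
    "bandpass_fir",
    "window_starts",
    "alpha_band_power",
    "compute_trp",
    "reject_artifacts",
    "aggregate_trp",
    "participant_trp",
    "write_trp_csv",
]


@dataclass
class FilterSpec:
    """Preprocessing and band-power parameters.

    band_low/band_high : FIR bandpass edges, Hz.
    transition_bw : FIR transition bandwidth, Hz; sets the tap count by the
        Hamming-window rule numtaps = ceil(3.3 * fs / transition_bw).
    numtaps : optional literal tap-count override.
    alpha_band : band of interest for the FFT filter, Hz (upper alpha).
    win_ms / overlap_ms : Hanning window length and overlap.
    log_base : base of the logarithm in the TRP formula (natural log).
    amp_limit : artifact rejection threshold, μV.
    """

    band_low: float = 0.1
    band_high: float = 50.0
    transition_bw: float = 0.35
    numtaps: int | None = None
    alpha_band: tuple[float, float] = (10.0, 12.0)
    win_ms: float = 1000.0
    overlap_ms: float = 900.0
    log_base: float = math.e
    amp_limit: float = 100.0

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not self.overlap_ms < self.win_ms:
            raise ValueError("overlap_ms must be below win_ms")

    @property
    def hop_ms(self) -> float:
        return self.win_ms - self.overlap_ms


@dataclass
class BandPowerSeries:
    """Per-window alpha-band power (μV²) for one channel of one epoch."""

    channel: str
    per_window_power: np.ndarray
    trial_mean: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_window_power = np.asarray(self.per_window_power, dtype=float)
        if self.per_window_power.size == 0:
            raise ValueError("empty power series")
        if np.any(self.per_window_power < 0):
            raise ValueError("band power must be non-negative")
        self.trial_mean = float(self.per_window_power.mean())


@dataclass
class TRPResult:
    """Participant-level TRP aggregates.

    per_trial : trials x channels array of single-trial TRPs.
    channel_means : channel label -> mean TRP over trials.
    area_means : scalp area -> mean of its two paired channels.
    """

    per_trial: np.ndarray
    channel_means: dict[str, float]
    area_means: dict[str, float]


def design_fir(spec: FilterSpec, sample_rate: float) -> np.ndarray:
    """Design the bandpass FIR taps for a given sample rate.

    Hamming-windowed design; the tap count follows the 3.3/Δf rule unless
    ``spec.numtaps`` overrides it (forced odd for a type-I linear-phase
    filter).  The tap mean is subtracted afterwards so the response at 0 Hz
    is exactly zero; the perturbation elsewhere is below 2e-4.
    """
    nyq = sample_rate / 2.0
    if not spec.band_high < nyq:
        raise ValueError(f"band_high {spec.band_high} must be below Nyquist {nyq}")
    n = spec.numtaps or int(np.ceil(3.3 * sample_rate / spec.transition_bw))
    if n % 2 == 0:
        n += 1
    taps = sps.firwin(
        n,
        [spec.band_low, spec.band_high],
        pass_zero=False,
        window="hamming",
        fs=sample_rate,
    )
    return taps - taps.sum() / n


def bandpass_fir(rec: EEGRecording, spec: FilterSpec | None = None) -> EEGRecording:
    """Zero-phase FIR bandpass of every channel (filtfilt; no phase shift)."""
    spec = spec or FilterSpec()
    taps = design_fir(spec, rec.sample_rate)
    padlen = 3 * len(taps)
    if rec.n_samples <= padlen:
        need = (padlen + 1) / rec.sample_rate
        raise ValueError(
            f"recording too short for the {len(taps)}-tap filter: need more "
            f"than {need:.1f} s at {rec.sample_rate} Hz"
        )
    filtered = sps.filtfilt(taps, [1.0], rec.signal, axis=1, padlen=padlen)
    return EEGRecording(rec.channel_names, rec.sample_rate, filtered, rec.start_time)


def window_starts(n_samples: int, sample_rate: float, spec: FilterSpec) -> np.ndarray:
    """Start samples of the Hanning window grid for an epoch of given length.

    Window k starts at round(k * hop_ms * fs / 1000); the count equals
    floor((N_ms − win_ms)/hop_ms) + 1 with N_ms = 1000 * n_samples / fs.
    """
    n_ms = 1000.0 * n_samples / sample_rate
    if n_ms < spec.win_ms:
        raise ValueError(
            f"epoch of {n_ms:.0f} ms shorter than one {spec.win_ms:.0f} ms window"
        )
    count = int(np.floor((n_ms - spec.win_ms) / spec.hop_ms)) + 1
    hop_samples = spec.hop_ms * sample_rate / 1000.0
    return np.round(np.arange(count) * hop_samples).astype(int)


def _band_bins(n_fft: int, sample_rate: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.fftfreq(n_fft, d=1.0 / sample_rate)
    lo, hi = band
    return (np.abs(freqs) >= lo) & (np.abs(freqs) <= hi)


def alpha_band_power(epoch: Epoch, spec: FilterSpec | None = None) -> list[BandPowerSeries]:
    """Windowed alpha-band power for every channel of one epoch.

    Each Hanning window is FFT-filtered (bins outside the closed alpha band
    zeroed, symmetrically over negative frequencies), inverse-transformed,
    squared sample-wise, and averaged over the window; the per-window values
    are averaged into the trial mean.  Units are μV².
    """
    spec = spec or FilterSpec()
    fs = epoch.sample_rate
    win_n = int(round(spec.win_ms * fs / 1000.0))
    starts = window_starts(epoch.n_samples, fs, spec)
    hann = np.hanning(win_n)
    keep = _band_bins(win_n, fs, spec.alpha_band)

    powers = np.empty((len(starts), epoch.data.shape[0]))
    for k, s in enumerate(starts):
        seg = epoch.data[:, s : s + win_n] * hann
        spectrum = np.fft.fft(seg, axis=1)
        spectrum[:, ~keep] = 0.0
        filtered = np.fft.ifft(spectrum, axis=1).real
        powers[k] = (filtered**2).mean(axis=1)

    return [
        BandPowerSeries(name, powers[:, i])
        for i, name in enumerate(MONTAGE_14[: epoch.data.shape[0]])
    ]


def compute_trp(pow_act: float, pow_ref: float, base: float = math.e) -> float:
    """Log power change log(Pow_act) − log(Pow_ref); natural log by default."""
    if pow_act <= 0 or pow_ref <= 0:
        raise ValueError("band powers must be positive for the log-power change")
    return (math.log(pow_act) - math.log(pow_ref)) / math.log(base)


def reject_artifacts(epoch: Epoch, amp_limit: float = 100.0) -> bool:
    """Keep an epoch iff its maximum absolute amplitude is within amp_limit μV.

    Automated stand-in for visual artifact screening (blinks, EMG, movement);
    the closed boundary keeps an epoch at exactly the limit.
    """
    if not amp_limit > 0:
        raise ValueError("amp_limit must be positive")
    return bool(np.max(np.abs(epoch.data)) <= amp_limit)


def aggregate_trp(
    per_trial: np.ndarray | list,
    areas: dict[str, tuple[str, str]] | None = None,
    channel_names: tuple[str, ...] = MONTAGE_14,
) -> TRPResult:
    """Average single-trial channel TRPs into participant and area values.

    ``per_trial`` is trials x channels.  Area values are the mean of each
    bilateral channel pair's participant-level means.
    """
    areas = areas or BRAIN_AREAS
    arr = np.asarray(per_trial, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("need at least one surviving trial (trials x channels)")
    ch_means = arr.mean(axis=0)
    idx = {name: i for i, name in enumerate(channel_names)}
    channel_means = {name: float(ch_means[idx[name]]) for name in channel_names}
    area_means = {
        area: float((channel_means[a] + channel_means[b]) / 2.0)
        for area, (a, b) in areas.items()
    }
    return TRPResult(arr, channel_means, area_means)


def participant_trp(
    ref_epochs: list[Epoch],
    act_epochs: list[Epoch],
    spec: FilterSpec | None = None,
    participant_id: str = "",
) -> TRPResult:
    """Full per-participant TRP: artifact screen, band power, log change, average.

    ``ref_epochs`` and ``act_epochs`` are matched by position (one pair per
    trial).  A trial survives only if both of its epochs pass the amplitude
    screen.  Raises if no trial survives, naming the participant.
    """
    spec = spec or FilterSpec()
    if len(ref_epochs) != len(act_epochs):
        raise ValueError("reference and activation epoch lists must pair up")
    rows = []
    for ref, act in zip(ref_epochs, act_epochs):
        if not (reject_artifacts(ref, spec.amp_limit) and reject_artifacts(act, spec.amp_limit)):
            continue
        p_ref = alpha_band_power(ref, spec)
        p_act = alpha_band_power(act, spec)
        rows.append(
            [
                compute_trp(a.trial_mean, r.trial_mean, spec.log_base)
                for a, r in zip(p_act, p_ref)
            ]
        )
    if not rows:
        raise ValueError(
            f"no artifact-free trials for participant {participant_id or '<unknown>'}"
        )
    return aggregate_trp(np.asarray(rows))


def write_trp_csv(
    results: dict[tuple[str, str], TRPResult], path: str | os.PathLike
) -> pd.DataFrame:
    """Write tidy TRP output: participant_id, task, channel, area, trp."""
    area_of = {ch: area for area, pair in BRAIN_AREAS.items() for ch in pair}
    records = [
        {
            "participant_id": pid,
            "task": task,
            "channel": ch,
            "area": area_of[ch],
            "trp": trp,
        }
        for (pid, task), res in sorted(results.items())
        for ch, trp in res.channel_means.items()
    ]
    frame = pd.DataFrame.from_records(records)
    frame.to_csv(path, index=False)
    return frame
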