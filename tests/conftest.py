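import numpy as np
import pytest
from hypothesis import settings

from spikealpha.core import MONTAGE_14, Epoch, EpochKind, Task, TrialEvent

# deterministic property tests, no wall-clock flakiness on loaded machines
settings.register_profile("package", deadline=None, derandomize=True)
settings.load_profile("package")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_epoch():
    """Factory for epochs filled with a given array or a constant."""

    def _make(kind=EpochKind.ACTIVATION, data=None, fill=0.0, fs=128.0, trial_id=0):
        n = int((5 if EpochKind(kind) is EpochKind.REFERENCE else 1) * fs)
        if data is None:
            data = np.full((len(MONTAGE_14), n), fill)
        return Epoch(trial_id, kind, data, fs)

    return _make


@pytest.fixture
def sine_epoch():
    """Epoch factory with one sinusoid on every channel."""

    def _make(freq, amp=1.0, kind=EpochKind.REFERENCE, fs=128.0, phase=0.0):
        n = int((5 if EpochKind(kind) is EpochKind.REFERENCE else 1) * fs)
        t = np.arange(n) / fs
        row = amp * np.sin(2 * np.pi * freq * t + phase)
        return Epoch(0, kind, np.tile(row, (len(MONTAGE_14), 1)), fs)

    return _make


@pytest.fixture
def trial_events():
    """24 well-formed trials on a behavioral clock starting at t=1000 ms."""

    def _make(n=24, fixation_ms=5000.0, rt_ms=3000.0, gap_ms=1500.0, t0=1000.0):
        events, cursor = [], t0
        for i in range(n):
            events.append(
                TrialEvent(
                    trial_id=i,
                    task=Task.SYMBOLIC,
                    fixation_onset=cursor,
                    response_time=cursor + fixation_ms + rt_ms,
                    correct=True,
                )
            )
            cursor += fixation_ms + rt_ms + gap_ms
        return events

    return _make
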