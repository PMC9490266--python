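"""Input scaling and sign-preserving Poisson rate coding.

An activation epoch (14 x 128 samples) is scaled into [−1, 1] by its global
maximum absolute amplitude, then unrolled over T discrete timesteps: at each
timestep an entry x fires a spike of polarity sign(x) with probability |x|
(an independent Uniform(0,1) draw per entry per timestep).  The empirical
firing rate therefore converges to |x| and the spike polarity carries the
sign of the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Epoch

__all__ = ["SpikeTrain", "scale_input", "poisson_encode"]


@dataclass
class SpikeTrain:
    """Ternary spike tensor: channels x time x T with entries in {−1, 0, +1}."""

    values: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.shape[-1] != self.T:
            raise ValueError("values must be channels x time x T")
        if not np.isin(self.values, (-1, 0, 1)).all():
            raise ValueError("spike entries must be in {-1, 0, +1}")

    def firing_rate(self) -> np.ndarray:
        """Empirical |rate| per entry: mean |spike| over timesteps."""
        return np.abs(self.values).mean(axis=-1)


def scale_input(epoch: Epoch | np.ndarray, per_channel: bool = False) -> np.ndarray:
    """Scale an epoch into [−1, 1] by its maximum absolute amplitude.

    One global factor is shared by all channels by default, preserving
    between-channel amplitude ratios; ``per_channel=True`` scales each row by
    its own maximum instead.  All-zero input stays all-zero.
    """
    data = epoch.data if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if data.size == 0:
        raise ValueError("empty epoch")
    if per_channel:
        denom = np.abs(data).max(axis=-1, keepdims=True)
        return np.divide(data, denom, out=np.zeros_like(data), where=denom > 0)
    denom = np.abs(data).max()
    return data / denom if denom > 0 else np.zeros_like(data)


def poisson_encode(
    scaled: np.ndarray,
    T: int,
    rng: np.random.Generator,
    *,
    signed: bool = True,
) -> SpikeTrain:
    """Poisson rate coding of a scaled input over T timesteps.

    Per timestep and entry, draw u ~ Uniform(0,1) and emit sign(x) when
    |x| > u.  With ``signed=False`` the comparison is x > u literally, so
    negative entries never fire (kept for comparison; discards the sign
    channel of the signal).  Deterministic for a given generator state.
    """
    x = np.asarray(scaled, dtype=float)
    if np.abs(x).max(initial=0.0) > 1.0:
        raise ValueError("scaled input must lie in [-1, 1]")
    if T < 1:
        raise ValueError("T must be >= 1")
    u = rng.random(size=x.shape + (T,))
    if signed:
        fired = np.abs(x)[..., None] > u
        values = np.sign(x)[..., None] * fired
    else:
        values = (x[..., None] > u).astype(float)
    return SpikeTrain(values.astype(np.int8), T)


def encode_batch(
    x: np.ndarray, T: int, rng: np.random.Generator, signed: bool = True
) -> np.ndarray:
    """Batched encoder used by the model: (B, ...) -> (T, B, ...) int8 frames."""
    u = rng.random(size=(T,) + x.shape)
    if signed:
        return (np.sign(x) * (np.abs(x) > u)).astype(np.int8)
    return (x > u).astype(np.int8)
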