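"""Integrate-and-fire (IF) temporal convolution: forward dynamics and the
surrogate-gradient backward contract.

Forward (per timestep t = 1..T): the ternary spike frame o[t] is convolved
with the kernel bank w and accumulated into the membrane potential,

    V[t] = V[t-1] + w * o[t],

and wherever V strictly exceeds the firing threshold V_th the unit emits an
output spike and hard-resets to zero.  The membrane potential after the last
timestep, V[T], is what feeds the downstream analog blocks.

Backward: the spike nonlinearity is non-differentiable, so its derivative is
approximated by the constant surrogate 1/V_th at the terminal timestep, and
dV[T]/dw is approximated by the correlation of the input spikes accumulated
over all T steps with the output grid (resets are ignored in the gradient).
The weight gradient is therefore

    dLoss/dw = (1/V_th) * corr(sum_t o[t], upstream gradient at V[T]).

With resets disabled and no threshold crossing this rule is exact up to the
1/V_th factor (and exactly the true gradient when V_th = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .encoding import SpikeTrain

__all__ = ["IFState", "IFConvResult", "conv_time_same", "conv_time_wgrad",
           "if_conv_forward", "if_backward_grads"]


def _pad_lr(k: int) -> tuple[int, int]:
    # 'same' padding for stride 1; even kernels pad one extra on the right
    left = (k - 1) // 2
    return left, k - 1 - left


def conv_time_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlate ``x`` (..., H, W) with kernels ``w`` (F, K) along the last
    axis, 'same' length: returns (..., F, H, W).

    out[..., f, h, t] = sum_k w[f, k] * x[..., h, t + k - (K-1)//2], zero
    padded.  Evaluated by FFT (exact to rounding; much faster than an
    im2col matmul at these sizes).
    """
    k = w.shape[1]
    wlen = x.shape[-1]
    left, right = _pad_lr(k)
    nfft = next_fast_len(wlen + k - 1)
    xf = rfft(x, nfft, axis=-1)  # (..., H, nf)
    wf = rfft(w[:, ::-1], nfft, axis=-1)  # (F, nf)
    out = irfft(xf[..., None, :, :] * wf[:, None, :], nfft, axis=-1)
    return out[..., right : right + wlen]


def conv_time_wgrad(x: np.ndarray, gout: np.ndarray, k: int) -> np.ndarray:
    """Kernel gradient of :func:`conv_time_same`.

    ``x`` is the input (..., H, W), ``gout`` the output gradient
    (..., F, H, W); returns (F, K).  Cross-correlation at lags
    (K-1)//2 - k, summed over batch and H in the frequency domain.
    """
    left, _ = _pad_lr(k)
    wlen = x.shape[-1]
    nfft = next_fast_len(wlen + k - 1)
    xf = rfft(x.reshape(-1, x.shape[-2], wlen), nfft, axis=-1)  # (B, H, nf)
    f = gout.shape[-3]
    gf = rfft(gout.reshape(-1, f, x.shape[-2], wlen), nfft, axis=-1)  # (B, F, H, nf)
    spec = np.einsum("bhn,bfhn->fn", xf.conj(), gf)
    corr = irfft(spec, nfft, axis=-1)  # corr[f, l] = sum_n x[n] g[n+l], circular
    return corr[:, (left - np.arange(k)) % nfft]


@dataclass
class IFState:
    """IF-neuron configuration: firing threshold and timestep count."""

    v_th: float = 2.0
    T: int = 16

    def __post_init__(self) -> None:
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class IFConvResult:
    """Forward-pass record of the IF convolution block.

    V : membrane potential after the final timestep (F, H, W) — the block
        output fed downstream.
    output_spikes : count of threshold crossings per unit over the T steps.
    spike_sum : input spikes accumulated over timesteps (H, W), retained for
        the surrogate backward pass.
    """

    V: np.ndarray
    output_spikes: np.ndarray
    spike_sum: np.ndarray
    v_th: float
    kernel_size: int = field(default=0)


def if_conv_forward(
    spikes: SpikeTrain,
    weights: np.ndarray,
    state: IFState | None = None,
    *,
    reset: bool = True,
) -> IFConvResult:
    """Run the IF convolution over all timesteps of one spike train.

    ``spikes.values`` is channels x time x T; ``weights`` is (F, K) temporal
    kernels applied with 'same' padding.  Set ``reset=False`` to disable the
    threshold/reset nonlinearity (pure accumulation), in which case V[T]
    equals the convolution of the time-summed spike train.
    """
    state = state or IFState()
    w = np.asarray(weights, dtype=float)
    if w.ndim != 2:
        raise ValueError(f"weights must be (filters, kernel), got shape {w.shape}")
    vals = spikes.values
    if spikes.T != state.T:
        raise ValueError(
            f"spike train has T={spikes.T} but IF state expects T={state.T}"
        )
    frames = np.moveaxis(vals, -1, 0).astype(float)  # (T, H, W)
    V = np.zeros((w.shape[0],) + frames.shape[1:])
    n_out = np.zeros_like(V)
    for t in range(state.T):
        V += conv_time_same(frames[t], w)
        if reset:
            fired = V > state.v_th
            n_out += fired
            V[fired] = 0.0
    return IFConvResult(
        V=V,
        output_spikes=n_out,
        spike_sum=frames.sum(axis=0),
        v_th=state.v_th,
        kernel_size=w.shape[1],
    )


def if_backward_grads(
    loss_grad_at_output: np.ndarray, result: IFConvResult
) -> np.ndarray:
    """Surrogate weight gradient of the IF convolution block.

    ``loss_grad_at_output`` is dLoss/dV[T] with the block's output shape
    (F, H, W).  Requires a completed forward pass (an :class:`IFConvResult`);
    returns the (F, K) kernel gradient scaled by the 1/V_th surrogate.
    """
    if result.kernel_size <= 0:
        raise ValueError("backward called without a completed forward pass")
    g = np.asarray(loss_grad_at_output, dtype=float)
    if g.shape != result.V.shape:
        raise ValueError(
            f"output gradient shape {g.shape} does not match V {result.V.shape}"
        )
    return conv_time_wgrad(result.spike_sum, g, result.kernel_size) / result.v_th
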