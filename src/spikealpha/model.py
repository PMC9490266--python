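"""The hybrid spiking/analog EEGNet-style classifier.

Architecture (14 channels x 128 samples in, 3 openness classes out):

  block 1  input, Poisson spike generator over T timesteps       (14, 128)
  block 2  temporal convolution with IF neurons, 8 kernels
           (1, 64), 'same' padding; BatchNorm on V[T]            (8, 14, 128)
  block 3  depthwise spatial convolution, 16 filters (14, 1),
           'valid'; ELU; average pool (1, 4); dropout 0.5        (16, 1, 32)
  block 4  separable temporal convolution, 16 filters (1, 16),
           'same'; BatchNorm; ELU; average pool (1, 8);
           dropout 0.5                                           (16, 1, 4)
  block 5  flatten (64) -> dense(3) -> softmax                   (3)

Only block 2 is spiking: the Poisson-encoded frames drive integrate-and-fire
neurons and the membrane potential after the last timestep feeds the analog
blocks.  The analog blocks backpropagate by the ordinary chain rule; block 2
uses the 1/V_th terminal-step surrogate (see :mod:`spikealpha.ifneuron`).
The pure-analog variant replaces block 2 with an ordinary convolution and
drops the encoder, giving the original compact convnet for comparison.

Everything runs on plain NumPy arrays, (batch, maps, electrodes, time).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .encoding import encode_batch, scale_input
from .ifneuron import conv_time_same, conv_time_wgrad

__all__ = ["ModelConfig", "SpikeEEGNet", "build_model"]


@dataclass
class ModelConfig:
    """Hyperparameters of the classifier; defaults reproduce the reference
    architecture exactly (shape trace asserted at construction)."""

    input_shape: tuple[int, int] = (14, 128)
    n_classes: int = 3
    T: int = 16
    v_th: float = 2.0
    block2_filters: int = 8
    block2_kernel: int = 64
    block3_filters: int = 16      # depthwise output maps (multiplier x block2)
    block3_pool: int = 4
    block4_filters: int = 16
    block4_kernel: int = 16
    block4_pool: int = 8
    dropout: float = 0.5
    variant: str = "spike"        # "spike" | "ann"
    eval_passes: int = 8          # encoder draws averaged at inference (spike)

    def __post_init__(self) -> None:
        if self.variant not in ("spike", "ann"):
            raise ValueError("variant must be 'spike' or 'ann'")
        if self.block3_filters % self.block2_filters:
            raise ValueError(
                "block3_filters must be a multiple of block2_filters "
                "(depthwise multiplier)"
            )

    @property
    def depth_multiplier(self) -> int:
        return self.block3_filters // self.block2_filters

    @property
    def flat_features(self) -> int:
        w = self.input_shape[1] // self.block3_pool // self.block4_pool
        return self.block4_filters * w


# ---------------------------------------------------------------------------
# layers


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x, *, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class SpikeConvIF(_Layer):
    """Block 2, spiking: Poisson encoder + IF temporal convolution.

    Consumes scaled input (B, H, W) in [-1, 1]; emits V[T] of shape
    (B, F, H, W).  The backward pass implements the terminal-timestep
    surrogate: grad_w = (1/V_th) * corr(sum_t o[t], dLoss/dV[T]); no input
    gradient is produced (the encoder has no parameters upstream).
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.T, self.v_th = cfg.T, cfg.v_th
        k, f = cfg.block2_kernel, cfg.block2_filters
        self.w = _glorot(rng, (f, k), k, f)
        self.params, self.grads = [self.w], [np.zeros_like(self.w)]
        self._spike_sum: np.ndarray | None = None

    def forward(self, x, *, training, rng):
        frames = encode_batch(x, self.T, rng).astype(float)  # (T, B, H, W)
        inc = conv_time_same(frames.reshape((-1,) + x.shape[1:]), self.w)
        inc = inc.reshape((self.T,) + x.shape[:1] + inc.shape[1:])  # (T,B,F,H,W)
        V = np.zeros(inc.shape[1:])
        for t in range(self.T):
            V += inc[t]
            fired = V > self.v_th
            V[fired] = 0.0
        self._spike_sum = frames.sum(axis=0)  # (B, H, W)
        return V

    def backward(self, g):
        self.grads[0][...] = (
            conv_time_wgrad(self._spike_sum, g, self.w.shape[1]) / self.v_th
        )
        return None  # first trainable layer; no upstream parameters


class TemporalConv(_Layer):
    """Block 2, analog: plain temporal convolution (the non-spiking variant)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        k, f = cfg.block2_kernel, cfg.block2_filters
        self.w = _glorot(rng, (f, k), k, f)
        self.params, self.grads = [self.w], [np.zeros_like(self.w)]

    def forward(self, x, *, training, rng):
        self._x = x
        return conv_time_same(x, self.w)

    def backward(self, g):
        self.grads[0][...] = conv_time_wgrad(self._x, g, self.w.shape[1])
        return None


class BatchNorm(_Layer):
    """Per-feature-map batch normalization over (batch, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros(channels), np.zeros(channels)]
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)

    def forward(self, x, *, training, rng):
        axes = (0, 2, 3)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        m, v = mean[None, :, None, None], var[None, :, None, None]
        self._xhat = (x - m) / np.sqrt(v + self.eps)
        self._istd = 1.0 / np.sqrt(v + self.eps)
        self._n = x.shape[0] * x.shape[2] * x.shape[3]
        self._training = training
        return self.gamma[None, :, None, None] * self._xhat + self.beta[None, :, None, None]

    def backward(self, g):
        axes = (0, 2, 3)
        self.grads[0][...] = (g * self._xhat).sum(axis=axes)
        self.grads[1][...] = g.sum(axis=axes)
        gxhat = g * self.gamma[None, :, None, None]
        if not self._training:  # eval: fixed affine map by the running stats
            return gxhat * self._istd
        n = self._n
        return (
            self._istd
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=axes, keepdims=True)
                - self._xhat * (gxhat * self._xhat).sum(axis=axes, keepdims=True)
            )
        )


class DepthwiseSpatial(_Layer):
    """Block 3 convolution: depthwise (H, 1) kernels spanning all electrodes,
    'valid' padding, depth multiplier m; (B, C, H, W) -> (B, C*m, 1, W)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c, m, h = cfg.block2_filters, cfg.depth_multiplier, cfg.input_shape[0]
        self.w = _glorot(rng, (c, m, h), h, m)
        self.params, self.grads = [self.w], [np.zeros_like(self.w)]

    def forward(self, x, *, training, rng):
        self._x = x
        out = np.einsum("bchw,cmh->bcmw", x, self.w)
        b, c, m, wlen = out.shape
        return out.reshape(b, c * m, 1, wlen)

    def backward(self, g):
        b = g.shape[0]
        c, m, h = self.w.shape
        g = g.reshape(b, c, m, -1)
        self.grads[0][...] = np.einsum("bcmw,bchw->cmh", g, self._x)
        return np.einsum("bcmw,cmh->bchw", g, self.w)


class ELU(_Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, *, training, rng):
        self._neg = x < 0
        self._expm = np.where(self._neg, self.alpha * np.expm1(x), 0.0)
        return np.where(self._neg, self._expm, x)

    def backward(self, g):
        return np.where(self._neg, self._expm + self.alpha, 1.0) * g


class AvgPoolTime(_Layer):
    """Average pooling (1, k) along the time axis."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k

    def forward(self, x, *, training, rng):
        b, c, h, w = x.shape
        if w % self.k:
            raise ValueError(f"time length {w} not divisible by pool {self.k}")
        return x.reshape(b, c, h, w // self.k, self.k).mean(axis=-1)

    def backward(self, g):
        return np.repeat(g, self.k, axis=-1) / self.k


class Dropout(_Layer):
    def __init__(self, p: float):
        super().__init__()
        self.p = p

    def forward(self, x, *, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class SeparableConvTime(_Layer):
    """Block 4: depthwise temporal conv (per-map kernel, 'same') followed by a
    pointwise 1x1 mixing convolution; (B, C, 1, W) -> (B, F, 1, W)."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        c, f, k = cfg.block3_filters, cfg.block4_filters, cfg.block4_kernel
        self.dw = _glorot(rng, (c, k), k, 1)
        self.pw = _glorot(rng, (f, c), c, f)
        self.params = [self.dw, self.pw]
        self.grads = [np.zeros_like(self.dw), np.zeros_like(self.pw)]
        self.k = k

    @staticmethod
    def _windows(x: np.ndarray, k: int, transpose: bool = False) -> np.ndarray:
        from numpy.lib.stride_tricks import sliding_window_view

        left = (k - 1) // 2
        right = k - 1 - left
        if transpose:  # padding of the adjoint correlation
            left, right = right, left
        pad = [(0, 0)] * (x.ndim - 1) + [(left, right)]
        return sliding_window_view(np.pad(x, pad), k, axis=-1)

    def forward(self, x, *, training, rng):
        self._x = x
        win = self._windows(x, self.k)  # (B, C, 1, W, K)
        self._mid = np.einsum("bchwk,ck->bchw", win, self.dw)
        return np.einsum("bchw,fc->bfhw", self._mid, self.pw)

    def backward(self, g):
        self.grads[1][...] = np.einsum("bfhw,bchw->fc", g, self._mid)
        gmid = np.einsum("bfhw,fc->bchw", g, self.pw)
        win = self._windows(self._x, self.k)
        self.grads[0][...] = np.einsum("bchw,bchwk->ck", gmid, win)
        gwin = self._windows(gmid, self.k, transpose=True)
        return np.einsum("bchwk,ck->bchw", gwin, self.dw[:, ::-1])


class Flatten(_Layer):
    def forward(self, x, *, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.b = np.zeros(n_out)
        self.params, self.grads = [self.w, self.b], [np.zeros_like(self.w), np.zeros(n_out)]

    def forward(self, x, *, training, rng):
        self._x = x
        return x @ self.w + self.b

    def backward(self, g):
        self.grads[0][...] = self._x.T @ g
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.w.T


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class SpikeEEGNet:
    """The assembled classifier (spiking or analog block 2).

    ``forward`` returns class probabilities; ``forward_logits`` the dense
    outputs.  Inputs are raw microvolt epochs (B, 14, 128); scaling into
    [-1, 1] happens inside so both variants consume identical datasets.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator | int | None = None):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        first = SpikeConvIF(cfg, rng) if cfg.variant == "spike" else TemporalConv(cfg, rng)
        self.layers: list[_Layer] = [
            first,
            BatchNorm(cfg.block2_filters),
            DepthwiseSpatial(cfg, rng),
            ELU(),
            AvgPoolTime(cfg.block3_pool),
            Dropout(cfg.dropout),
            SeparableConvTime(cfg, rng),
            BatchNorm(cfg.block4_filters),
            ELU(),
            AvgPoolTime(cfg.block4_pool),
            Dropout(cfg.dropout),
            Flatten(),
            Dense(cfg.flat_features, cfg.n_classes, rng),
        ]
        self._check_shapes()

    def _check_shapes(self) -> None:
        trace = self.shape_trace()
        h, w = self.cfg.input_shape
        expect = [
            (self.cfg.block2_filters, h, w),
            (self.cfg.block3_filters, 1, w),
            (self.cfg.block3_filters, 1, w // self.cfg.block3_pool),
            (self.cfg.block4_filters, 1, w // self.cfg.block3_pool),
            (self.cfg.block4_filters, 1, w // self.cfg.block3_pool // self.cfg.block4_pool),
            (self.cfg.flat_features,),
            (self.cfg.n_classes,),
        ]
        got = [trace[k] for k in ("block2", "block3", "block3_pool",
                                  "block4", "block4_pool", "flatten", "dense")]
        for name, e, g in zip(
            ("block2", "block3", "block3_pool", "block4", "block4_pool",
             "flatten", "dense"), expect, got,
        ):
            if e != g:
                raise ValueError(f"shape trace mismatch at {name}: expected {e}, got {g}")

    def shape_trace(self) -> dict[str, tuple[int, ...]]:
        """Per-block output shapes (without the batch axis) of a forward pass."""
        x = np.zeros((1,) + self.cfg.input_shape)
        rng = np.random.default_rng(0)
        names = {1: "block2", 2: "block3", 4: "block3_pool", 6: "block4",
                 9: "block4_pool", 11: "flatten", 12: "dense"}
        trace: dict[str, tuple[int, ...]] = {"input": self.cfg.input_shape}
        for i, layer in enumerate(self.layers):
            x = layer.forward(x, training=False, rng=rng)
            if i in names:
                trace[names[i]] = x.shape[1:]
        return trace

    def _scaled(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return np.stack([scale_input(e) for e in x])

    def forward_logits(self, x: np.ndarray, *, training: bool = False,
                       rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        out = self._scaled(x)
        for layer in self.layers:
            out = layer.forward(out, training=training, rng=rng)
        return out

    def forward(self, x: np.ndarray, *, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class probabilities (B, 3); rows sum to 1."""
        return _softmax(self.forward_logits(x, training=training, rng=rng))

    def predict_proba(self, x: np.ndarray,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Inference probabilities; the spiking variant averages
        ``cfg.eval_passes`` independent encoder draws (rate-coded inference),
        the analog variant is deterministic and uses a single pass."""
        rng = rng or np.random.default_rng(0)
        passes = self.cfg.eval_passes if self.cfg.variant == "spike" else 1
        return np.mean(
            [self.forward(x, training=False, rng=rng) for _ in range(passes)], axis=0
        )

    def predict(self, x: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        return self.predict_proba(x, rng=rng).argmax(axis=1)

    def backward(self, grad_logits: np.ndarray) -> None:
        g = grad_logits
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:
                break

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + every parameter array."""
        arrays = {f"param_{i}": p for i, p in enumerate(self.parameters)}
        bn_state = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm):
                bn_state[f"bn{i}_mean"] = layer.run_mean
                bn_state[f"bn{i}_var"] = layer.run_var
        np.savez(path, config=json.dumps(asdict(self.cfg)), **arrays, **bn_state)

    @classmethod
    def load(cls, path) -> "SpikeEEGNet":
        with np.load(path, allow_pickle=False) as archive:
            raw = json.loads(str(archive["config"]))
            raw["input_shape"] = tuple(raw["input_shape"])
            model = cls(ModelConfig(**raw), rng=0)
            for i, p in enumerate(model.parameters):
                p[...] = archive[f"param_{i}"]
            for i, layer in enumerate(model.layers):
                if isinstance(layer, BatchNorm):
                    layer.run_mean = archive[f"bn{i}_mean"]
                    layer.run_var = archive[f"bn{i}_var"]
        return model


def build_model(cfg: ModelConfig | None = None, variant: str | None = None,
                seed: int | None = None) -> SpikeEEGNet:
    """Construct the classifier; ``variant`` overrides ``cfg.variant``."""
    cfg = cfg or ModelConfig()
    if variant is not None:
        cfg = ModelConfig(**{**asdict(cfg), "variant": variant})
    if isinstance(cfg.input_shape, list):
        cfg.input_shape = tuple(cfg.input_shape)
    return SpikeEEGNet(cfg, rng=seed)
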