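"""Training loop, stratified cross-validation, and evaluation metrics.

Training follows the per-iteration scheme of the hybrid model: forward
through the encoder, the IF convolution and the analog blocks; backward
through the analog blocks by the ordinary chain rule and through the IF
block by the 1/V_th terminal-step surrogate.  The optimizer is Adam on
categorical cross-entropy.  Evaluation reports accuracy and macro-averaged
precision, recall and F1 over the three openness classes, per fold and as
fold means of a stratified 5-fold cross-validation (each fold is an 80/20
split of the pooled samples).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold, train_test_split

from .model import ModelConfig, SpikeEEGNet, _softmax, build_model

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "EvalReport", "train", "evaluate", "crossvalidate"]

CLASS_LABELS = (0, 1, 2)  # low, medium, high


@dataclass
class TrainConfig:
    """Optimization and protocol parameters.

    Loss is categorical cross-entropy; the optimizer is Adam (adaptive
    moments).  ``folds=5`` stratified folds make each test share 20%,
    matching the 80/20 split statement; ``train_fraction`` applies to the
    single held-out-split mode.  The default budget of 30 epochs at batch 32
    is the package's convergence/runtime compromise for ~500-sample datasets
    on one CPU.
    """

    learning_rate: float = 1e-2
    epochs: int = 30
    batch_size: int = 32
    folds: int = 5
    train_fraction: float = 0.8
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class EvalReport:
    """Accuracy and macro precision/recall/F1, per fold and as means."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    per_fold: list[dict[str, float]] = field(default_factory=list)

    def summary(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


class _Adam:
    def __init__(self, params: list[np.ndarray], tc: TrainConfig):
        self.params = params
        self.tc = tc
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        tc = self.tc
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = tc.beta1 * m + (1 - tc.beta1) * g
            v[...] = tc.beta2 * v + (1 - tc.beta2) * g * g
            mhat = m / (1 - tc.beta1**self.t)
            vhat = v / (1 - tc.beta2**self.t)
            p -= tc.learning_rate * mhat / (np.sqrt(vhat) + tc.eps)


def _one_hot(y: np.ndarray, n: int = 3) -> np.ndarray:
    out = np.zeros((len(y), n))
    out[np.arange(len(y)), y] = 1.0
    return out


def train(
    model: SpikeEEGNet,
    X: np.ndarray,
    y: np.ndarray,
    tc: TrainConfig | None = None,
) -> list[float]:
    """Mini-batch training; returns the per-epoch mean loss history.

    Deterministic given ``tc.seed`` (shuffling, dropout and the Poisson
    encoder all draw from one seeded generator).  Raises on single-class
    data and aborts on a non-finite loss.
    """
    tc = tc or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    rng = np.random.default_rng(tc.seed)
    opt = _Adam(model.parameters, tc)
    onehot = _one_hot(y, model.cfg.n_classes)
    history: list[float] = []
    for epoch in range(tc.epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            xb, yb = X[idx], onehot[idx]
            logits = model.forward_logits(xb, training=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start // tc.batch_size}: "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]"
                )
            model.backward((probs - yb) / len(xb))
            opt.step(model.gradients)
            losses.append(float(loss))
        history.append(float(np.mean(losses)))
    return history


def evaluate(predictions: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Accuracy, macro precision/recall/F1 and the 3x3 confusion matrix.

    Classes never predicted contribute 0 to the macro averages (with a
    warning), the standard zero-division convention.
    """
    predictions = np.asarray(predictions, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if predictions.shape != truth.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} predictions vs {truth.shape} truth"
        )
    missing = set(CLASS_LABELS) - set(np.unique(predictions))
    if missing and set(np.unique(truth)) & missing:
        warnings.warn(
            f"classes never predicted: {sorted(missing)}; they contribute 0 "
            "to the macro averages",
            stacklevel=2,
        )
    acc = accuracy_score(truth, predictions)
    prec, rec, f1, _ = precision_recall_fscore_support(
        truth, predictions, labels=list(CLASS_LABELS), average="macro", zero_division=0
    )
    cm = confusion_matrix(truth, predictions, labels=list(CLASS_LABELS))
    fold = {"accuracy": float(acc), "precision": float(prec),
            "recall": float(rec), "f1": float(f1)}
    return EvalReport(float(acc), float(prec), float(rec), float(f1), cm, [fold])


def _fit_eval(cfg, X, y, tr_idx, te_idx, tc, fold_seed):
    model = build_model(cfg or ModelConfig(), seed=fold_seed)
    fold_tc = replace(tc, seed=fold_seed)
    train(model, X[tr_idx], y[tr_idx], fold_tc)
    preds = model.predict(X[te_idx], rng=np.random.default_rng(fold_seed + 1))
    return evaluate(preds, y[te_idx])


def crossvalidate(
    X: np.ndarray,
    y: np.ndarray,
    tc: TrainConfig | None = None,
    cfg: ModelConfig | None = None,
    *,
    holdout: bool = False,
) -> EvalReport:
    """Stratified k-fold cross-validation (default 5 folds, each an 80/20
    split); ``holdout=True`` runs a single stratified 80/20 split instead.

    Every fold trains a freshly initialized model (seed derived from
    ``tc.seed`` and the fold index) and evaluates on its held-out share.
    The report carries per-fold metrics, their means, and the summed
    confusion matrix.
    """
    tc = tc or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < tc.folds:
        raise ValueError(f"dataset of {len(X)} samples cannot fill {tc.folds} folds")

    if holdout:
        tr, te = train_test_split(
            np.arange(len(X)), test_size=1 - tc.train_fraction,
            stratify=y, random_state=tc.seed,
        )
        splits = [(tr, te)]
    else:
        skf = StratifiedKFold(n_splits=tc.folds, shuffle=True, random_state=tc.seed)
        splits = list(skf.split(X, y))
        for _, te_idx in splits:
            if len(np.unique(y[te_idx])) < len(np.unique(y)):
                raise ValueError("a fold is missing a class; check stratification")

    reports = []
    for k, (tr_idx, te_idx) in enumerate(splits):
        rep = _fit_eval(cfg, X, y, tr_idx, te_idx, tc, fold_seed=tc.seed + 1000 * (k + 1))
        logger.info("fold %d: %s", k, rep.summary())
        reports.append(rep)

    per_fold = [r.per_fold[0] for r in reports]
    means = {k: float(np.mean([f[k] for f in per_fold])) for k in per_fold[0]}
    confusion = np.sum([r.confusion for r in reports], axis=0)
    return EvalReport(
        means["accuracy"], means["precision"], means["recall"], means["f1"],
        confusion, per_fold,
    )
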