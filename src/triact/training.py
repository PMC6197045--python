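"""SGD training with step learning-rate decay, early stopping at the
log-loss slope sign change, and block-wise k-fold cross-validation.

The optimized loss is categorical cross-entropy on the softmax outputs;
the 0-1 classification error is tracked as the validation metric.  The
learning rate follows ``base_lr * 0.5 ** floor(epoch / period)``.
Weight decay (L2) applies to weight matrices only, never biases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from triact.cnn_model import (
    NetworkParams,
    NetworkSpec,
    backward_batch,
    forward_batch,
    init_params,
    predict_batch,
)
from triact.codes import CANONICAL_CODES
from triact.evaluation import ConfusionMatrix
from triact.preprocess import FoldAssignment, make_folds
from triact.signal_io import DatasetBundle, Window, stack_windows

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """The loss became non-finite during optimization."""


@dataclass
class TrainConfig:
    """Optimizer and schedule settings (defaults follow the published
    regimen: lr 0.0003 halved every 100 epochs, momentum 0.9, weight
    decay 0.0005, batch size 128)."""

    base_lr: float = 0.0003
    lr_halving_period_epochs: int = 100
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 128
    max_epochs: int = 300
    early_stop_smoothing_window: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_halving_period_epochs < 1:
            raise ValueError("lr_halving_period_epochs must be >= 1")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_error: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)


@dataclass
class SGDState:
    """Momentum buffers, one per parameter array."""

    buffers: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def for_params(cls, params: NetworkParams) -> "SGDState":
        return cls(
            buffers={k: np.zeros_like(v) for k, v in params.weights.items()}
        )


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Step decay: ``base_lr * 0.5 ** floor(epoch / period)``."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.base_lr * 0.5 ** (epoch // config.lr_halving_period_epochs)


def sgd_step(
    params: NetworkParams,
    batch_x: np.ndarray,
    batch_y: np.ndarray,
    lr: float,
    config: TrainConfig,
    state: SGDState,
    dropout_rng: np.random.Generator | None = None,
) -> float:
    """One SGD update on a batch; modifies ``params`` and ``state`` in
    place and returns the batch cross-entropy loss.

    Gradients are averaged over the batch; the L2 weight-decay term is
    added to weight-matrix gradients (biases exempt); momentum buffers
    combine past and current gradients.
    """
    if batch_x.shape[0] == 0:
        raise ValueError("batch must be non-empty")
    _, cache = forward_batch(
        batch_x, params, training_mode=dropout_rng is not None,
        dropout_rng=dropout_rng,
    )
    loss, grads = backward_batch(params, cache, batch_y)
    if not np.isfinite(loss):
        raise TrainingDivergedError(f"non-finite loss {loss}")
    for name, grad in grads.items():
        if not name.endswith("_b") and config.weight_decay:
            grad = grad + config.weight_decay * params.weights[name]
        buf = state.buffers[name]
        buf *= config.momentum
        buf += grad
        params.weights[name] -= lr * buf
    return loss


def detect_early_stop(
    history: TrainHistory | list[float], smoothing_window: int
) -> int | None:
    """First epoch at which the smoothed validation log-loss slope turns
    positive, or ``None``.

    The loss sequence is smoothed with a trailing moving average of
    ``smoothing_window`` epochs; the first epoch whose smoothed value
    strictly exceeds the previous epoch's is returned (zero slope does
    not trigger).  Requires at least ``smoothing_window + 1`` epochs.
    """
    losses = history.val_loss if isinstance(history, TrainHistory) else history
    w = smoothing_window
    if w < 1:
        raise ValueError("smoothing_window must be >= 1")
    if len(losses) < w + 1:
        return None
    arr = np.asarray(losses, dtype=float)
    kernel = np.ones(w) / w
    smoothed = np.convolve(arr, kernel, mode="valid")  # index t -> epoch t+w-1
    diffs = np.diff(smoothed)
    positive = np.flatnonzero(diffs > 0)
    if positive.size == 0:
        return None
    return int(positive[0]) + w  # epoch index of the increased value


def _batches(
    n: int, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def evaluate_split(
    params: NetworkParams, x: np.ndarray, y: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """(cross-entropy, 0-1 error rate, predicted indices) on a split."""
    probs, _ = forward_batch(x, params)
    eps = 1e-12
    ce = float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))
    preds = probs.argmax(axis=1)
    err = float(np.mean(preds != y))
    return ce, err, preds


def train(
    bundle: DatasetBundle,
    folds: FoldAssignment,
    held_out_fold: int,
    config: TrainConfig,
    spec: NetworkSpec | None = None,
) -> tuple[NetworkParams, TrainHistory]:
    """Train on k-1 folds, validate on the held-out fold.

    Stops at the early-stopping epoch (smoothed validation log-loss slope
    sign change) or ``max_epochs``; the returned parameters are those of
    the epoch with the minimum validation 0-1 error.
    """
    spec = spec or NetworkSpec()
    train_wins, val_wins = folds.split(bundle, held_out_fold)
    if not train_wins:
        raise ValueError("training set is empty")
    x_train, y_train = stack_windows(train_wins)
    x_val, y_val = stack_windows(val_wins)

    rng = np.random.default_rng(config.rng_seed)
    params = init_params(spec, seed=config.rng_seed)
    state = SGDState.for_params(params)
    history = TrainHistory()
    best_err = np.inf
    best_params = params.copy()

    for epoch in range(config.max_epochs):
        lr = lr_schedule(epoch, config)
        epoch_losses = []
        for idx in _batches(len(y_train), config.batch_size, rng):
            loss = sgd_step(
                params, x_train[idx], y_train[idx], lr, config, state,
                dropout_rng=rng if spec.dropout_rate > 0 else None,
            )
            epoch_losses.append(loss)
        val_ce, val_err, _ = evaluate_split(params, x_val, y_val)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_ce)
        history.val_error.append(val_err)
        history.learning_rate.append(lr)
        if val_err < best_err:
            best_err = val_err
            best_params = params.copy()
        stop = detect_early_stop(history, config.early_stop_smoothing_window)
        if stop is not None:
            logger.info(
                "early stop at epoch %d (slope sign change at %d)",
                epoch, stop,
            )
            break
    return best_params, history


def cross_validate(
    bundle: DatasetBundle,
    config: TrainConfig,
    k: int = 10,
    spec: NetworkSpec | None = None,
    folds: FoldAssignment | None = None,
) -> tuple[list[ConfusionMatrix], list[TrainHistory]]:
    """Block-wise k-fold cross-validation.

    Each fold is held out once; every window is scored in exactly one
    validation confusion matrix.  Returns the per-fold matrices (their
    elementwise sum is the pooled matrix) and per-fold histories.
    """
    folds = folds or make_folds(bundle, k)
    labels = tuple(c.value for c in CANONICAL_CODES)
    matrices: list[ConfusionMatrix] = []
    histories: list[TrainHistory] = []
    for fold in range(folds.k):
        params, history = train(bundle, folds, fold, config, spec=spec)
        _, val_wins = folds.split(bundle, fold)
        x_val, y_val = stack_windows(val_wins)
        preds = predict_batch(x_val, params)
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        np.add.at(counts, (y_val, preds), 1)
        matrices.append(ConfusionMatrix(labels=labels, counts=counts))
        histories.append(history)
    return matrices, histories
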