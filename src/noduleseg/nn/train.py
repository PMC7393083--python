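"""Dice loss and SGD training for the residual U-Net.

The loss is the soft Dice complement averaged over the mini-batch:
``1 - 2 * sum(p * t) / (sum(p) + sum(t) + eps)`` per sample, where ``p``
are sigmoid outputs and ``t`` binary targets. The epsilon keeps the
all-empty case finite. Optimization is plain stochastic gradient
descent (optional classical momentum), reproducible per seed: both the
weight initialization and the per-epoch shuffling flow from the
configured seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .resunet import ResUNet

DICE_EPS = 1e-7


@dataclass
class TrainConfig:
    """Optimization settings.

    The full-scale reference configuration is SGD with learning rate
    1e-4, mini-batch 8, and up to 700 epochs; small-scale experiments
    use a larger rate and momentum to converge within CPU budgets.
    """

    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 700
    momentum: float = 0.0
    seed: int = 0
    binarize_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be >= 0 and batch_size >= 1")


def dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = DICE_EPS) -> float:
    """Mean soft-Dice complement over the batch (first axis)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    axes = tuple(range(1, pred.ndim))
    inter = (pred * truth).sum(axis=axes)
    denom = pred.sum(axis=axes) + truth.sum(axis=axes) + eps
    return float(np.mean(1.0 - 2.0 * inter / denom))


def dice_loss_grad(pred: np.ndarray, truth: np.ndarray, eps: float = DICE_EPS) -> np.ndarray:
    """Gradient of :func:`dice_loss` with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    axes = tuple(range(1, pred.ndim))
    shape = (pred.shape[0],) + (1,) * (pred.ndim - 1)
    inter = (pred * truth).sum(axis=axes).reshape(shape)
    denom = (pred.sum(axis=axes) + truth.sum(axis=axes) + eps).reshape(shape)
    grad = -2.0 * (truth * denom - inter) / denom**2
    return (grad / pred.shape[0]).astype(np.float32)


def _batch_dsc(pred_bin: np.ndarray, truth: np.ndarray) -> float:
    inter = float((pred_bin * truth).sum())
    denom = float(pred_bin.sum() + truth.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    train_dsc: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)


def predict(model: ResUNet, patches: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Forward a (n, H, W) stack in inference mode; returns probabilities."""
    out = np.empty(patches.shape, dtype=np.float32)
    for i in range(0, len(patches), batch_size):
        x = patches[i : i + batch_size][..., None].astype(np.float32)
        out[i : i + batch_size] = model.forward(x, train=False)[..., 0]
    return out


def evaluate_dsc(model: ResUNet, patches: np.ndarray, masks: np.ndarray, threshold: float = 0.5) -> float:
    """Aggregate binary DSC of the model over a patch set."""
    prob = predict(model, patches)
    return _batch_dsc((prob >= threshold).astype(np.float32), masks.astype(np.float32))


def train(
    model: ResUNet,
    patches: np.ndarray,
    masks: np.ndarray,
    cfg: TrainConfig,
    val_patches: np.ndarray | None = None,
    val_masks: np.ndarray | None = None,
) -> TrainHistory:
    """Minimize the Dice loss with mini-batch SGD.

    ``patches``/``masks`` are (n, H, W) stacks matching the model spec.
    The history records per-epoch mean loss and aggregate train (and,
    when a validation set is given, validation) DSC. Aborts with a
    diagnostic on non-finite loss.
    """
    n = len(patches)
    if n == 0:
        raise ValueError("empty training set")
    if patches.shape[1:] != model.spec.input_shape:
        raise ValueError(
            f"patch shape {patches.shape[1:]} != model input {model.spec.input_shape}"
        )
    rng = np.random.default_rng(cfg.seed)
    params = model.params()
    velocity = [np.zeros_like(v) for v, _ in params] if cfg.momentum else None
    history = TrainHistory()

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            x = patches[idx][..., None].astype(np.float32)
            t = masks[idx][..., None].astype(np.float32)
            prob = model.forward(x, train=True)
            loss = dice_loss(prob, t)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch start {start}; "
                    f"prob range [{prob.min()}, {prob.max()}]"
                )
            losses.append(loss)
            model.backward(dice_loss_grad(prob, t))
            for j, (value, grad) in enumerate(params):
                if velocity is not None:
                    velocity[j] = cfg.momentum * velocity[j] - cfg.learning_rate * grad
                    value += velocity[j]
                else:
                    value -= cfg.learning_rate * grad
        history.loss.append(float(np.mean(losses)))
        history.train_dsc.append(evaluate_dsc(model, patches, masks, cfg.binarize_threshold))
        if val_patches is not None:
            history.val_dsc.append(
                evaluate_dsc(model, val_patches, val_masks, cfg.binarize_threshold)
            )
    return history
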