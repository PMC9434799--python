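"""Compound training objective: Dice loss plus focal loss, averaged per class.

For each of the four classes (background, NCR/NET, edema, enhancing) the
one-vs-rest probability plane is scored with

* Dice loss ``1 - (2 * sum(y * p) + eps) / (sum(y) + sum(p) + eps)``, where
  the smoothing constant ``eps`` keeps the ratio defined when both the
  truth and the prediction are empty, and
* focal loss ``sum(-y (1-p)^gamma log p - (1-y) p^gamma log(1-p))``, the
  class-balanced cross-entropy whose modulating exponent ``gamma``
  down-weights easy pixels (``gamma = 0`` recovers plain cross-entropy).

The compound loss is ``alpha * Dice + beta * Focal`` per class, averaged
over the classes, computed per image and then averaged over the batch.
Pure Dice training (``alpha=1, beta=0``) is available as a control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

PROB_FLOOR = 1e-7  # probabilities are clipped to [floor, 1 - floor] in log terms


@dataclass(frozen=True)
class LossConfig:
    """Weights and constants of the compound loss."""

    alpha: float = 0.1  # Dice weight
    beta: float = 0.9  # focal weight
    gamma: float = 2.0  # focal modulating exponent
    epsilon: float = 1e-5  # Dice smoothing constant
    include_background: bool = True  # background class joins the per-class average

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0 or self.epsilon <= 0:
            raise ValueError("alpha, beta, gamma must be >= 0 and epsilon > 0")

    @classmethod
    def dice_only(cls) -> "LossConfig":
        return cls(alpha=1.0, beta=0.0)


def _flat(t) -> Tensor:
    t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=np.float64))
    return t.reshape(int(np.prod(t.shape)))


def dice_loss(pred, target, epsilon: float = 1e-5) -> Tensor:
    """Soft Dice loss on a single class plane (any shape, flattened)."""
    p, y = _flat(pred), _flat(target)
    inter = (p * y).sum()
    return 1.0 - (2.0 * inter + epsilon) / (p.sum() + y.sum() + epsilon)


def focal_loss(pred, target, gamma: float = 2.0) -> Tensor:
    """Summed binary focal loss on a single class plane."""
    p = _flat(pred).clamp(PROB_FLOOR, 1.0 - PROB_FLOOR)
    y = _flat(target)
    pos = y * (1.0 - p) ** gamma * p.log()
    neg = (1.0 - y) * p**gamma * (1.0 - p).log()
    return -(pos + neg).sum()


def softmax_channels(scores: Tensor) -> Tensor:
    """Softmax over the class axis of (N, C, H, W) scores, numerically shifted."""
    shifted = scores - Tensor(scores.data.max(axis=1, keepdims=True))
    exp = shifted.exp()
    return exp / exp.sum(axis=1, keepdims=True)


def combined_loss(probs: Tensor, onehot, cfg: LossConfig) -> Tensor:
    """Compound loss for a batch.

    ``probs``: (N, C, H, W) per-pixel class probabilities; ``onehot``:
    ground truth of the same shape.  The loss is evaluated per image and
    per class, combined with the configured weights, averaged over classes
    and then over the batch.
    """
    y = onehot if isinstance(onehot, Tensor) else Tensor(np.asarray(onehot, dtype=probs.dtype))
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {y.shape}")
    n, c = probs.shape[0], probs.shape[1]
    classes = range(c) if cfg.include_background else range(1, c)
    per_image = []
    for i in range(n):
        terms = []
        for k in classes:
            p_plane = probs[i, k]
            y_plane = y[i, k]
            term = 0.0
            if cfg.alpha:
                term = term + cfg.alpha * dice_loss(p_plane, y_plane, cfg.epsilon)
            if cfg.beta:
                term = term + cfg.beta * focal_loss(p_plane, y_plane, cfg.gamma)
            terms.append(term)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        per_image.append(total * (1.0 / len(terms)))
    batch = per_image[0]
    for t in per_image[1:]:
        batch = batch + t
    return batch * (1.0 / n)


def one_hot(labels: np.ndarray, classes: int = 4) -> np.ndarray:
    """(N, H, W) integer labels -> (N, C, H, W) float one-hot."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= classes:
        raise ValueError(f"labels outside [0, {classes})")
    eye = np.eye(classes, dtype=np.float32)
    return np.ascontiguousarray(eye[labels].transpose(0, 3, 1, 2))
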