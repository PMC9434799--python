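"""Seeded training and evaluation loops.

Optimization follows the reference protocol: Adam (beta1=0.9, beta2=0.999,
eps=1e-8), batch size 8, learning rate 1e-5, no augmentation, scheduler,
weight decay or early stopping.  Shuffling, initialization and therefore
entire loss histories are reproducible bit-for-bit from the seed on a
fixed machine.

Epoch-oriented runs (``epochs``) and step-oriented runs (``max_steps``,
used by the desk-scale overfit protocol) share the same loop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .brats_io import SlicePair
from .losses import LossConfig, combined_loss, one_hot, softmax_channels
from .metrics import EvalRecord, score_case
from .network import MMUNetNetwork
from .nn import DTYPE


@dataclass
class TrainConfig:
    """Optimization settings."""

    batch_size: int = 8
    epochs: int = 15
    learning_rate: float = 1e-5
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)
    max_steps: int | None = None  # optional hard cap across epochs
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size >= 1, epochs >= 1 and learning_rate > 0 required")


class Adam:
    """Adam with per-parameter first/second moment estimates."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


@dataclass
class TrainResult:
    epoch_losses: list[float]
    step_losses: list[float]
    steps: int


def train(net: MMUNetNetwork, dataset: list[SlicePair], cfg: TrainConfig) -> TrainResult:
    """Train in place; returns the loss history."""
    if not dataset:
        raise ValueError("training dataset is empty")
    images = np.stack([s.images for s in dataset]).astype(DTYPE)
    targets = one_hot(np.stack([s.labels for s in dataset]), net.config.classes)
    rng = np.random.default_rng(cfg.seed)
    net.set_train(True)
    opt = Adam(net.parameters(), cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.adam_eps)

    epoch_losses: list[float] = []
    step_losses: list[float] = []
    log_lines: list[str] = []
    steps = 0
    done = False
    for epoch in range(cfg.epochs):
        losses = []
        for idx in _batches(len(dataset), cfg.batch_size, rng):
            net.zero_grad()
            scores = net.forward(images[idx])
            probs = softmax_channels(scores)
            loss = combined_loss(probs, targets[idx], cfg.loss)
            value = float(loss.data)
            if not np.isfinite(value):
                raise FloatingPointError(f"non-finite loss at step {steps}")
            loss.backward()
            opt.step()
            losses.append(value)
            step_losses.append(value)
            steps += 1
            if cfg.max_steps is not None and steps >= cfg.max_steps:
                done = True
                break
        epoch_losses.append(float(np.mean(losses)))
        log_lines.append(json.dumps({"epoch": epoch, "mean_loss": epoch_losses[-1], "steps": steps}))
        if done:
            break
    if cfg.checkpoint_path:
        net.save_weights(cfg.checkpoint_path)
    if cfg.log_path:
        Path(cfg.log_path).write_text("\n".join(log_lines) + "\n")
    return TrainResult(epoch_losses=epoch_losses, step_losses=step_losses, steps=steps)


def evaluate(net: MMUNetNetwork, dataset: list[SlicePair], *, batch_size: int = 8) -> list[EvalRecord]:
    """Deterministic per-slice evaluation records (evaluation mode)."""
    if not dataset:
        raise ValueError("evaluation dataset is empty")
    records: list[EvalRecord] = []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start : start + batch_size]
        batch = np.stack([s.images for s in chunk]).astype(DTYPE)
        preds = net.predict_labels(batch)
        for pair, pred in zip(chunk, preds):
            records.append(
                score_case(pred, pair.labels, case_id=f"{pair.case_id}#z{pair.slice_index}")
            )
    return records
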