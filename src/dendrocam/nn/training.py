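"""Training loop: pixel-wise binary cross-entropy, Adam, fixed seeds.

Every stochastic step (weight init, shuffling) is driven by an explicit
seed, so two runs with the same seed, data and config produce identical
loss histories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .layers import Parameter, sigmoid
from .network import TrunkSegmenter

__all__ = ["TrainingConfig", "TrainingHistory", "Adam", "bce_with_logits", "train"]


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 15
    learning_rate: float = 2e-3
    batch_size: int = 8
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size must be >= 1 and learning_rate > 0")


@dataclass
class TrainingHistory:
    """Per-epoch mean loss and pixel accuracy on the training data."""

    loss: List[float] = field(default_factory=list)
    pixel_accuracy: List[float] = field(default_factory=list)

    def write_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "loss", "pixel_accuracy"])
            for i, (l, a) in enumerate(zip(self.loss, self.pixel_accuracy), start=1):
                writer.writerow([i, f"{l:.8f}", f"{a:.6f}"])


class Adam:
    """Adam optimiser over a fixed parameter list."""

    def __init__(
        self,
        params: Sequence[Parameter],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits.

    Stable form: softplus(z) - y*z with softplus(z) = max(z,0) + log1p(exp(-|z|)).
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0.0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).astype(np.float32)
    return loss, grad


def _unpack(dataset) -> Tuple[np.ndarray, np.ndarray]:
    """Accept (image, mask) pairs or objects with .image / .mask attributes."""
    images, masks = [], []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "mask"):
            img = item.image
            msk = item.mask.labels if hasattr(item.mask, "labels") else item.mask
        else:
            img, msk = item
            msk = msk.labels if hasattr(msk, "labels") else msk
        images.append(np.asarray(img, dtype=np.float32))
        masks.append(np.asarray(msk, dtype=np.float32))
    return np.stack(images), np.stack(masks)


def train(
    model: TrunkSegmenter,
    dataset,
    config: TrainingConfig = TrainingConfig(),
    log_csv: Optional[Union[str, Path]] = None,
) -> TrainingHistory:
    """Fit the segmenter on (image, ground-truth mask) pairs.

    Returns the per-epoch loss/accuracy history; optionally writes it to
    ``log_csv``.  Deterministic given ``config.seed``.
    """
    items = list(dataset)
    if len(items) == 0:
        raise ValueError("training dataset is empty")
    images, masks = _unpack(items)
    if images.shape[:3] != masks.shape[:3] + () and images.shape[1:3] != masks.shape[1:3]:
        raise ValueError("image and mask spatial shapes differ")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainingHistory()
    n = len(items)

    for _epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_loss = 0.0
        correct = 0
        total = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = images[idx]
            yb = masks[idx][..., None]
            logits = model.forward_logits(xb, train=True)
            loss, grad = bce_with_logits(logits, yb)
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            pred = logits >= 0.0  # sigmoid(z) >= 0.5  <=>  z >= 0
            correct += int(np.sum(pred == (yb >= 0.5)))
            total += yb.size
        history.loss.append(epoch_loss / n)
        history.pixel_accuracy.append(correct / total)

    if log_csv is not None:
        history.write_csv(log_csv)
    return history


def pixel_accuracy(model: TrunkSegmenter, dataset) -> float:
    """Mean fraction of correctly labelled pixels over a dataset."""
    items = list(dataset)
    if not items:
        raise ValueError("dataset is empty")
    images, masks = _unpack(items)
    correct = 0
    total = 0
    for img, msk in zip(images, masks):
        pred = model.predict_proba(img) >= model.cfg.threshold
        correct += int(np.sum(pred == (msk >= 0.5)))
        total += msk.size
    return correct / total
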