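"""Optimisation of a segmentation network under the published protocol.

Stochastic gradient descent with momentum 0.9 and a piecewise-constant
learning rate: 0.001 at epoch 1, multiplied by 0.3 after every 10 epochs.
The default batcher streams shuffled samples continuously across epoch
boundaries ("rolling"), so n=831 images at batch 4 over 100 epochs yield
exactly floor(831*100/4) = 20,775 iterations — the remainder of each epoch
rolls into the next batch instead of being truncated or padded. The
conventional per-epoch batcher (ceil(n/batch) steps per epoch, partial final
batch) is also available.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .nn.graph import NetworkGraph
from .specs import TrainConfig

__all__ = [
    "TrainRecord",
    "lr_schedule",
    "pixelwise_loss",
    "iteration_count",
    "train",
    "SGDMomentum",
]


def lr_schedule(epoch: int, config: TrainConfig) -> float:
    """Learning rate for a 1-based epoch: base * factor**floor((e-1)/period)."""
    if not 1 <= epoch <= config.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {config.epochs}]")
    drops = (epoch - 1) // config.lr_drop_period_epochs
    return config.base_learning_rate * config.lr_drop_factor ** drops


def pixelwise_loss(probabilities: np.ndarray, truth_mask: np.ndarray,
                   tol: float = 1e-4) -> float:
    """Mean over pixels of -log p(true class) for per-pixel 2-class
    distributions (the 2-channel softmax form of binary cross-entropy).

    probabilities : (..., 2, H, W); truth_mask : (..., H, W) in {0, 1}.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    mask = np.asarray(truth_mask)
    if probs.ndim == 3:
        probs = probs[None]
        mask = mask[None]
    if probs.shape[0] != mask.shape[0] or probs.shape[2:] != mask.shape[1:]:
        raise ValueError("probability map and truth mask shapes do not match")
    colsum = probs.sum(axis=1)
    if np.abs(colsum - 1.0).max() > tol:
        raise ValueError("probabilities are not normalised per pixel")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("truth mask must be binary")
    labels = mask.astype(np.int64)
    p_true = np.take_along_axis(probs, labels[:, None], axis=1)[:, 0]
    return float(-np.log(np.maximum(p_true, 1e-12)).mean())


def iteration_count(n_samples: int, config: TrainConfig) -> int:
    """Total SGD iterations implied by the batching mode."""
    if config.batching == "rolling":
        return (n_samples * config.epochs) // config.mini_batch_size
    steps = -(-n_samples // config.mini_batch_size)  # ceil
    return steps * config.epochs


class SGDMomentum:
    """Classic momentum update: v <- m*v - lr*g ; w <- w + v."""

    def __init__(self, graph: NetworkGraph, momentum: float):
        self.graph = graph
        self.momentum = momentum
        self.velocity = {}

    def step(self, lr: float) -> None:
        for layer in self.graph:
            for pname, grad in layer.grads.items():
                key = (layer.name, pname)
                v = self.velocity.get(key)
                if v is None:
                    v = np.zeros_like(layer.params[pname])
                v *= self.momentum
                v -= lr * grad.astype(np.float32, copy=False)
                self.velocity[key] = v
                layer.params[pname] += v


@dataclass
class TrainRecord:
    """Learning curves and bookkeeping for one run."""

    iteration_loss: List[float] = field(default_factory=list)
    iteration_epoch: List[int] = field(default_factory=list)
    epoch_accuracy: List[float] = field(default_factory=list)
    learning_rates: List[float] = field(default_factory=list)  # per epoch
    epoch_seconds: List[float] = field(default_factory=list)
    checkpoint_path: Optional[str] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, len(self.iteration_loss) + 1),
            "epoch": self.iteration_epoch,
            "loss": self.iteration_loss,
        })

    def epochs_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.epoch_accuracy) + 1),
            "train_pixel_accuracy": self.epoch_accuracy,
            "learning_rate": self.learning_rates,
            "seconds": self.epoch_seconds,
        })


def _sample_stream(n: int, epochs: int, shuffle: bool,
                   rng: np.random.Generator) -> np.ndarray:
    """Concatenation of per-epoch sample orders (reshuffled each epoch)."""
    orders = []
    for _ in range(epochs):
        order = rng.permutation(n) if shuffle else np.arange(n)
        orders.append(order)
    return np.concatenate(orders)


def train(graph: NetworkGraph, images: np.ndarray, masks: np.ndarray,
          config: TrainConfig, checkpoint_path=None,
          log_every: int = 0) -> TrainRecord:
    """Fit ``graph`` on (N, 3, H, W) images and (N, H, W) binary masks.

    Deterministic given ``config.seed``: the seed drives both weight
    initialisation and the shuffling stream. Aborts with a diagnostic on a
    non-finite loss.
    """
    n = len(images)
    if n == 0:
        raise ValueError("training set is empty")
    if masks.shape[0] != n:
        raise ValueError("images and masks disagree in length")
    images = np.ascontiguousarray(images, dtype=np.float32)
    masks = np.ascontiguousarray(masks, dtype=np.int64)

    rng = np.random.default_rng(config.seed)
    graph.initialize(int(rng.integers(0, 2 ** 31 - 1)))
    opt = SGDMomentum(graph, config.momentum)
    record = TrainRecord()

    batch = config.mini_batch_size
    if config.batching == "rolling":
        stream = _sample_stream(n, config.epochs, config.shuffle_each_epoch,
                                rng)
        total_iters = iteration_count(n, config)
        batches = [stream[i * batch:(i + 1) * batch]
                   for i in range(total_iters)]
        epoch_of = [min(i * batch // n + 1, config.epochs)
                    for i in range(total_iters)]
    else:
        batches, epoch_of = [], []
        for e in range(1, config.epochs + 1):
            order = (rng.permutation(n) if config.shuffle_each_epoch
                     else np.arange(n))
            for i in range(0, n, batch):
                batches.append(order[i:i + batch])
                epoch_of.append(e)

    current_epoch = 0
    correct = total = 0
    t0 = time.perf_counter()
    for it, (idx, epoch) in enumerate(zip(batches, epoch_of), start=1):
        if epoch != current_epoch:
            if current_epoch > 0:
                record.epoch_accuracy.append(correct / max(total, 1))
                record.epoch_seconds.append(time.perf_counter() - t0)
                t0 = time.perf_counter()
            correct = total = 0
            current_epoch = epoch
            record.learning_rates.append(lr_schedule(epoch, config))
        lr = record.learning_rates[-1]

        xb = images[idx]
        yb = masks[idx]
        probs = graph.forward(xb, training=True)
        loss = pixelwise_loss(probs, yb)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss {loss!r} at iteration {it} "
                f"(epoch {epoch}, lr {lr:g}); aborting")
        onehot = np.zeros_like(probs)
        np.put_along_axis(onehot, yb[:, None], 1.0, axis=1)
        delta = (probs - onehot).astype(np.float32) / yb.size
        graph.backward(delta, from_logits=True)
        opt.step(lr)

        pred = probs.argmax(axis=1)
        correct += int((pred == yb).sum())
        total += yb.size
        record.iteration_loss.append(loss)
        record.iteration_epoch.append(epoch)
        if log_every and it % log_every == 0:
            print(f"iter {it}/{len(batches)} epoch {epoch} "
                  f"lr {lr:g} loss {loss:.4f}")

    record.epoch_accuracy.append(correct / max(total, 1))
    record.epoch_seconds.append(time.perf_counter() - t0)
    if checkpoint_path is not None:
        checkpoint_path = Path(checkpoint_path)
        graph.save(checkpoint_path)
        record.checkpoint_path = str(checkpoint_path)
    return record
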