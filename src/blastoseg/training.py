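"""From-scratch training loop with the published optimisation protocol.

Adam with an initial learning rate of 1e-4, mini-batches of 20 images,
epsilon 1e-6 and global L2 regularisation (read as a weight-decay-style
penalty on convolution weights, excluding biases and batch-norm affine
terms), for 40 epochs with the sample order reshuffled every epoch.  These
defaults describe full-dataset training at 400x400; desk-scale runs shrink
the image size, batch and epoch count through the same config.

Everything is deterministic given the config seed on a fixed device: weight
initialisation, the per-epoch shuffling stream, and the arithmetic itself.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .dataio import ImageSample
from .losses import LossConfig, loss_and_score_grad, one_hot
from .network import Network, NetworkSpec, build_network
from . import nn

__all__ = ["TrainingConfig", "TrainingCurve", "epoch_order", "pixel_accuracy", "train"]


@dataclass
class TrainingConfig:
    initial_learning_rate: float = 1e-4
    batch_size: int = 20
    epochs: int = 40
    adam_epsilon: float = 1e-6
    l2_regularization: float = 1e-4
    shuffle_each_epoch: bool = True
    seed: int = 0
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("learning rate must be > 0, batch_size >= 1, epochs >= 0")
        if self.adam_epsilon <= 0 or self.l2_regularization < 0:
            raise ValueError("adam_epsilon must be > 0 and l2_regularization >= 0")

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        raw["loss"]["class_weights"] = [float(v) for v in self.loss.class_weights]
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TrainingCurve:
    """Per-iteration training log: (iteration, epoch, loss, pixel accuracy)."""

    records: list[tuple[int, int, float, float]] = field(default_factory=list)

    def append(self, iteration: int, epoch: int, loss: float, accuracy: float) -> None:
        if self.records and iteration <= self.records[-1][0]:
            raise ValueError("iterations must be strictly increasing")
        self.records.append((iteration, epoch, loss, accuracy))

    @property
    def losses(self) -> list[float]:
        return [r[2] for r in self.records]

    @property
    def accuracies(self) -> list[float]:
        return [r[3] for r in self.records]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["iteration", "epoch", "loss", "accuracy"])
            writer.writerows(self.records)


def epoch_order(seed: int, epoch: int, n: int, shuffle: bool = True) -> np.ndarray:
    """Sample visit order for one epoch: a permutation drawn from a seed
    derived from ``(seed, epoch)``, so each sample appears exactly once."""
    if not shuffle:
        return np.arange(n)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(epoch,)))
    return rng.permutation(n)


def pixel_accuracy(label_map: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of pixels where the prediction matches the ground truth."""
    if label_map.shape != mask.shape:
        raise ValueError(f"shape mismatch {label_map.shape} vs {mask.shape}")
    return float((label_map == mask).mean())


def _stack_batch(samples: list[ImageSample], dtype) -> tuple[np.ndarray, np.ndarray]:
    imgs = np.stack([s.image for s in samples]).astype(dtype)[:, None]
    masks = np.stack([s.mask for s in samples])
    return imgs, masks


def train(
    spec: NetworkSpec,
    train_samples: list[ImageSample],
    config: TrainingConfig,
    network: Network | None = None,
) -> tuple[Network, TrainingCurve]:
    """Train a network from scratch; returns the network and its curve.

    Runs ``epochs x ceil(N / batch_size)`` iterations.  Each epoch draws a
    fresh permutation of the sample order from a seed derived from
    ``(config.seed, epoch)``, so every sample appears exactly once per epoch
    and runs with the same seed are bit-identical.  A non-finite loss aborts
    with the offending iteration in the message.
    """
    if not train_samples:
        raise ValueError("training set is empty")
    shapes = {s.image.shape for s in train_samples}
    if len(shapes) != 1:
        raise ValueError(f"training samples disagree in shape: {sorted(shapes)}")

    net = network if network is not None else build_network(spec, seed=config.seed)
    params = net.parameters()
    opt = nn.Adam(
        params,
        lr=config.initial_learning_rate,
        eps=config.adam_epsilon,
        weight_decay=config.l2_regularization,
    )
    curve = TrainingCurve()
    n = len(train_samples)
    iteration = 0
    for epoch in range(config.epochs):
        order = epoch_order(config.seed, epoch, n, config.shuffle_each_epoch)
        for start in range(0, n, config.batch_size):
            batch = [train_samples[i] for i in order[start : start + config.batch_size]]
            x, masks = _stack_batch(batch, net.dtype)
            target = one_hot(masks, dtype=net.dtype)
            scores = net.forward(x, training=True)
            loss, dscores = loss_and_score_grad(scores, target, config.loss)
            iteration += 1
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"loss became non-finite ({loss}) at iteration {iteration} "
                    f"(epoch {epoch})"
                )
            acc = pixel_accuracy(scores.argmax(axis=1), masks)
            curve.append(iteration, epoch, float(loss), acc)
            opt.zero_grad()
            net.backward(dscores)
            opt.step()
    return net, curve
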