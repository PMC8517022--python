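"""The patch-presence blossom detector.

A VGG-style encoder — consecutive 3x3 convolution + 2x2 max-pooling blocks
with per-block filter doubling, one fully connected layer, dropout and a
2-unit softmax giving the probability that a patch contains a blooming
stand.  Training uses RMSprop on a class-weighted cross-entropy (background
weight 1, bloom weight = n_background / n_bloom), flip-only augmentation,
an 80/20 train/validation split and keeps the epoch snapshot with the best
weighted validation accuracy.

A deterministic color-rule detector doubles as a test oracle: it declares
presence when the 128 x 128 patch core contains a 4-connected clump of
pixels whose red and blue both exceed green by a margin — the visual
signature of a clumped magenta stand with no visible individual crown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._nn import (Conv2D, Dense, Dropout, Flatten, MaxPool2, Network,
                  ReLU, RMSProp, softmax, weighted_cross_entropy)

__all__ = [
    "DetectorConfig", "TrainingHistory", "BloomDetector",
    "build_detector", "augment_patch", "train_detector", "predict_patches",
    "reference_color_detector", "class_weight_ratio",
]


def class_weight_ratio(n_background: int, n_bloom: int) -> float:
    """Weight of the bloom class: background images per bloom image."""
    if n_bloom <= 0 or n_background <= 0:
        raise ValueError("both classes need at least one example")
    return n_background / n_bloom


@dataclass
class DetectorConfig:
    """Hyper-parameters of the encoder and its training loop."""

    n_blocks: int = 5
    filters_per_block: tuple[int, ...] | None = None  # doubled from base
    base_filters: int = 16
    dense_units: int = 100
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 30
    input_side: int = 136
    n_bands: int = 4
    weight_loss: bool = True  # apply class weights to the loss, not only
    #                           the metric
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.filters_per_block is None:
            self.filters_per_block = tuple(
                self.base_filters * 2 ** i for i in range(self.n_blocks))
        elif len(self.filters_per_block) != self.n_blocks:
            raise ValueError("filters_per_block length must equal n_blocks")


@dataclass
class TrainingHistory:
    """Per-epoch loss and weighted validation accuracy."""

    loss: list[float] = field(default_factory=list)
    weighted_accuracy: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based index of the epoch with the best weighted accuracy."""
        return int(np.argmax(self.weighted_accuracy)) + 1

    @property
    def best_weighted_accuracy(self) -> float:
        return float(np.max(self.weighted_accuracy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.loss) + 1),
            "loss": self.loss,
            "weighted_accuracy": self.weighted_accuracy,
        })


class BloomDetector:
    """The encoder network plus its configuration."""

    def __init__(self, config: DetectorConfig) -> None:
        side = config.input_side
        if side < 2 ** config.n_blocks:
            raise ValueError(
                f"input side {side} too small for {config.n_blocks} "
                "pooling blocks")
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        c_in = config.n_bands
        for c_out in config.filters_per_block:
            layers += [Conv2D(c_in, c_out, rng), ReLU(), MaxPool2()]
            side //= 2
            c_in = c_out
        layers.append(Flatten())
        layers.append(Dense(side * side * c_in, config.dense_units, rng))
        layers.append(ReLU())
        layers.append(Dropout(config.dropout_rate))
        layers.append(Dense(config.dense_units, 2, rng))
        self.net = Network(layers)
        self._flat_side = side

    @property
    def n_params(self) -> int:
        return self.net.n_params

    @property
    def n_trainable_params(self) -> int:
        return self.net.n_params  # every parameter is trainable

    def predict_proba(self, patches: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
        """Softmax probabilities (background, bloom) per patch."""
        x = _as_input(patches, self.config)
        out = np.empty((x.shape[0], 2))
        for i in range(0, x.shape[0], batch_size):
            out[i:i + batch_size] = softmax(
                self.net.forward(x[i:i + batch_size], train=False))
        return out

    def save_weights(self, path) -> None:
        np.savez(path, *self.net.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.net.set_weights([data[k] for k in data.files])


def _as_input(patches: np.ndarray, config: DetectorConfig) -> np.ndarray:
    x = np.asarray(patches)
    if x.ndim == 3:
        x = x[None]
    if x.ndim != 4 or x.shape[3] != config.n_bands:
        raise ValueError(
            f"patches must be (n, side, side, {config.n_bands}), "
            f"got {x.shape}")
    if x.shape[1] != config.input_side or x.shape[2] != config.input_side:
        raise ValueError(
            f"patch side {x.shape[1:3]} does not match the configured "
            f"input side {config.input_side}")
    return (x.astype(np.float32) / 254.0)


def build_detector(config: DetectorConfig) -> BloomDetector:
    """Build the encoder; reports total and trainable parameter counts."""
    return BloomDetector(config)


def augment_patch(patch: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Flip the patch horizontally and/or vertically, each with p = 0.5.

    Flips are the only augmentation; atmosphere and illumination provide the
    rest in real imagery.
    """
    out = patch
    if rng.random() < 0.5:
        out = out[::-1, :]
    if rng.random() < 0.5:
        out = out[:, ::-1]
    return out


def train_detector(
    model: BloomDetector,
    patches: np.ndarray,
    labels: np.ndarray,
    config: DetectorConfig | None = None,
) -> tuple[BloomDetector, TrainingHistory]:
    """Train with flip augmentation and keep the best-epoch snapshot.

    The data are split 80/20 into train/validation (seeded); the loss is
    cross-entropy with class weights {background: 1, bloom:
    n_background/n_bloom} (weights also enter the accuracy metric), the
    optimizer is RMSprop, and the returned model carries the weights of the
    epoch with the highest weighted validation accuracy.
    """
    config = config or model.config
    labels = np.asarray(labels, int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("need at least one example of each class")
    x = _as_input(patches, config)
    rng = np.random.default_rng(config.seed)
    n = x.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, n // 5)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    ratio = class_weight_ratio(int((labels == 0).sum()),
                               int((labels == 1).sum()))
    cw = np.array([1.0, ratio])
    metric_w = cw[labels[val_idx]]
    opt = RMSProp(lr=config.learning_rate)
    history = TrainingHistory()
    best_acc, best_weights = -np.inf, model.net.get_weights()
    for _epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb = np.stack([augment_patch(x[j], rng) for j in idx])
            yb = labels[idx]
            probs = softmax(model.net.forward(xb, train=True, rng=rng))
            sw = cw[yb] if config.weight_loss else np.ones(yb.size)
            loss, dlogits = weighted_cross_entropy(probs, yb, sw)
            model.net.backward(dlogits)
            opt.step(model.net)
            losses.append(loss)
        val_pred = predict_patches(model, patches[val_idx])
        correct = (val_pred == labels[val_idx]).astype(float)
        acc = float((metric_w * correct).sum() / metric_w.sum())
        history.loss.append(float(np.mean(losses)))
        history.weighted_accuracy.append(acc)
        if acc > best_acc:
            best_acc = acc
            best_weights = model.net.get_weights()
    model.net.set_weights(best_weights)
    return model, history


def predict_patches(model: BloomDetector, patches: np.ndarray) -> np.ndarray:
    """Binary presence per patch: 1 iff P(bloom) >= 0.5 (ties to presence)."""
    probs = model.predict_proba(patches)
    return (probs[:, 1] >= 0.5).astype(int)


def reference_color_detector(
    patch: np.ndarray,
    min_clump: int = 9,
    delta: int = 10,
    border: int = 4,
) -> int:
    """Deterministic color-rule presence oracle on an 8-bit patch.

    Presence (1) iff the patch core (the border is ignored, as labels apply
    to the core only) contains a 4-connected component of at least
    ``min_clump`` pixels with red > green + delta and blue > green + delta.
    """
    patch = np.asarray(patch)
    core = patch[border:-border, border:-border] if border else patch
    r = core[..., 0].astype(int)
    g = core[..., 1].astype(int)
    b = core[..., 2].astype(int)
    magenta = (r > g + delta) & (b > g + delta)
    if not magenta.any():
        return 0
    labeled, n = ndimage.label(magenta)  # 4-connectivity by default
    if n == 0:
        return 0
    sizes = ndimage.sum_labels(magenta, labeled, np.arange(1, n + 1))
    return int(sizes.max() >= min_clump)
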