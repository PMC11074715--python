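"""VGG-16-style binary classifier with frozen feature blocks, plus the
training regime (RMSprop, sparse categorical cross-entropy, early stopping
with best-weight restore).

The reference architecture is the 13-convolution VGG-16 feature extractor
(3x3 kernels, stride 1, five 2x2/stride-2 max-pools) with the first ten
convolutions frozen and the last three fine-tuned, followed by a custom head
of three dense+dropout blocks and a 2-way softmax.  For a 144x144x3 input
the pre-flatten feature map is 4x4x512.

``ModelSpec.reduced()`` is a width- and depth-reduced variant of the same
layer grammar, sized for CPU-scale experiments on phantom data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from ._nn import ReLU, Conv2D, Dense, Dropout, Flatten, MaxPool2D, RMSprop, Sequential
from ._nn import relu, softmax  # noqa: F401  (re-exported operations)
from .errors import ValidationError
from .phantoms import load_png
from .segment import resize_image

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainHistory",
    "build_model",
    "train",
    "predict",
    "save_weights",
    "load_weights",
    "load_image_batch",
    "relu",
    "softmax",
]

_VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: conv blocks (a max-pool after each), then a
    dense head with one dropout layer per dense layer, then softmax."""

    input_shape: tuple[int, int, int] = (144, 144, 3)
    conv_blocks: tuple[tuple[int, ...], ...] = _VGG16_BLOCKS
    frozen_conv_layers: int = 10
    head_widths: tuple[int, ...] = (512, 256, 64)
    dropout_rate: float = 0.5
    n_classes: int = 2

    def __post_init__(self):
        total = self.n_conv_layers
        if not (0 <= self.frozen_conv_layers <= total):
            raise ValidationError(
                f"frozen ({self.frozen_conv_layers}) + trainable conv layers "
                f"must equal the total of {total}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValidationError("dropout_rate must lie in [0, 1)")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        h, w, _ = self.input_shape
        if min(h, w) // (2 ** len(self.conv_blocks)) < 1:
            raise ValidationError(
                f"input {h}x{w} collapses below 1px through "
                f"{len(self.conv_blocks)} pools"
            )

    @property
    def n_conv_layers(self) -> int:
        return sum(len(b) for b in self.conv_blocks)

    @property
    def trainable_conv_layers(self) -> int:
        return self.n_conv_layers - self.frozen_conv_layers

    @property
    def feature_map_shape(self) -> tuple[int, int, int]:
        h, w, _ = self.input_shape
        for _block in self.conv_blocks:
            h, w = h // 2, w // 2
        return (h, w, self.conv_blocks[-1][-1])

    @classmethod
    def vgg16(cls, **overrides) -> "ModelSpec":
        return cls(**overrides)

    @classmethod
    def reduced(cls, side: int = 64, channels: int = 1) -> "ModelSpec":
        """A small all-trainable variant for CPU-scale phantom experiments."""
        return cls(
            input_shape=(side, side, channels),
            conv_blocks=((8,), (8,), (16,), (16,), (32,)),
            frozen_conv_layers=0,
            head_widths=(32,),
            dropout_rate=0.2,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults follow the fine-tuning regime
    (RMSprop at 2e-5 with sparse categorical cross-entropy)."""

    learning_rate: float = 2e-5
    max_epochs: int = 30
    batch_size: int = 32
    early_stopping_patience: int = 5
    seed: int = 0
    pretrained_weights: str = "random"  # "random" or a path to a .npz checkpoint

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValidationError("learning rate must be >= 0")
        if self.early_stopping_patience < 1:
            raise ValidationError("patience must be >= 1")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValidationError("max_epochs and batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    stopped_epoch: int = 0  # 1-based epoch at which training halted
    best_epoch: int = 0  # 1-based epoch whose weights were restored

    def __len__(self) -> int:
        return len(self.train_loss)


def build_model(spec: ModelSpec, seed: int = 0, weights_path: str | Path | None = None) -> Sequential:
    """Assemble the layer stack; freeze the first ``spec.frozen_conv_layers``.

    Weights are He-initialized from ``seed``; ``weights_path`` optionally
    loads a pretrained checkpoint (e.g. feature weights transferred from a
    large source corpus) saved by :func:`save_weights`.
    """
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    in_ch = spec.input_shape[2]
    conv_idx = 0
    for bi, block in enumerate(spec.conv_blocks):
        for width in block:
            conv = Conv2D(in_ch, width, ksize=3, rng=rng, name=f"conv{conv_idx + 1}")
            conv.trainable = conv_idx >= spec.frozen_conv_layers
            layers.append(conv)
            layers.append(ReLU())
            in_ch = width
            conv_idx += 1
        layers.append(MaxPool2D())
    layers.append(Flatten())
    fh, fw, fc = spec.feature_map_shape
    in_dim = fh * fw * fc
    for wi, width in enumerate(spec.head_widths):
        layers.append(Dense(in_dim, width, rng=rng, name=f"fc{wi + 1}"))
        layers.append(ReLU())
        layers.append(Dropout(spec.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
        in_dim = width
    layers.append(Dense(in_dim, spec.n_classes, rng=rng, name="logits"))
    model = Sequential(layers)
    model.spec = spec
    if weights_path is not None:
        load_weights(model, weights_path)
    return model


def load_image_batch(paths, side: int, channels: int) -> np.ndarray:
    """Stack images from disk into a float array in [0, 1] of the model shape."""
    out = np.zeros((len(paths), side, side, channels))
    for i, p in enumerate(paths):
        img = load_png(p)
        if img.ndim == 3 and channels == 1:
            from .prep import to_grayscale

            img = to_grayscale(img)
        img = resize_image(img, side=side)
        if img.ndim == 2:
            img = img[..., None]
        if img.shape[2] != channels:
            img = np.repeat(img[..., :1], channels, axis=2)
        out[i] = img / 255.0
    return out


def _as_arrays(data, spec: ModelSpec):
    """Accept a Partition of manifests or ((Xtr, ytr), (Xval, yval)) arrays."""
    side, channels = spec.input_shape[0], spec.input_shape[2]
    if hasattr(data, "train"):  # Partition
        tr, va = data.train, data.validation
        if len(tr) == 0 or len(va) == 0:
            raise ValidationError("train and validation parts must be non-empty")
        xtr = load_image_batch(tr["path"].tolist(), side, channels)
        ytr = tr["label"].to_numpy(dtype=int)
        xva = load_image_batch(va["path"].tolist(), side, channels)
        yva = va["label"].to_numpy(dtype=int)
        return (xtr, ytr), (xva, yva)
    (xtr, ytr), (xva, yva) = data
    return (np.asarray(xtr, dtype=float), np.asarray(ytr, dtype=int)), (
        np.asarray(xva, dtype=float),
        np.asarray(yva, dtype=int),
    )


def _check_shape(x: np.ndarray, spec: ModelSpec) -> None:
    if x.ndim != 4 or x.shape[1:] != tuple(spec.input_shape):
        raise ValidationError(
            f"image batch shape {x.shape[1:]} does not match model input "
            f"{tuple(spec.input_shape)}"
        )


def _evaluate(model: Sequential, x: np.ndarray, y: np.ndarray, batch_size: int):
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = _nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(model: Sequential, data, config: TrainConfig | None = None) -> TrainHistory:
    """Mini-batch RMSprop with early stopping on validation loss.

    Only unfrozen layers are updated.  Training halts when the validation
    loss has not improved for ``early_stopping_patience`` consecutive epochs
    (or at ``max_epochs``) and the best-validation weights are restored.
    """
    config = config or TrainConfig()
    spec: ModelSpec = model.spec
    (xtr, ytr), (xva, yva) = _as_arrays(data, spec)
    _check_shape(xtr, spec)
    _check_shape(xva, spec)

    rng = np.random.default_rng(config.seed)
    opt = RMSprop(lr=config.learning_rate)
    history = TrainHistory()
    best_loss = np.inf
    best_weights = model.get_weights()
    wait = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xtr))
        epoch_loss, correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = xtr[idx], ytr[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            opt.step(model)
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(epoch_loss / len(xtr))
        history.train_accuracy.append(correct / len(xtr))

        val_loss, val_acc = _evaluate(model, xva, yva, config.batch_size)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)

        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            history.best_epoch = epoch
            wait = 0
        else:
            wait += 1
        history.stopped_epoch = epoch
        if wait >= config.early_stopping_patience:
            break

    model.set_weights(best_weights)
    return history


def predict(model: Sequential, images, batch_size: int = 32) -> np.ndarray:
    """Per-image class probabilities ``(p_no_tumor, p_tumor)``; rows sum to 1."""
    spec: ModelSpec = model.spec
    if isinstance(images, (list, tuple)) and images and isinstance(images[0], (str, Path)):
        images = load_image_batch(list(images), spec.input_shape[0], spec.input_shape[2])
    if isinstance(images, pd.DataFrame):
        images = load_image_batch(
            images["path"].tolist(), spec.input_shape[0], spec.input_shape[2]
        )
    x = np.asarray(images, dtype=float)
    _check_shape(x, spec)
    probs = []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i : i + batch_size], train=False)
        probs.append(softmax(logits, axis=1))
    return np.concatenate(probs, axis=0)


def save_weights(model: Sequential, path: str | Path) -> None:
    np.savez(str(path), *model.get_weights())


def load_weights(model: Sequential, path: str | Path) -> None:
    with np.load(str(path)) as data:
        weights = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    model.set_weights(weights)
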