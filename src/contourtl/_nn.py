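"""A compact numpy convnet engine: the layers, loss and optimizer needed for
a VGG-style classifier with frozen feature blocks.

Data layout is channels-last, ``(N, H, W, C)``.  Convolution is im2col +
matmul with 'same' zero padding; pooling floors odd spatial dims, matching
the familiar 144 -> 72 -> 36 -> 18 -> 9 -> 4 cascade of five 2x2/stride-2
max-pools.  Layers marked non-trainable still propagate gradients but are
skipped by the optimizer, so their weights stay bit-identical through
training — the mechanism behind "frozen" transfer-learning blocks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

__all__ = [
    "Layer", "Conv2D", "MaxPool2D", "Flatten", "Dense", "ReLU", "Dropout",
    "Sequential", "RMSprop", "softmax", "relu", "softmax_cross_entropy",
]


def relu(x):
    """F(x) = max(0, x), elementwise."""
    return np.maximum(0.0, x)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """exp(z_i) / sum_j exp(z_j) with max-subtraction for overflow safety."""
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean sparse categorical cross-entropy; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), y] + eps))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    trainable = True  # frozen layers set this to False

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """3x3-style convolution, stride 1, 'same' zero padding, He init."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int = 3,
                 rng: np.random.Generator | None = None, name: str = "conv"):
        if ksize % 2 == 0:
            raise ValidationError("conv kernel size must be odd for same padding")
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * in_ch
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(ksize, ksize, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.ksize = ksize
        self.stride = 1
        self.name = name
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        k = self.ksize
        p = k // 2
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> columns (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(1, 2))
        self._cols = win.reshape(n * h * w, c * k * k)
        self._xshape = x.shape
        w2 = self.w.transpose(2, 0, 1, 3).reshape(c * k * k, -1)
        out = self._cols @ w2 + self.b
        return out.reshape(n, h, w, -1)

    def backward(self, dout):
        k = self.ksize
        p = k // 2
        n, h, w, c = self._xshape
        f = self.w.shape[-1]
        d2 = dout.reshape(n * h * w, f)
        dw2 = self._cols.T @ d2  # (C*k*k, F)
        self.dw = dw2.reshape(c, k, k, f).transpose(1, 2, 0, 3)
        self.db = d2.sum(axis=0)
        w2 = self.w.transpose(2, 0, 1, 3).reshape(c * k * k, f)
        dcols = (d2 @ w2.T).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class MaxPool2D(Layer):
    """2x2 window, stride 2; odd trailing rows/cols are dropped (floor)."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : ho * 2, : wo * 2, :]
        r = xc.reshape(n, ho, 2, wo, 2, c).transpose(0, 1, 3, 5, 2, 4)
        r = r.reshape(n, ho, wo, c, 4)
        self._argmax = r.argmax(axis=-1)
        self._xshape = x.shape
        return r.max(axis=-1)

    def backward(self, dout):
        n, h, w, c = self._xshape
        ho, wo = h // 2, w // 2
        onehot = np.eye(4)[self._argmax]  # (N, Ho, Wo, C, 4)
        dwin = onehot * dout[..., None]
        dwin = dwin.reshape(n, ho, wo, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros((n, h, w, c))
        dx[:, : ho * 2, : wo * 2, :] = dwin.reshape(n, ho * 2, wo * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._xshape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, name: str = "dense"):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.name = name
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout: active only during training; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not (0.0 <= rate < 1.0):
            raise ValidationError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """Plain layer stack with forward/backward and weight (de)serialization."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def trainable_params(self):
        """Yield (unique_key, param_array, grad_array) for unfrozen layers."""
        for i, layer in enumerate(self.layers):
            if not layer.trainable:
                continue
            grads = layer.grads()
            for key, value in layer.params().items():
                yield f"{i}:{key}", value, grads[key]

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out.extend(v.copy() for v in layer.params().values())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for key, value in layer.params().items():
                new = next(it)
                if new.shape != value.shape:
                    raise ValidationError(
                        f"weight shape mismatch: {new.shape} vs {value.shape}"
                    )
                value[...] = new


class RMSprop:
    """Keep a running mean of squared gradients; divide the step by its root."""

    def __init__(self, lr: float = 2e-5, rho: float = 0.9, eps: float = 1e-7):
        if lr < 0:
            # lr == 0 is a degenerate but legal setting (used to exercise the
            # early-stopping contract on a frozen loss)
            raise ValidationError("learning rate must be >= 0")
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self._cache: dict[str, np.ndarray] = {}

    def step(self, model: Sequential) -> None:
        for key, param, grad in model.trainable_params():
            cache = self._cache.get(key)
            if cache is None:
                cache = np.zeros_like(param)
                self._cache[key] = cache
            cache *= self.rho
            cache += (1.0 - self.rho) * grad * grad
            param -= self.lr * grad / (np.sqrt(cache) + self.eps)
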