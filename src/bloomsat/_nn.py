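"""A compact CPU conv-net: layers, softmax cross-entropy and RMSprop.

Implements exactly what the blossom detector needs — 3x3 same-padding
convolutions (im2col), 2x2 max pooling, dense layers, inverted dropout and a
2-class softmax head with per-class weights — all in float32 NumPy with an
explicit seeded generator, so training is reproducible run-to-run on a
single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ReLU", "MaxPool2", "Flatten", "Dense", "Dropout",
           "Network", "RMSProp", "softmax", "weighted_cross_entropy"]


class Layer:
    """Base layer; parameters live in ``params`` with matching ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,H,W,C) -> (N*H*W, k*k*C) windows of the 'same'-padded input."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
    N, Hp, Wp, C = xp.shape
    H, W = Hp - 2 * p, Wp - 2 * p
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, (N, H, W, k, k, C), (s[0], s[1], s[2], s[1], s[2], s[3]))
    return np.ascontiguousarray(win).reshape(N * H * W, k * k * C)


class Conv2D(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3) -> None:
        super().__init__()
        self.k, self.c_in, self.c_out = k, c_in, c_out
        fan_in = k * k * c_in
        self.params["W"] = rng.normal(
            0, np.sqrt(2.0 / fan_in), (k * k * c_in, c_out)
        ).astype(np.float32)
        self.params["b"] = np.zeros(c_out, np.float32)

    def forward(self, x, train, rng):
        self._shape = x.shape
        self._cols = _im2col(x, self.k)
        out = self._cols @ self.params["W"] + self.params["b"]
        N, H, W, _ = x.shape
        return out.reshape(N, H, W, self.c_out)

    def backward(self, dout):
        N, H, W, C = self._shape
        dflat = dout.reshape(-1, self.c_out)
        self.grads["W"] = self._cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = (dflat @ self.params["W"].T).reshape(
            N, H, W, self.k, self.k, C)
        p = self.k // 2
        dxp = np.zeros((N, H + 2 * p, W + 2 * p, C), np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i:i + H, j:j + W] += dcols[:, :, :, i, j]
        return dxp[:, p:p + H, p:p + W]


class ReLU(Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train, rng):
        N, H, W, C = x.shape
        Hc, Wc = (H // 2) * 2, (W // 2) * 2
        if Hc == 0 or Wc == 0:
            raise ValueError("input too small to pool")
        self._shape = x.shape
        xc = x[:, :Hc, :Wc].reshape(N, Hc // 2, 2, Wc // 2, 2, C)
        out = xc.max(axis=(2, 4))
        mask = xc == out[:, :, None, :, None, :]
        self._mask = mask / np.maximum(mask.sum(axis=(2, 4),
                                                keepdims=True), 1)
        return out

    def backward(self, dout):
        N, H, W, C = self._shape
        d = self._mask * dout[:, :, None, :, None, :]
        Hc, Wc = (H // 2) * 2, (W // 2) * 2
        dx = np.zeros(self._shape, np.float32)
        dx[:, :Hc, :Wc] = d.reshape(N, Hc, Wc, C)
        return dx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.params["W"] = rng.normal(
            0, np.sqrt(2.0 / n_in), (n_in, n_out)).astype(np.float32)
        self.params["b"] = np.zeros(n_out, np.float32)

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_cross_entropy(
    probs: np.ndarray, labels: np.ndarray, sample_weights: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean weighted CE over the batch and the gradient w.r.t. logits."""
    n = labels.size
    p = np.clip(probs[np.arange(n), labels], 1e-12, None)
    loss = float(np.mean(sample_weights * -np.log(p)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits *= (sample_weights / n)[:, None]
    return loss, dlogits.astype(np.float32)


class Network:
    """A plain sequential network."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers
                for p in layer.params.values()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for name in layer.params:
                layer.params[name] = next(it).copy()


class RMSProp:
    """RMSprop with Keras-style defaults (rho 0.9, epsilon 1e-7)."""

    def __init__(self, lr: float = 1e-4, rho: float = 0.9,
                 eps: float = 1e-7) -> None:
        self.lr, self.rho, self.eps = lr, rho, eps
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def step(self, net: Network) -> None:
        for i, layer in enumerate(net.layers):
            if not layer.params:
                continue
            cache = self._cache.setdefault(
                i, {k: np.zeros_like(v) for k, v in layer.params.items()})
            for name, p in layer.params.items():
                g = layer.grads[name]
                cache[name] = self.rho * cache[name] \
                    + (1 - self.rho) * g * g
                p -= self.lr * g / (np.sqrt(cache[name]) + self.eps)
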