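"""A compact NumPy neural-network engine for small image classifiers.

Implements exactly the pieces the print-quality classifier needs — 3x3
same-padding convolution, batch normalization, ReLU, 2x2 max pooling,
dense layers with optional L2 penalty, dropout, and an Adam optimizer with
sigmoid/binary-cross-entropy loss — in channels-last float32 layout.
Convolutions are evaluated as nine shifted GEMMs, which keeps the hot path
inside BLAS. All randomness (initialization, dropout) flows from the
``numpy.random.Generator`` handed to each layer, so a fixed seed makes
training bit-reproducible on a fixed BLAS.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "Adam",
    "bce_with_logits",
]

_F32 = np.float32


class Layer:
    """Base layer: params/grads are parallel lists of float32 arrays."""

    params: list
    grads: list

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def l2_loss(self) -> float:
        return 0.0


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, channels-last (N,H,W,C)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (9 * cin))  # He initialization
        self.W = (rng.standard_normal((3, 3, cin, cout)) * scale).astype(_F32)
        self.b = np.zeros(cout, dtype=_F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        self._xp_shape = xp.shape
        self._xp = xp if train else None
        cout = self.W.shape[-1]
        y = np.empty((n, h, w, cout), dtype=_F32)
        y[:] = self.b
        flat_y = y.reshape(-1, cout)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di : di + h, dj : dj + w, :].reshape(-1, self.W.shape[2])
                flat_y += patch @ self.W[di, dj]
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, cout = dout.shape
        cin = self.W.shape[2]
        flat_d = dout.reshape(-1, cout)
        dxp = np.zeros(self._xp_shape, dtype=_F32)
        for di in range(3):
            for dj in range(3):
                patch = self._xp[:, di : di + h, dj : dj + w, :].reshape(-1, cin)
                self.grads[0][di, dj] = patch.T @ flat_d
                dxp[:, di : di + h, dj : dj + w, :] += (flat_d @ self.W[di, dj].T).reshape(
                    n, h, w, cin
                )
        self.grads[1][:] = flat_d.sum(axis=0)
        self._xp = None
        return dxp[:, 1:-1, 1:-1, :]


class BatchNorm(Layer):
    """Per-channel batch normalization over the (N, H, W) axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv.astype(_F32), x.shape, axes)
        return (self.gamma * xhat + self.beta).astype(_F32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, shape, axes = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads[0][:] = (dout * xhat).sum(axis=axes)
        self.grads[1][:] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv
        self._cache = None
        return dx.astype(_F32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, _F32(0.0))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, _F32(0.0))


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xf = xr.reshape(n, h // 2, w // 2, c, 4)
        self._arg = xf.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(xf, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        dxf = np.zeros((n, h // 2, w // 2, c, 4), dtype=_F32)
        np.put_along_axis(dxf, self._arg[..., None], dout[..., None], axis=-1)
        dx = dxf.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(n, h, w, c)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer; ``l2`` adds a weight penalty to loss and grads."""

    def __init__(self, din: int, dout: int, rng: np.random.Generator, l2: float = 0.0) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / din)
        self.W = (rng.standard_normal((din, dout)) * scale).astype(_F32)
        self.b = np.zeros(dout, dtype=_F32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.l2 = l2

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][:] = self._x.T @ dout
        if self.l2 > 0:
            self.grads[0] += _F32(self.l2) * self.W
        self.grads[1][:] = dout.sum(axis=0)
        dx = dout @ self.W.T
        self._x = None
        return dx

    def l2_loss(self) -> float:
        if self.l2 > 0:
            return 0.5 * self.l2 * float((self.W.astype(np.float64) ** 2).sum())
        return 0.0


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(_F32) / _F32(
            1.0 - self.rate
        )
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """A plain layer stack with logits output."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    def l2_loss(self) -> float:
        return sum(layer.l2_loss() for layer in self.layers)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Sigmoid probabilities, evaluated in inference mode."""
        out = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            out.append(1.0 / (1.0 + np.exp(-logits.astype(np.float64))))
        return np.concatenate(out).ravel()


def bce_with_logits(
    logits: np.ndarray, y: np.ndarray, sample_weight: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted binary cross-entropy on logits; returns (loss, dlogits).

    Numerically stable log-sum-exp form; the gradient is
    ``w * (sigmoid(z) - y) / sum(w)``.
    """
    z = logits.astype(np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float).ravel()
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    loss_i = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * y
    wsum = w.sum()
    loss = float((w * loss_i).sum() / wsum)
    p = 1.0 / (1.0 + np.exp(-z))
    dlogits = (w * (p - y) / wsum).astype(_F32).reshape(logits.shape)
    return loss, dlogits


class Adam:
    """Adam optimizer over a parameter list (in-place updates)."""

    def __init__(
        self,
        params: list,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * (g * g)
            p -= _F32(self.lr) * (m / bias1) / (np.sqrt(v / bias2) + _F32(self.eps))
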