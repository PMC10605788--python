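"""A small vectorized NumPy neural-network backend for 1D signal models.

Implements exactly the layer set the surface classifier needs — 1D
convolution ("same" padding, stride 1), ReLU, batch normalization,
1D max pooling (ceil- or floor-mode length arithmetic), dropout, flatten,
dense — with reverse-mode gradients and an Adam optimizer.  Activations
are ``[batch, length, channels]`` float32; convolution is lowered to a
matrix product (im2col) so the heavy lifting runs in BLAS.

This module is deliberately minimal: no graphs, no autograd, just the
layers above with hand-written backward passes, which keeps the training
loop deterministic under a seed and fast on a single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Layer",
    "Conv1D",
    "ReLU",
    "BatchNorm",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "softmax",
    "sparse_cross_entropy",
    "pooled_length",
]


def pooled_length(n: int, pool: int = 3, mode: str = "ceil") -> int:
    """Output length of a pool/stride-``pool`` max pooling layer."""
    if mode == "ceil":
        return -(-n // pool)
    if mode == "floor":
        return (n - pool) // pool + 1 if n >= pool else 0
    raise ValueError(f"unknown pool mode {mode!r}")


def glorot_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    """Base layer: parameter dicts plus forward/backward."""

    kind = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.state: dict[str, np.ndarray] = {}  # non-trainable (BN statistics)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def n_trainable(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def n_non_trainable(self) -> int:
        return sum(int(s.size) for s in self.state.values())

    def describe(self) -> str:
        return self.kind


class Conv1D(Layer):
    """Temporal convolution, stride 1, zero ("same") padding."""

    kind = "conv1d"

    def __init__(self, in_channels: int, filters: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.filters = filters
        self.kernel_size = kernel_size
        fan_in = kernel_size * in_channels
        fan_out = kernel_size * filters
        self.params["W"] = glorot_uniform(
            (kernel_size, in_channels, filters), fan_in, fan_out, rng)
        self.params["b"] = np.zeros(filters, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, L, C = x.shape
        k = self.kernel_size
        pad = (k - 1) // 2
        xp = np.pad(x, ((0, 0), (pad, k - 1 - pad), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)
        # win: (N, L, C, k) -> columns ordered (k, C)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(N * L, k * C)
        self._col = col if training else None
        self._shape = (N, L, C)
        Wm = self.params["W"].reshape(k * C, self.filters)
        y = col @ Wm + self.params["b"]
        return y.reshape(N, L, self.filters)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, L, C = self._shape
        k = self.kernel_size
        pad = (k - 1) // 2
        dyf = dy.reshape(N * L, self.filters)
        Wm = self.params["W"].reshape(k * C, self.filters)
        self.grads["W"] = (self._col.T @ dyf).reshape(k, C, self.filters)
        self.grads["b"] = dyf.sum(axis=0)
        dcol = (dyf @ Wm.T).reshape(N, L, k, C)
        dxp = np.zeros((N, L + k - 1, C), dtype=dy.dtype)
        for j in range(k):
            dxp[:, j:j + L] += dcol[:, :, j, :]
        self._col = None
        return dxp[:, pad:pad + L]

    def describe(self) -> str:
        return (f"conv1d(filters={self.filters}, kernel_size="
                f"{self.kernel_size}, strides=1, padding=same)")


class ReLU(Layer):
    kind = "relu"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class BatchNorm(Layer):
    """Per-channel batch normalization over batch and time axes."""

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.99,
                 eps: float = 1e-3) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self._updates = 0
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.state["moving_mean"] = np.zeros(channels, dtype=np.float32)
        self.state["moving_var"] = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            # Cumulative average during warm-up, exponential after: the
            # moving statistics track the data from the first step instead
            # of decaying slowly from their 0/1 initialization.
            self._updates += 1
            m = min(self.momentum, 1.0 - 1.0 / self._updates)
            self.state["moving_mean"] = (m * self.state["moving_mean"]
                                         + (1 - m) * mean).astype(np.float32)
            self.state["moving_var"] = (m * self.state["moving_var"]
                                        + (1 - m) * var).astype(np.float32)
        else:
            mean = self.state["moving_mean"]
            var = self.state["moving_var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat = xhat
            self._inv = inv
            self._m = x.shape[0] * x.shape[1]
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.grads["gamma"] = (dy * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dy.sum(axis=(0, 1))
        g = self.params["gamma"]
        dxhat = dy * g
        dx = (inv / m) * (m * dxhat
                          - dxhat.sum(axis=(0, 1))
                          - xhat * (dxhat * xhat).sum(axis=(0, 1)))
        self._xhat = None
        return dx.astype(dy.dtype)


class MaxPool1D(Layer):
    """Max pooling, pool size = stride.

    ``mode="ceil"`` pads the tail with -inf so the output length is
    ceil(L / pool); ``mode="floor"`` drops the remainder (output
    floor length), the conventional 'valid' arithmetic.
    """

    kind = "maxpool1d"

    def __init__(self, pool: int = 3, mode: str = "ceil") -> None:
        super().__init__()
        self.pool = pool
        self.mode = mode

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        N, L, C = x.shape
        p = self.pool
        Lo = pooled_length(L, p, self.mode)
        if Lo < 1:
            raise ValueError(f"pooling collapses length {L} to zero")
        if self.mode == "ceil":
            Lp = Lo * p
            if Lp != L:
                x = np.concatenate(
                    [x, np.full((N, Lp - L, C), -np.inf, dtype=x.dtype)], axis=1)
        else:
            x = x[:, : Lo * p]
        blocks = x.reshape(N, Lo, p, C)
        self._arg = blocks.argmax(axis=2)
        self._in_len = L
        out = np.take_along_axis(blocks, self._arg[:, :, None, :], axis=2)[:, :, 0, :]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, Lo, C = dy.shape
        p = self.pool
        dblocks = np.zeros((N, Lo, p, C), dtype=dy.dtype)
        np.put_along_axis(dblocks, self._arg[:, :, None, :], dy[:, :, None, :],
                          axis=2)
        dx = dblocks.reshape(N, Lo * p, C)
        L = self._in_len
        if dx.shape[1] >= L:
            dx = dx[:, :L]
        else:  # floor mode dropped a remainder
            dx = np.concatenate(
                [dx, np.zeros((N, L - dx.shape[1], C), dtype=dy.dtype)], axis=1)
        return dx

    def describe(self) -> str:
        return f"maxpool1d(pool_size={self.pool}, strides={self.pool}, mode={self.mode})"


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask

    def describe(self) -> str:
        return f"dropout(rate={self.rate})"


class Flatten(Layer):
    kind = "flatten"

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    kind = "dense"

    def __init__(self, in_features: int, units: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.units = units
        self.params["W"] = glorot_uniform((in_features, units), in_features,
                                          units, rng)
        self.params["b"] = np.zeros(units, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        dx = dy @ self.params["W"].T
        self._x = None
        return dx

    def describe(self) -> str:
        return f"dense(units={self.units}, activation=softmax)"


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sparse_cross_entropy(logits: np.ndarray, y: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Mean sparse categorical cross-entropy and its logit gradient."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p
    grad[np.arange(n), y] -= 1.0
    return float(loss), (grad / n).astype(np.float32)


class Network:
    """An ordered layer stack with a softmax classification head."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], training=False)))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        return self.predict_proba(x, batch_size=batch_size).argmax(axis=1)

    def train_batch(self, x: np.ndarray, y: np.ndarray,
                    optimizer: "Adam") -> float:
        logits = self.forward(x, training=True)
        loss, grad = sparse_cross_entropy(logits, y)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        optimizer.step(self)
        return loss

    # -- weights ---------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            for key in sorted(layer.params):
                out.append(layer.params[key].copy())
            for key in sorted(layer.state):
                out.append(layer.state[key].copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            for key in sorted(layer.params):
                layer.params[key] = next(it).copy()
            for key in sorted(layer.state):
                layer.state[key] = next(it).copy()

    def n_trainable(self) -> int:
        return sum(l.n_trainable() for l in self.layers)

    def n_non_trainable(self) -> int:
        return sum(l.n_non_trainable() for l in self.layers)


class Adam:
    """Adam with a mutable learning rate (for reduce-on-plateau)."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7) -> None:
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[int, dict[str, np.ndarray]] = {}
        self._v: dict[int, dict[str, np.ndarray]] = {}

    def step(self, net: Network) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for li, layer in enumerate(net.layers):
            if not layer.params:
                continue
            m = self._m.setdefault(li, {})
            v = self._v.setdefault(li, {})
            for key, p in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                mk = m.setdefault(key, np.zeros_like(p))
                vk = v.setdefault(key, np.zeros_like(p))
                mk += (1 - b1) * (g - mk)
                vk += (1 - b2) * (g * g - vk)
                p -= self.lr * (mk / bias1) / (np.sqrt(vk / bias2) + self.eps)
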