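"""Minimal neural-network layer library on numpy.

Each layer implements ``forward(x, training)`` and ``backward(grad_out)``;
``backward`` consumes the cache left by the most recent forward call and
returns the gradient with respect to the layer input, accumulating parameter
gradients in ``Param.grad``.  All randomness (initialization, dropout) flows
through explicit ``numpy.random.Generator`` instances, so CPU runs are
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_features)
        self.W = Param(rng.uniform(-bound, bound, size=(in_features, out_features)))
        self.b = Param(rng.uniform(-bound, bound, size=out_features))
        self.in_features = in_features

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        if x.shape[1] != self.in_features:
            raise ValueError(
                f"linear layer expects width {self.in_features}, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Layer):
    """1-D convolution, stride 1, dilation 1, symmetric zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(in_channels * kernel)
        self.W = Param(
            rng.uniform(-bound, bound, size=(out_channels, in_channels, kernel))
        )
        self.b = Param(rng.uniform(-bound, bound, size=out_channels))
        self.kernel, self.padding = kernel, padding
        self.in_channels = in_channels

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"conv1d expects {self.in_channels} channels, got {x.shape[1]}"
            )
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.padding, self.padding)))
        t_out = T + 2 * self.padding - self.kernel + 1
        y = np.broadcast_to(
            self.b.value[None, :, None], (B, len(self.b.value), t_out)
        ).copy()
        for k in range(self.kernel):
            y += np.einsum("bct,oc->bot", xp[:, :, k:k + t_out], self.W.value[:, :, k])
        self._xp, self._t_out = xp, t_out
        return y

    def backward(self, grad):
        xp, t_out = self._xp, self._t_out
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            self.W.grad[:, :, k] += np.einsum(
                "bot,bct->oc", grad, xp[:, :, k:k + t_out]
            )
            dxp[:, :, k:k + t_out] += np.einsum(
                "bot,oc->bct", grad, self.W.value[:, :, k]
            )
        self.b.grad += grad.sum(axis=(0, 2))
        p = self.padding
        return dxp[:, :, p:xp.shape[2] - p] if p else dxp


class BatchNorm1d(Layer):
    """Batch normalization over (B,) or (B, T) statistics per feature/channel.

    Accepts (B, F) or (B, C, T) inputs, mirroring the usual 1-D convention.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(num_features))
        self.beta = Param(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum, self.eps = momentum, eps

    def params(self):
        return [self.gamma, self.beta]

    def _shape(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _expand(self, v, ndim):
        return v[None, :] if ndim == 2 else v[None, :, None]

    def forward(self, x, training=False):
        axes = self._shape(x)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        self._xhat, self._inv, self._axes = xhat, inv, axes
        self._n = x.shape[0] if x.ndim == 2 else x.shape[0] * x.shape[2]
        self._training = training
        return self._expand(self.gamma.value, x.ndim) * xhat + self._expand(
            self.beta.value, x.ndim
        )

    def backward(self, grad):
        xhat, inv, axes, n = self._xhat, self._inv, self._axes, self._n
        ndim = grad.ndim
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self._expand(self.gamma.value, ndim)
        if not self._training:
            return g * self._expand(inv, ndim)
        s1 = g.sum(axis=axes, keepdims=True)
        s2 = (g * xhat).sum(axis=axes, keepdims=True)
        return (g - s1 / n - xhat * s2 / n) * self._expand(inv, ndim)


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = p, rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class MaxPool1d(Layer):
    """Kernel-2, stride-2 max pooling; odd trailing positions are dropped
    (floor division of the temporal length)."""

    def __init__(self, kernel: int = 2):
        self.kernel = kernel

    def forward(self, x, training=False):
        B, C, T = x.shape
        t_out = T // self.kernel
        trimmed = x[:, :, : t_out * self.kernel].reshape(B, C, t_out, self.kernel)
        self._argmax = trimmed.argmax(axis=3)
        self._in_shape = x.shape
        return trimmed.max(axis=3)

    def backward(self, grad):
        B, C, T = self._in_shape
        t_out = grad.shape[2]
        dx = np.zeros((B, C, t_out, self.kernel))
        np.put_along_axis(dx, self._argmax[..., None], grad[..., None], axis=3)
        out = np.zeros(self._in_shape)
        out[:, :, : t_out * self.kernel] = dx.reshape(B, C, t_out * self.kernel)
        return out


class Embedding(Layer):
    """Trainable lookup table mapping integer indices to dense vectors."""

    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        self.W = Param(rng.standard_normal((num_embeddings, dim)))
        self.num_embeddings = num_embeddings

    def params(self):
        return [self.W]

    def forward(self, idx, training=False):
        idx = np.asarray(idx)
        if idx.min() < 0 or idx.max() >= self.W.value.shape[0]:
            raise ValueError(
                f"embedding indices must lie in [0, {self.W.value.shape[0] - 1}]"
            )
        self._idx = idx
        return self.W.value[idx]

    def backward(self, grad):
        np.add.at(self.W.grad, self._idx, grad)
        return None  # integer inputs have no gradient


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
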