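"""Minimal 1-D neural-network layers with explicit forward/backward passes.

All layers operate on float32 tensors of shape (batch, length, channels)
except ``Dense`` after ``Flatten``, which sees (batch, features). Each layer
exposes ``params``/``grads`` as parallel lists of arrays so optimizers can
walk the whole model uniformly.

Convolutions are stride-1 with 'same' zero padding (odd widths), implemented
via ``sliding_window_view`` + ``tensordot``; the input gradient is the full
correlation of the output gradient with the width-flipped kernel, which for
odd widths under symmetric padding uses the same padding amount.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def regularization_loss(self) -> float:
        return 0.0

    def output_length(self, length: int) -> int:
        """Length axis after this layer (identity for most layers)."""
        return length


def _windows(x: np.ndarray, width: int, pad: int) -> np.ndarray:
    """(B, L, C) -> (B, L_out, C, width) sliding windows after zero padding."""
    xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
    return np.lib.stride_tricks.sliding_window_view(xp, width, axis=1)


class Conv1D(Layer):
    """Stride-1 'same' 1-D convolution with optional L1/L2 weight penalty."""

    def __init__(
        self,
        in_channels: int,
        n_filters: int,
        width: int,
        l1: float = 0.0,
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if width % 2 != 1:
            raise ValueError(f"filter width must be odd, got {width}")
        rng = rng or np.random.default_rng()
        fan_in, fan_out = width * in_channels, width * n_filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # glorot-uniform
        self.kernel = rng.uniform(-limit, limit, size=(width, in_channels, n_filters)).astype(np.float32)
        self.bias = np.zeros(n_filters, dtype=np.float32)
        self.l1, self.l2 = float(l1), float(l2)
        self.pad = (width - 1) // 2
        self.params = [self.kernel, self.bias]
        self.grads = [np.zeros_like(self.kernel), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x if training else None
        win = _windows(x, self.kernel.shape[0], self.pad)  # (B, L, C, W)
        return np.tensordot(win, self.kernel, axes=([2, 3], [1, 0])) + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win = _windows(self._x, self.kernel.shape[0], self.pad)
        dk = np.tensordot(win, grad, axes=([0, 1], [0, 1]))  # (C, W, F)
        self.grads[0][...] = dk.transpose(1, 0, 2)
        if self.l1:
            self.grads[0] += self.l1 * np.sign(self.kernel)
        if self.l2:
            self.grads[0] += 2.0 * self.l2 * self.kernel
        self.grads[1][...] = grad.sum(axis=(0, 1))
        gwin = _windows(grad, self.kernel.shape[0], self.pad)  # (B, L, F, W)
        kflip = self.kernel[::-1]  # (W, C, F)
        return np.tensordot(gwin, kflip, axes=([2, 3], [2, 0]))  # (B, L, C)

    def regularization_loss(self) -> float:
        loss = 0.0
        if self.l1:
            loss += self.l1 * float(np.abs(self.kernel).sum())
        if self.l2:
            loss += self.l2 * float((self.kernel ** 2).sum())
        return loss


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, channels: int, momentum: float = 0.99, eps: float = 1e-3) -> None:
        super().__init__()
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
            self._inv_std = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mean) * self._inv_std
            return self.gamma * self._xhat + self.beta
        return self.gamma * (x - self.running_mean) / np.sqrt(self.running_var + self.eps) + self.beta

    def backward(self, grad: np.ndarray) -> np.ndarray:
        m = grad.shape[0] * grad.shape[1]
        self.grads[0][...] = (grad * self._xhat).sum(axis=(0, 1))
        self.grads[1][...] = grad.sum(axis=(0, 1))
        dxhat = grad * self.gamma
        return (
            self._inv_std / m
            * (m * dxhat - dxhat.sum(axis=(0, 1)) - self._xhat * (dxhat * self._xhat).sum(axis=(0, 1)))
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling by default (stride = pool window)."""

    def __init__(self, pool: int = 2, stride: int | None = None) -> None:
        super().__init__()
        self.pool = pool
        self.stride = pool if stride is None else stride
        if self.stride != self.pool and self.stride != 1:
            raise ValueError("only stride == pool or stride == 1 supported")

    def output_length(self, length: int) -> int:
        if self.stride == self.pool:
            return length // self.pool
        return length - self.pool + 1

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        b, length, c = x.shape
        self._in_shape = x.shape
        if self.stride == self.pool:
            n = length // self.pool
            blocks = x[:, : n * self.pool].reshape(b, n, self.pool, c)
            self._argmax = blocks.argmax(axis=2)
            return blocks.max(axis=2)
        win = np.lib.stride_tricks.sliding_window_view(x, self.pool, axis=1)  # (B, L', C, P)
        self._argmax = win.argmax(axis=3)
        return win.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, length, c = self._in_shape
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        n = grad.shape[1]
        bi, ni, ci = np.ogrid[:b, :n, :c]
        if self.stride == self.pool:
            flat_pos = ni * self.pool + self._argmax
        else:
            flat_pos = ni + self._argmax
        np.add.at(dx, (bi, flat_pos, ci), grad)
        return dx


class Dense(Layer):
    """Affine map on the trailing axis (position-wise on 3-D inputs)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (in_features + out_features))
        self.weight = rng.uniform(-limit, limit, size=(in_features, out_features)).astype(np.float32)
        self.bias = np.zeros(out_features, dtype=np.float32)
        self.params = [self.weight, self.bias]
        self.grads = [np.zeros_like(self.weight), np.zeros_like(self.bias)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return x @ self.weight + self.bias

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.grads[0][...] = x2.T @ g2
        self.grads[1][...] = g2.sum(axis=0)
        return grad @ self.weight.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must lie in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self.rate == 0.0:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray, eps: float = 1e-12) -> float:
    return float(-(onehot * np.log(probs + eps)).sum(axis=-1).mean())
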