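"""Minimal numpy feed-forward layers with reverse-mode gradients.

The encoder/classifier architectures used here need exact layer-by-layer
control (conv kernels and padding, batch-norm rows, per-model dropout,
max-pool geometry), so the layers are implemented directly on numpy with
hand-written backward passes and an Adam optimizer. Shapes follow the
usual conventions: dense tensors are (N, F), convolutional tensors are
(N, C, L).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def state_arrays(self) -> list[np.ndarray]:
        """Arrays that define the layer beyond params (e.g. BN running stats)."""
        return []

    def set_state_arrays(self, arrays: list[np.ndarray]) -> None:
        assert not arrays

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map (N, n_in) -> (N, n_out); uniform fan-in init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Param(rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.b = Param(rng.uniform(-bound, bound, size=n_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class Conv1d(Layer):
    """1-D convolution, stride 1, symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, padding: int,
                 rng: np.random.Generator):
        self.kernel = kernel
        self.padding = padding
        bound = 1.0 / np.sqrt(c_in * kernel)
        self.W = Param(rng.uniform(-bound, bound, size=(c_out, c_in, kernel)))
        self.b = Param(rng.uniform(-bound, bound, size=c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._cols = cols
        out = np.einsum("nclk,ock->nol", cols, self.W.value, optimize=True)
        return out + self.b.value[:, None]

    def backward(self, grad):
        self.W.grad += np.einsum("nol,nclk->ock", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        pad = self.kernel - 1 - self.padding
        gp = np.pad(grad, ((0, 0), (0, 0), (pad, pad)))
        gcols = np.lib.stride_tricks.sliding_window_view(gp, self.kernel, axis=2)
        return np.einsum(
            "nolk,ock->ncl", gcols, self.W.value[:, :, ::-1], optimize=True
        )


class MaxPool1d(Layer):
    def __init__(self, kernel: int = 6, stride: int = 2):
        self.kernel = kernel
        self.stride = stride

    def forward(self, x, training=False):
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        win = win[:, :, :: self.stride]
        self._arg = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        n, c, n_out = grad.shape
        pos = self._arg + np.arange(n_out) * self.stride
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(dx, (ni, ci, pos), grad)
        return dx


class BatchNorm(Layer):
    """Batch normalization over axis 0 for dense input or (0, 2) per
    channel for convolutional input (``conv=True``)."""

    def __init__(self, n_features: int, conv: bool = False,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.conv = conv
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.run_mean = np.zeros(n_features)
        self.run_var = np.ones(n_features)

    def params(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return [self.run_mean.copy(), self.run_var.copy()]

    def set_state_arrays(self, arrays):
        self.run_mean, self.run_var = [a.copy() for a in arrays]

    def _shape(self):
        return (1, -1, 1) if self.conv else (1, -1)

    def forward(self, x, training=False):
        axes = (0, 2) if self.conv else (0,)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.run_mean = (1 - m) * self.run_mean + m * mean
            self.run_var = (1 - m) * self.run_var + m * var
        else:
            mean, var = self.run_mean, self.run_var
        s = self._shape()
        self._istd = (1.0 / np.sqrt(var + self.eps)).reshape(s)
        self._xhat = (x - mean.reshape(s)) * self._istd
        return self.gamma.value.reshape(s) * self._xhat + self.beta.value.reshape(s)

    def backward(self, grad):
        axes = (0, 2) if self.conv else (0,)
        s = self._shape()
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        m = grad.shape[0] * (grad.shape[2] if self.conv else 1)
        dxhat = grad * self.gamma.value.reshape(s)
        term = (
            m * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=axes, keepdims=True)
        )
        return self._istd / m * term


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.slope * grad)


class Sigmoid(Layer):
    def forward(self, x, training=False):
        self._out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._out

    def backward(self, grad):
        return grad * self._out * (1 - self._out)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_arrays(self):
        return [a for layer in self.layers for a in layer.state_arrays()]

    def set_state_arrays(self, arrays):
        i = 0
        for layer in self.layers:
            k = len(layer.state_arrays())
            layer.set_state_arrays(arrays[i : i + k])
            i += k

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad.fill(0.0)

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray):
    """Mean BCE loss and its gradient with respect to the probabilities."""
    p = np.clip(p, 1e-7, 1 - 1e-7)
    loss = float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
    grad = (p - y) / (p * (1 - p)) / len(y)
    return loss, grad
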