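"""Minimal NumPy neural-network layers with explicit backpropagation.

Only what the murmur models need: 1D convolutions (same padding), batch
normalisation, ReLU / leaky ReLU, dropout, fixed and adaptive pooling,
nearest-neighbour upsampling, dense layers and an Adam optimiser.  Every
layer implements ``forward(x, training)`` and ``backward(grad)``; parameter
gradients accumulate into ``Param.grad`` and are consumed by ``Adam.step``.

All backward passes are verified against central finite differences in the
test suite, so the layers can be trusted as building blocks for the U-Net,
the pooling encoder and the patient-level classifier.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "LeakyReLU",
    "Dropout",
    "MaxPool1d",
    "AvgPool1d",
    "Upsample1d",
    "Linear",
    "AdaptiveMaxPool1d",
    "AdaptiveAvgPool1d",
    "AdaptiveMinPool1d",
    "Adam",
    "sigmoid",
    "softmax",
]


class Param:
    """A trainable array together with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; layers without parameters return an empty list."""

    def parameters(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.result_type(x, np.float32))
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv1d(Layer):
    """1D convolution with 'same' zero padding (odd kernel), stride 1.

    Input/output layout is ``(batch, channels, time)``.  Implemented with
    ``sliding_window_view`` + ``tensordot`` so the heavy lifting is a single
    BLAS matmul in both directions.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 5,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        self.weight = Param(_he_init(rng, (out_channels, in_channels, kernel_size),
                                     fan_in, dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype))
        self.kernel_size = kernel_size
        self._x_col = None

    def parameters(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        # (B, Cin, T, K)
        col = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
        self._x_col = col if training else None
        w = self.weight.value
        out = np.tensordot(col, w, axes=([1, 3], [1, 2]))  # (B, T, Cout)
        out = np.ascontiguousarray(out.transpose(0, 2, 1))
        out += self.bias.value[None, :, None]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k = self.kernel_size
        pad = k // 2
        col = self._x_col
        # dW: sum over batch and time
        self.weight.grad += np.tensordot(grad, col, axes=([0, 2], [0, 2]))
        self.bias.grad += grad.sum(axis=(0, 2))
        # dx = grad (*) flipped kernel, swapping in/out channels
        gp = np.pad(grad, ((0, 0), (0, 0), (pad, pad)))
        gcol = np.lib.stride_tricks.sliding_window_view(gp, k, axis=2)
        w_flip = self.weight.value[:, :, ::-1]
        dx = np.tensordot(gcol, w_flip, axes=([1, 3], [0, 2]))  # (B, T, Cin)
        return np.ascontiguousarray(dx.transpose(0, 2, 1))


class BatchNorm1d(Layer):
    """Batch normalisation over the batch (and time, for 3D input) axes."""

    def __init__(self, num_features: int, momentum: float = 0.9,
                 eps: float = 1e-5, dtype=np.float32):
        self.gamma = Param(np.ones(num_features, dtype=dtype))
        self.beta = Param(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        axes = (0, 2) if x.ndim == 3 else (0,)
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean.astype(np.float64))
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var.astype(np.float64))
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv_std.reshape(shape)
        out = self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)
        if training:
            self._cache = (xhat, inv_std, axes, shape)
        return out.astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes, shape = self._cache
        n = grad.size // grad.shape[1]
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = self.gamma.value.reshape(shape)
        dxhat = grad * g
        dx = (dxhat - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / n)
        return dx * inv_std.reshape(shape)


class ReLU(Layer):
    def forward(self, x, training=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.negative_slope = negative_slope

    def forward(self, x, training=True):
        self._mask = x > 0
        return np.where(self._mask, x, self.negative_slope * x)

    def backward(self, grad):
        return np.where(self._mask, grad, self.negative_slope * grad)


class Dropout(Layer):
    """Inverted dropout; identity when evaluating or p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, training=True):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class MaxPool1d(Layer):
    """Kernel-2, stride-2 max pooling on (B, C, T); T must be even."""

    def forward(self, x, training=True):
        a, b = x[:, :, 0::2], x[:, :, 1::2]
        self._take_first = a >= b
        return np.where(self._take_first, a, b)

    def backward(self, grad):
        B, C, T = grad.shape
        dx = np.zeros((B, C, 2 * T), dtype=grad.dtype)
        dx[:, :, 0::2] = np.where(self._take_first, grad, 0)
        dx[:, :, 1::2] = np.where(self._take_first, 0, grad)
        return dx


class AvgPool1d(Layer):
    """Kernel-2, stride-2 average pooling on (B, C, T); T must be even."""

    def forward(self, x, training=True):
        return 0.5 * (x[:, :, 0::2] + x[:, :, 1::2])

    def backward(self, grad):
        return np.repeat(0.5 * grad, 2, axis=2)


class Upsample1d(Layer):
    """Nearest-neighbour x2 upsampling on (B, C, T)."""

    def forward(self, x, training=True):
        return np.repeat(x, 2, axis=2)

    def backward(self, grad):
        return grad[:, :, 0::2] + grad[:, :, 1::2]


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Param(_he_init(rng, (out_features, in_features),
                                     in_features, dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, training=True):
        self._x = x if training else None
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


def _adaptive_bounds(t: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(m + 1)
    starts = (idx[:-1] * t) // m
    ends = np.maximum(((idx[1:] * t) + m - 1) // m, starts + 1)
    return starts, np.minimum(ends, t)


class _AdaptiveExtremePool1d(Layer):
    """Shared machinery for adaptive max / min pooling to m segments."""

    _argfun = staticmethod(np.argmax)

    def __init__(self, output_size: int):
        self.output_size = output_size

    def forward(self, x, training=True):
        B, C, T = x.shape
        m = self.output_size
        starts, ends = _adaptive_bounds(T, m)
        out = np.empty((B, C, m), dtype=x.dtype)
        self._arg = np.empty((B, C, m), dtype=np.int64)
        for j in range(m):
            seg = x[:, :, starts[j]:ends[j]]
            a = self._argfun(seg, axis=2)
            self._arg[:, :, j] = a + starts[j]
            out[:, :, j] = np.take_along_axis(seg, a[:, :, None], axis=2)[:, :, 0]
        self._in_T = T
        return out

    def backward(self, grad):
        B, C, m = grad.shape
        dx = np.zeros((B, C, self._in_T), dtype=grad.dtype)
        bi = np.arange(B)[:, None, None]
        ci = np.arange(C)[None, :, None]
        np.add.at(dx, (bi, ci, self._arg), grad)
        return dx


class AdaptiveMaxPool1d(_AdaptiveExtremePool1d):
    _argfun = staticmethod(np.argmax)


class AdaptiveMinPool1d(_AdaptiveExtremePool1d):
    _argfun = staticmethod(np.argmin)


class AdaptiveAvgPool1d(Layer):
    def __init__(self, output_size: int):
        self.output_size = output_size

    def forward(self, x, training=True):
        B, C, T = x.shape
        m = self.output_size
        starts, ends = _adaptive_bounds(T, m)
        self._bounds = (starts, ends, T)
        out = np.empty((B, C, m), dtype=x.dtype)
        for j in range(m):
            out[:, :, j] = x[:, :, starts[j]:ends[j]].mean(axis=2)
        return out

    def backward(self, grad):
        starts, ends, T = self._bounds
        B, C, m = grad.shape
        dx = np.zeros((B, C, T), dtype=grad.dtype)
        for j in range(m):
            dx[:, :, starts[j]:ends[j]] += (grad[:, :, j:j + 1]
                                            / (ends[j] - starts[j]))
        return dx


class Adam:
    """Adam optimiser over a list of Params (Kingma & Ba defaults)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value, dtype=np.float64) for p in params]
        self._v = [np.zeros_like(p.value, dtype=np.float64) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad.astype(np.float64)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps))
            p.value -= update.astype(p.value.dtype)


def state_dict(layers: list[Layer]) -> list[np.ndarray]:
    """Snapshot all parameter values (deep copies) of a layer stack."""
    return [p.value.copy() for layer in layers for p in layer.parameters()]


def load_state(layers: list[Layer], state: list[np.ndarray]) -> None:
    params = [p for layer in layers for p in layer.parameters()]
    if len(params) != len(state):
        raise ValueError("state does not match layer stack")
    for p, v in zip(params, state):
        p.value = v.copy()
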