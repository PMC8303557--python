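"""Minimal feed-forward CNN layers with explicit backpropagation.

All layers operate on float32/float64 arrays in NCHW layout and implement
``forward(x, train)`` / ``backward(grad_out)`` pairs.  The backward pass of
every layer returns the gradient with respect to its input, so a
:class:`Sequential` stack can be differentiated end to end; this is what the
trainer and the Grad-CAM implementation rely on.

The framework is deliberately small: convolution via im2col, batch
normalization with running statistics, max pooling, dense layers, ReLU and
sigmoid activations, residual blocks, and an SGD-with-momentum optimizer.
Everything is deterministic given a ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "Dense",
    "ResidualBlock",
    "BottleneckBlock",
    "SGD",
]


class Parameter:
    """A trainable array together with its gradient accumulator."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape


class Module:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[Parameter]:
        return []

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train=train)


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    def parameters(self):
        out: list[Parameter] = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


# ---------------------------------------------------------------------------
# im2col helpers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride, :, :]  # n, c, ho, wo, k, k
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int):
    n, c, h, w = xshape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    dx = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 4, 5, 1, 2)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d[:, :, i, j]
    if pad:
        dx = dx[:, :, pad : pad + h, pad : pad + w]
    return dx


class Conv2d(Module):
    """2-D convolution (cross-correlation) with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels))
        self.k = kernel_size
        self.stride = stride
        self.pad = padding
        self._cache = None

    def forward(self, x, train=True):
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.weight.value.reshape(self.weight.shape[0], -1)
        out = cols @ w2.T + self.bias.value
        n = x.shape[0]
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        self._cache = (x.shape, cols)
        return out

    def backward(self, grad_out):
        xshape, cols = self._cache
        n, cout, ho, wo = grad_out.shape
        g = grad_out.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.weight.grad += (g.T @ cols).reshape(self.weight.shape)
        self.bias.grad += g.sum(axis=0)
        dcols = g @ self.weight.value.reshape(cout, -1)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad_out):
        xhat, inv, xshape = self._cache
        n = xshape[0] * xshape[2] * xshape[3]
        self.gamma.grad += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad_out.sum(axis=(0, 2, 3))
        g = grad_out * self.gamma.value[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        gx_sum = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, -1, 1, 1)
        dx = (g - gsum / n - xhat * gx_sum / n) * inv[None, :, None, None]
        return dx

    def parameters(self):
        return [self.gamma, self.beta]


class ReLU(Module):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad_out):
        return grad_out * self._mask


class Sigmoid(Module):
    def forward(self, x, train=True):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, grad_out):
        return grad_out * self._out * (1.0 - self._out)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int | None = None, padding: int = 0) -> None:
        self.k = kernel_size
        self.stride = stride or kernel_size
        self.pad = padding

    def forward(self, x, train=True):
        n, c, h, w = x.shape
        xr = x.reshape(n * c, 1, h, w)
        if self.pad:
            xr = np.pad(
                xr,
                ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        cols, ho, wo = _im2col(xr, self.k, self.stride, 0)
        self._argmax = cols.argmax(axis=1)
        self._shapes = (x.shape, xr.shape, ho, wo)
        out = cols.max(axis=1).reshape(n * c, ho, wo).reshape(n, c, ho, wo)
        return out

    def backward(self, grad_out):
        xshape, xrshape, ho, wo = self._shapes
        n, c, h, w = xshape
        g = grad_out.reshape(-1)
        dcols = np.zeros((g.size, self.k * self.k), dtype=grad_out.dtype)
        dcols[np.arange(g.size), self._argmax] = g
        dx = _col2im(dcols, xrshape, self.k, self.stride, 0)
        if self.pad:
            dx = dx[:, :, self.pad : self.pad + h, self.pad : self.pad + w]
        return dx.reshape(n, c, h, w)


class GlobalAvgPool2d(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out):
        n, c, h, w = self._shape
        return np.broadcast_to(grad_out[:, :, None, None], self._shape) / (h * w)


class Flatten(Module):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Dense(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x, train=True):
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad_out):
        self.weight.grad += grad_out.T @ self._x
        self.bias.grad += grad_out.sum(axis=0)
        return grad_out @ self.weight.value

    def parameters(self):
        return [self.weight, self.bias]


class ResidualBlock(Module):
    """Basic two-convolution residual block (3x3 + 3x3) with identity skip."""

    def __init__(self, in_channels, out_channels, stride=1, rng=None):
        self.main = Sequential(
            Conv2d(in_channels, out_channels, 3, stride=stride, padding=1, rng=rng),
            BatchNorm2d(out_channels),
            ReLU(),
            Conv2d(out_channels, out_channels, 3, stride=1, padding=1, rng=rng),
            BatchNorm2d(out_channels),
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    def forward(self, x, train=True):
        main = self.main.forward(x, train=train)
        skip = self.shortcut.forward(x, train=train) if self.shortcut else x
        return self.relu.forward(main + skip, train=train)

    def backward(self, grad_out):
        g = self.relu.backward(grad_out)
        gx = self.main.backward(g)
        gx = gx + (self.shortcut.backward(g) if self.shortcut else g)
        return gx

    def parameters(self):
        out = self.main.parameters()
        if self.shortcut:
            out.extend(self.shortcut.parameters())
        return out


class BottleneckBlock(Module):
    """1x1 - 3x3 - 1x1 bottleneck residual block (expansion 4)."""

    expansion = 4

    def __init__(self, in_channels, mid_channels, stride=1, rng=None):
        out_channels = mid_channels * self.expansion
        self.main = Sequential(
            Conv2d(in_channels, mid_channels, 1, rng=rng),
            BatchNorm2d(mid_channels),
            ReLU(),
            Conv2d(mid_channels, mid_channels, 3, stride=stride, padding=1, rng=rng),
            BatchNorm2d(mid_channels),
            ReLU(),
            Conv2d(mid_channels, out_channels, 1, rng=rng),
            BatchNorm2d(out_channels),
        )
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride, rng=rng),
                BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = None
        self.relu = ReLU()

    forward = ResidualBlock.forward
    backward = ResidualBlock.backward
    parameters = ResidualBlock.parameters


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, parameters: list[Parameter], lr: float, momentum: float = 0.9):
        self.parameters = parameters
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in parameters]

    def zero_grad(self):
        for p in self.parameters:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.parameters, self._velocity):
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v
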