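"""Minimal CNN building blocks with explicit backpropagation.

All computation is float32 numpy.  Each layer caches what its backward
pass needs during ``forward(train=True)``; ``backward`` consumes the
upstream gradient and accumulates parameter gradients in place.  This is
deliberately a small, deterministic core: no threads, no global state,
reproducible bit-for-bit from a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Flatten",
    "BatchNorm2d",
    "Sequential",
    "ResidualBlock",
]

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    n, c, h, w = x.shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow), (n, c, h, w, oh, ow)


def _col2im(dcols: np.ndarray, shape_info: tuple, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w, oh, ow = shape_info
    dcols = dcols.reshape(n, c, k, k, oh, ow)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Conv2d(Layer):
    """2D convolution via im2col, He-normal initialised."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None,
                 bias: bool = True):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Parameter(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Parameter(np.zeros(cout)) if bias else None
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols, info = _im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.w.value[None], cols)  # (N, cout, oh*ow)
        if self.b is not None:
            out += self.b.value[None, :, None]
        n, _, _, _, oh, ow = info
        if train:
            self._cache = (cols, info)
        return out.reshape(n, -1, oh, ow)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, info = self._cache
        n, c, h, w, oh, ow = info
        d2 = dout.reshape(n, -1, oh * ow)
        self.w.grad += np.matmul(d2, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.b is not None:
            self.b.grad += d2.sum(axis=(0, 2))
        dcols = np.matmul(self.w.value.T[None], d2)
        self._cache = None
        return _col2im(dcols, info, self.k, self.stride, self.pad)


class Linear(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / nin)
        self.w = Parameter(rng.normal(0.0, std, size=(nin, nout)))
        self.b = Parameter(np.zeros(nout))
        self._x = None

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        dx = dout @ self.w.value.T
        self._x = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0.0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2d(Layer):
    """Non-overlapping 2x2 max pooling (ties go to the first element)."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        windows = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = dwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(n, c, h, w)


class GlobalAvgPool2d(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).copy()


class Flatten(Layer):
    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        shape = self._shape
        self._shape = None
        return dout.reshape(shape)


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        dx = inv[None, :, None, None] * (dxhat - s1 / m - xhat * s2 / m)
        self._cache = None
        return dx


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def children(self) -> list[Layer]:
        return self.layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Layer):
    """conv-bn-relu-conv-bn with identity (or 1x1-projected) skip, relu out."""

    def __init__(self, cin: int, cout: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(cin, cout, 3, stride=stride, pad=1, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, stride=1, pad=1, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj: Sequential | None = Sequential(
                Conv2d(cin, cout, 1, stride=stride, pad=0, rng=rng, bias=False),
                BatchNorm2d(cout),
            )
        else:
            self.proj = None
        self._mask = None

    def children(self) -> list[Layer]:
        subs: list[Layer] = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.proj is not None:
            subs.append(self.proj)
        return subs

    def parameters(self) -> list[Parameter]:
        ps = (self.conv1.parameters() + self.bn1.parameters()
              + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            ps += self.proj.parameters()
        return ps

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = self.bn1.forward(self.conv1.forward(x, train), train)
        out = self.relu1.forward(out, train)
        out = self.bn2.forward(self.conv2.forward(out, train), train)
        skip = self.proj.forward(x, train) if self.proj is not None else x
        out = out + skip
        res = np.maximum(out, 0.0)
        if train:
            self._mask = out > 0.0
        return res

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dout = dout * self._mask
        self._mask = None
        dskip = self.proj.backward(dout) if self.proj is not None else dout
        d = self.bn2.backward(dout)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        d = self.bn1.backward(d)
        dx = self.conv1.backward(d)
        return dx + dskip


def iter_layers(layer: Layer):
    """Depth-first traversal over a layer tree (containers included)."""
    yield layer
    for sub in layer.children():
        yield from iter_layers(sub)


def get_model_state(model: Layer) -> list[np.ndarray]:
    """All arrays defining the model: parameters plus batch-norm statistics,
    in deterministic traversal order."""
    arrays: list[np.ndarray] = []
    for layer in iter_layers(model):
        if isinstance(layer, (Conv2d, Linear)):
            arrays.extend(p.value.copy() for p in layer.parameters())
        elif isinstance(layer, BatchNorm2d):
            arrays.extend([layer.gamma.value.copy(), layer.beta.value.copy(),
                           layer.running_mean.copy(), layer.running_var.copy()])
    return arrays


def set_model_state(model: Layer, arrays: list[np.ndarray]) -> None:
    """Inverse of :func:`get_model_state`."""
    it = iter(arrays)
    for layer in iter_layers(model):
        if isinstance(layer, (Conv2d, Linear)):
            for p in layer.parameters():
                p.value[...] = next(it)
        elif isinstance(layer, BatchNorm2d):
            layer.gamma.value[...] = next(it)
            layer.beta.value[...] = next(it)
            layer.running_mean[...] = next(it)
            layer.running_var[...] = next(it)
    if next(it, None) is not None:
        raise ValueError("state array count does not match the model")
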