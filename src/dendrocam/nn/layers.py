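"""Minimal numpy building blocks for the trunk segmenter.

All layers operate on NHWC float32 arrays and implement explicit
forward/backward passes.  Spatial convolutions use shift-and-add (nine
vectorised adds for a 3x3 kernel) rather than im2col, which keeps peak
memory at one feature map and is bandwidth-bound rather than
compute-bound at these sizes; channel mixing is a single matmul.

Convolutions carry no bias terms, matching the parameter accounting
``D_k^2 M + M N_out`` of a separable block exactly; the only biases in
the network are the attention convolution and the final 1x1 classifier.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

__all__ = [
    "Parameter",
    "DepthwiseConv2d",
    "PointwiseConv",
    "SeparableConv2d",
    "Conv2d",
    "ReLU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "SpatialAttention",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Parameter:
    """A trainable array and its accumulated gradient."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> List[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class DepthwiseConv2d(Layer):
    """One k x k spatial filter per channel, 'same' zero padding, stride 1."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("depthwise kernel size must be odd for 'same' padding")
        self.k = kernel_size
        self.w = Parameter(
            _he_init(rng, (kernel_size, kernel_size, channels), kernel_size**2)
        )
        self._x_pad: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.w]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._x_pad = xp if train else None
        h, w = x.shape[1], x.shape[2]
        out = np.zeros_like(x)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                out += wv[i, j] * xp[:, i : i + h, j : j + w, :]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._x_pad
        h, w = grad.shape[1], grad.shape[2]
        for i in range(k):
            for j in range(k):
                self.w.grad[i, j] += np.einsum(
                    "nhwc,nhwc->c", grad, xp[:, i : i + h, j : j + w, :]
                )
        gp = np.pad(grad, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = np.zeros_like(grad)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                # transposed correlation: flipped kernel over padded grad
                dx += wv[i, j] * gp[:, k - 1 - i : k - 1 - i + h, k - 1 - j : k - 1 - j + w, :]
        self._x_pad = None
        return dx


class PointwiseConv(Layer):
    """1x1 convolution (per-pixel channel mixing), optionally with bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rng: np.random.Generator,
        bias: bool = False,
    ):
        self.w = Parameter(_he_init(rng, (in_channels, out_channels), in_channels))
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._x: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        out = x @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        cin, cout = self.w.value.shape
        self.w.grad += x.reshape(-1, cin).T @ grad.reshape(-1, cout)
        if self.b is not None:
            self.b.grad += grad.reshape(-1, cout).sum(axis=0)
        self._x = None
        return grad @ self.w.value.T


class SeparableConv2d(Layer):
    """Depthwise k x k followed by a 1x1 pointwise mix (MobileNet block).

    Parameter count is exactly ``k^2 * M + M * N_out``.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
    ):
        self.depthwise = DepthwiseConv2d(in_channels, kernel_size, rng)
        self.pointwise = PointwiseConv(in_channels, out_channels, rng)

    def parameters(self) -> List[Parameter]:
        return self.depthwise.parameters() + self.pointwise.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.pointwise.forward(self.depthwise.forward(x, train), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.depthwise.backward(self.pointwise.backward(grad))


class Conv2d(Layer):
    """Small standard convolution ('same' padding), used only for the
    attention map head where the input has two channels."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        if kernel_size % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        self.k = kernel_size
        fan_in = kernel_size**2 * in_channels
        self.w = Parameter(
            _he_init(rng, (kernel_size, kernel_size, in_channels, out_channels), fan_in)
        )
        self.b = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self._x_pad: Optional[np.ndarray] = None

    def parameters(self) -> List[Parameter]:
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._x_pad = xp if train else None
        n, h, w, _ = x.shape
        cout = self.w.value.shape[3]
        out = np.zeros((n, h, w, cout), dtype=x.dtype)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                out += xp[:, i : i + h, j : j + w, :] @ wv[i, j]
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = self._x_pad
        n, h, w, cout = grad.shape
        cin = self.w.value.shape[2]
        g2 = grad.reshape(-1, cout)
        for i in range(k):
            for j in range(k):
                self.w.grad[i, j] += (
                    xp[:, i : i + h, j : j + w, :].reshape(-1, cin).T @ g2
                )
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        gp = np.pad(grad, ((0, 0), (p, p), (p, p), (0, 0)))
        dx = np.zeros((n, h, w, cin), dtype=grad.dtype)
        wv = self.w.value
        for i in range(k):
            for j in range(k):
                dx += gp[:, k - 1 - i : k - 1 - i + h, k - 1 - j : k - 1 - j + w, :] @ wv[i, j].T
        self._x_pad = None
        return dx


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        self._mask = x > 0 if train else None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad * self._mask
        self._mask = None
        return g


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2.  Requires even spatial dimensions."""

    def __init__(self) -> None:
        self._mask: Optional[np.ndarray] = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            # route gradient to every maximal element of the window; with
            # continuous activations ties have measure zero
            up = out[:, :, None, :, None, :]
            self._mask = (xr == up).astype(x.dtype)
            self._shape = x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h2, w2, c = grad.shape
        g = self._mask * grad[:, :, None, :, None, :]
        self._mask = None
        return g.reshape(self._shape)


class UpsampleNearest2x(Layer):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        return grad.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SpatialAttention(Layer):
    """Spatial attention: channel-wise max- and average-pooling are
    concatenated into a 2-channel descriptor, convolved, and passed
    through a sigmoid; the resulting H x W x 1 map multiplicatively
    re-weights the input features.

    ``forward`` returns the re-weighted features; :meth:`attention_map`
    exposes the map itself (values strictly in (0, 1)).
    """

    def __init__(self, kernel_size: int, rng: np.random.Generator):
        self.conv = Conv2d(2, 1, kernel_size, rng, bias=True)
        self._cache = None

    def parameters(self) -> List[Parameter]:
        return self.conv.parameters()

    def _descriptor(self, x: np.ndarray) -> np.ndarray:
        return np.stack([x.max(axis=3), x.mean(axis=3)], axis=3)

    def attention_map(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] < 1:
            raise ValueError(f"expected NHWC features with C >= 1, got {x.shape}")
        desc = self._descriptor(x)
        return sigmoid(self.conv.forward(desc, train))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        desc = self._descriptor(x)
        a = sigmoid(self.conv.forward(desc, train))
        if train:
            argmax = x.argmax(axis=3)
            self._cache = (x, a, argmax)
        return x * a

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, a, argmax = self._cache
        c = x.shape[3]
        dx = grad * a
        da = (grad * x).sum(axis=3, keepdims=True)
        dz = da * a * (1.0 - a)
        ddesc = self.conv.backward(dz)
        # average-pool branch: uniform 1/C
        dx += ddesc[..., 1:2] / c
        # max-pool branch: route to the arg-max channel
        dmax = ddesc[..., 0]
        n, h, w = dmax.shape
        flat = np.zeros((n * h * w, c), dtype=grad.dtype)
        flat[np.arange(n * h * w), argmax.ravel()] = dmax.ravel()
        dx += flat.reshape(n, h, w, c)
        self._cache = None
        return dx
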