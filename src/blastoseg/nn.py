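"""Minimal NumPy neural-network engine used to build the segmentation model.

Implements exactly the layer set the architecture needs — 2-D convolution
with stride/dilation, depthwise convolution, pointwise (1x1) convolution,
2x2/stride-2 transposed convolution, 2x2 max pooling, batch normalisation and
ReLU — each with an analytic backward pass, plus the Adam optimizer.  The
convolutions are expressed as BLAS matrix products over k*k shifted views of
the padded input, which is what makes CPU training of the full network
practical at reduced image sizes.

Data layout is NCHW throughout; float32 by default (float64 is supported for
finite-difference gradient checking).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Adam",
    "BatchNorm2d",
    "Conv2d",
    "ConvTranspose2d",
    "DepthwiseConv2d",
    "MaxPool2d",
    "Module",
    "Param",
    "ReLU",
    "Sequential",
]


class Param:
    """A learnable tensor with its gradient accumulator.

    ``decay`` marks whether the parameter participates in L2 regularisation
    (convolution weights do; biases and batch-norm affine terms do not).
    """

    __slots__ = ("value", "grad", "decay", "name")

    def __init__(self, value: np.ndarray, decay: bool = True, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay
        self.name = name


class Module:
    def parameters(self) -> list[Param]:
        return []

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return []

    def init(self, rng: np.random.Generator) -> None:
        pass

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """k x k convolution with stride, dilation and zero padding."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        dilation: int = 1,
        padding: int = 0,
        bias: bool = True,
        dtype=np.float32,
    ):
        self.cin, self.cout = in_channels, out_channels
        self.k, self.s, self.d, self.p = kernel, stride, dilation, padding
        self.dtype = dtype
        self.weight = Param(np.zeros((out_channels, in_channels, kernel, kernel), dtype=dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype), decay=False) if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def init(self, rng: np.random.Generator) -> None:
        self.weight.value = _he_normal(
            rng, self.weight.value.shape, self.cin * self.k * self.k, self.dtype
        )

    def out_size(self, h: int) -> int:
        return (h + 2 * self.p - self.d * (self.k - 1) - 1) // self.s + 1

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        n, c, _, _ = xp.shape
        k, s, d = self.k, self.s, self.d
        cols = np.empty((n, c, k * k, ho, wo), dtype=xp.dtype)
        for a in range(k):
            for b in range(k):
                cols[:, :, a * k + b] = xp[
                    :, :, a * d : a * d + (ho - 1) * s + 1 : s, b * d : b * d + (wo - 1) * s + 1 : s
                ]
        return cols.reshape(n, c * k * k, ho * wo)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        ho, wo = self.out_size(h), self.out_size(w)
        if ho <= 0 or wo <= 0:
            raise ValueError(f"non-positive output size for input {h}x{w}")
        if self.k == 1 and self.s == 1:
            cols = x.reshape(n, c, h * w)
            xp_shape = None
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
            cols = self._im2col(xp, ho, wo)
            xp_shape = xp.shape
        wm = self.weight.value.reshape(self.cout, -1)
        y = np.matmul(wm, cols)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        self._cache = (cols, xp_shape, (n, c, h, w), (ho, wo)) if training else None
        return y.reshape(n, self.cout, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xp_shape, (n, c, h, w), (ho, wo) = self._cache
        dyf = dy.reshape(n, self.cout, ho * wo)
        wm = self.weight.value.reshape(self.cout, -1)
        self.weight.grad += (
            np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.weight.value.shape)
        )
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(wm.T, dyf)  # (n, c*k*k, ho*wo)
        if self.k == 1 and self.s == 1:
            return dcols.reshape(n, c, h, w)
        k, s, d = self.k, self.s, self.d
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        dcols = dcols.reshape(n, c, k * k, ho, wo)
        for a in range(k):
            for b in range(k):
                dxp[
                    :, :, a * d : a * d + (ho - 1) * s + 1 : s, b * d : b * d + (wo - 1) * s + 1 : s
                ] += dcols[:, :, a * k + b]
        if self.p:
            return dxp[:, :, self.p : self.p + h, self.p : self.p + w]
        return dxp


class DepthwiseConv2d(Module):
    """3x3 per-channel (grouped) convolution, stride 1, 'same' padding."""

    def __init__(self, channels: int, kernel: int = 3, bias: bool = True, dtype=np.float32):
        self.c, self.k = channels, kernel
        self.p = kernel // 2
        self.dtype = dtype
        self.weight = Param(np.zeros((channels, kernel, kernel), dtype=dtype))
        self.bias = Param(np.zeros(channels, dtype=dtype), decay=False) if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def init(self, rng: np.random.Generator) -> None:
        self.weight.value = _he_normal(rng, self.weight.value.shape, self.k * self.k, self.dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c:
            raise ValueError(f"expected {self.c} channels, got {c}")
        xp = np.pad(x, ((0, 0), (0, 0), (self.p, self.p), (self.p, self.p)))
        y = np.zeros_like(x)
        wv = self.weight.value
        for a in range(self.k):
            for b in range(self.k):
                y += wv[:, a, b][None, :, None, None] * xp[:, :, a : a + h, b : b + w]
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (xp, (h, w)) if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, (h, w) = self._cache
        wv = self.weight.value
        dxp = np.zeros_like(xp)
        for a in range(self.k):
            for b in range(self.k):
                self.weight.grad[:, a, b] += np.einsum(
                    "nchw,nchw->c", dy, xp[:, :, a : a + h, b : b + w]
                )
                dxp[:, :, a : a + h, b : b + w] += wv[:, a, b][None, :, None, None] * dy
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        return dxp[:, :, self.p : self.p + h, self.p : self.p + w]


class ConvTranspose2d(Module):
    """2x2 transposed convolution with stride 2 — exact spatial doubling."""

    def __init__(self, in_channels: int, out_channels: int, bias: bool = True, dtype=np.float32):
        self.cin, self.cout = in_channels, out_channels
        self.k = 2
        self.dtype = dtype
        self.weight = Param(np.zeros((in_channels, out_channels, 2, 2), dtype=dtype))
        self.bias = Param(np.zeros(out_channels, dtype=dtype), decay=False) if bias else None
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def init(self, rng: np.random.Generator) -> None:
        self.weight.value = _he_normal(rng, self.weight.value.shape, self.cin * 4, self.dtype)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        xr = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        wr = self.weight.value.reshape(c, self.cout * 4)
        y = (xr @ wr).reshape(n, h, w, self.cout, 2, 2)
        y = y.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.cout, 2 * h, 2 * w)
        if self.bias is not None:
            y += self.bias.value[None, :, None, None]
        self._cache = (xr, (n, h, w)) if training else None
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xr, (n, h, w) = self._cache
        dyr = (
            dy.reshape(n, self.cout, h, 2, w, 2)
            .transpose(0, 2, 4, 1, 3, 5)
            .reshape(n * h * w, self.cout * 4)
        )
        wr = self.weight.value.reshape(self.cin, self.cout * 4)
        self.weight.grad += (xr.T @ dyr).reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dx = (dyr @ wr.T).reshape(n, h, w, self.cin).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(dx)


class MaxPool2d(Module):
    """2x2 max pooling with stride 2 (requires even spatial size)."""

    def __init__(self):
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial size, got {h}x{w}")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w)) if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return np.ascontiguousarray(dx)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with learnable affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.c = channels
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(np.ones(channels, dtype=dtype), decay=False)
        self.beta = Param(np.zeros(channels, dtype=dtype), decay=False)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self._cache: tuple | None = None

    def parameters(self) -> list[Param]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        y = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv_std) if training else None
        return y.astype(x.dtype, copy=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += np.einsum("nchw,nchw->c", dy, xhat)
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = np.einsum("nchw,nchw->c", dxhat, xhat)
        dx = (inv_std[None, :, None, None] / m) * (
            m * dxhat - s1[None, :, None, None] - xhat * s2[None, :, None, None]
        )
        return dx.astype(dy.dtype, copy=False)


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        self._mask = x > 0 if training else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def parameters(self) -> list[Param]:
        return [p for m in self.modules for p in m.parameters()]

    def buffers(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for i, m in enumerate(self.modules):
            out += [(f"{i}.{name}", buf) for name, buf in m.buffers()]
        return out

    def init(self, rng: np.random.Generator) -> None:
        for m in self.modules:
            m.init(rng)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for m in self.modules:
            x = m.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


class Adam(Module):
    """Adam optimizer with optional L2 regularisation on decayable weights.

    The L2 term is added to the gradient before the moment updates (classic
    coupled weight decay), matching the reading of global L2 regularisation
    as a penalty on all convolution weights.
    """

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-6,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
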