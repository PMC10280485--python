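"""Minimal CPU neural-network layer with manual backpropagation.

The GAN components need 2-D convolutions, transposed convolutions, batch
normalization, dense layers and Adam. This module implements exactly that
set on float32 numpy arrays in NHWC layout (channels last — the native
layout of the 8-bit rasters the pipeline works with, and the
cache-friendly one for an im2col formulation on CPU). Convolutions use
im2col/col2im so the inner loop is a single BLAS matmul; transposed
convolutions are realized as stride-1 convolutions of the zero-dilated
input with the spatially flipped kernel, which is their textbook
definition.

Every layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients into ``Param.grad`` during ``backward``
(callers zero gradients between optimizer steps). Correctness of each
backward pass is checked against central finite differences in the test
suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np
from numpy.lib.stride_tricks import as_strided

F32 = np.float32

_BN_STATS_FROZEN = False


@contextmanager
def frozen_batchnorm_stats():
    """Batch-norm layers normalize with batch statistics but leave their
    running averages untouched inside this context.

    Used for discriminator passes over *generated* batches: inference is
    always on real images, so the running statistics must describe real
    data only — otherwise a diverging generator drags them arbitrarily far
    from the real-image distribution and eval-mode forward passes collapse.
    """
    global _BN_STATS_FROZEN
    previous = _BN_STATS_FROZEN
    _BN_STATS_FROZEN = True
    try:
        yield
    finally:
        _BN_STATS_FROZEN = previous


class Param:
    """A learnable tensor with its accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.asarray(data, dtype=F32)
        self.grad = np.zeros_like(self.data)


class Module:
    """Base class: a forward/backward pair with learnable parameters."""

    def params(self) -> list[Param]:
        out: list[Param] = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# im2col / col2im (NHWC)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, k: int, stride: int, oh: int, ow: int) -> np.ndarray:
    """Patch matrix (N*oh*ow, k*k*C) of a padded NHWC input."""
    n, _, _, c = xp.shape
    s0, s1, s2, s3 = xp.strides
    view = as_strided(
        xp,
        shape=(n, oh, ow, k, k, c),
        strides=(s0, s1 * stride, s2 * stride, s1, s2, s3),
    )
    return view.reshape(n * oh * ow, k * k * c)


def _col2im(
    dcols: np.ndarray,
    padded_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Scatter-add patch gradients back onto the padded input."""
    n, hp, wp, c = padded_shape
    dxp = np.zeros(padded_shape, dtype=F32)
    d6 = dcols.reshape(n, oh, ow, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += d6[
                :, :, :, i, j, :
            ]
    return dxp


def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    """3x3/1x1 convolution, NHWC, weight layout (k, k, cin, cout)."""

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int,
        stride: int = 1,
        pad: int = 0,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))  # He init
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=F32)
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        xp = _pad_hw(x, p)
        oh = (h + 2 * p - k) // s + 1
        ow = (w + 2 * p - k) // s + 1
        cols = _im2col(xp, k, s, oh, ow)
        cout = self.w.data.shape[3]
        out = cols @ self.w.data.reshape(-1, cout) + self.b.data
        self._cache = (cols, xp.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, cout)

    def backward(self, dout):
        cols, padded_shape, (n, oh, ow) = self._cache
        cout = self.w.data.shape[3]
        dmat = dout.reshape(-1, cout)
        self.w.grad += (cols.T @ dmat).reshape(self.w.data.shape)
        self.b.grad += dmat.sum(axis=0)
        dcols = dmat @ self.w.data.reshape(-1, cout).T
        dxp = _col2im(dcols, padded_shape, self.k, self.stride, oh, ow)
        p = self.pad
        return dxp[:, p : dxp.shape[1] - p, p : dxp.shape[2] - p, :] if p else dxp


class ConvTranspose2d(Module):
    """Transposed convolution: stride-1 conv of the zero-dilated input.

    Weight layout (k, k, cout, cin) so that the effective stride-1 kernel
    is the spatially flipped view with cin/cout swapped.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Param(rng.normal(0.0, std, size=(k, k, cin, cout)))
        self.b = Param(np.zeros(cout))
        self.k, self.stride, self.pad = k, stride, pad
        self._cache = None

    def _effective_weight(self) -> np.ndarray:
        # (k, k, cin, cout) flipped spatially; used by the stride-1 conv
        return np.ascontiguousarray(self.w.data[::-1, ::-1, :, :])

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=F32)
        n, h, w, c = x.shape
        k, s, p = self.k, self.stride, self.pad
        hd, wd = (h - 1) * s + 1, (w - 1) * s + 1
        xd = np.zeros((n, hd, wd, c), dtype=F32)
        xd[:, ::s, ::s, :] = x
        q = k - 1 - p
        xp = _pad_hw(xd, q)
        oh, ow = hd + 2 * q - k + 1, wd + 2 * q - k + 1
        cols = _im2col(xp, k, 1, oh, ow)
        cout = self.w.data.shape[3]
        weff = self._effective_weight().reshape(-1, cout)
        out = cols @ weff + self.b.data
        self._cache = (cols, xp.shape, (n, oh, ow))
        return out.reshape(n, oh, ow, cout)

    def backward(self, dout):
        cols, padded_shape, (n, oh, ow) = self._cache
        cout = self.w.data.shape[3]
        dmat = dout.reshape(-1, cout)
        dweff = (cols.T @ dmat).reshape(self.k, self.k, -1, cout)
        self.w.grad += dweff[::-1, ::-1, :, :]
        self.b.grad += dmat.sum(axis=0)
        weff = self._effective_weight().reshape(-1, cout)
        dcols = dmat @ weff.T
        dxp = _col2im(dcols, padded_shape, self.k, 1, oh, ow)
        q = self.k - 1 - self.pad
        dxd = dxp[:, q : dxp.shape[1] - q, q : dxp.shape[2] - q, :] if q else dxp
        return np.ascontiguousarray(dxd[:, :: self.stride, :: self.stride, :])


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def forward(self, x, train: bool = True):
        x = np.asarray(x, dtype=F32)
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            if not _BN_STATS_FROZEN:
                self.running_mean = (
                    self.momentum * self.running_mean + (1 - self.momentum) * mean
                )
                self.running_var = (
                    self.momentum * self.running_var + (1 - self.momentum) * var
                )
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(F32)
        xhat = (x - mean) * invstd
        self._cache = (xhat, invstd, train)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dout):
        xhat, invstd, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += dout.sum(axis=(0, 1, 2))
        if not train:
            return dout * self.gamma.data * invstd
        n = dout.shape[0] * dout.shape[1] * dout.shape[2]
        dxhat = dout * self.gamma.data
        sum_dxhat = dxhat.sum(axis=(0, 1, 2))
        sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 1, 2))
        return (invstd / n) * (n * dxhat - sum_dxhat - xhat * sum_dxhat_xhat)


class Dense(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / din)
        self.w = Param(rng.normal(0.0, std, size=(din, dout)))
        self.b = Param(np.zeros(dout))
        self._cache = None

    def forward(self, x, train: bool = True):
        x = np.asarray(x, dtype=F32)
        self._cache = x
        return x @ self.w.data + self.b.data

    def backward(self, dout):
        x = self._cache
        self.w.grad += x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data.T


class ReLU(Module):
    def forward(self, x, train: bool = True):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(F32)

    def backward(self, dout):
        return dout * self._mask


class Tanh(Module):
    def forward(self, x, train: bool = True):
        self._out = np.tanh(x).astype(F32)
        return self._out

    def backward(self, dout):
        return dout * (1.0 - self._out**2)


class Reshape(Module):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape

    def forward(self, x, train: bool = True):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class GlobalAvgPool(Module):
    def forward(self, x, train: bool = True):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :], self._in_shape) / (h * w)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock(Module):
    """Two 3x3 conv/BN stages with identity (or 1x1-projected) skip."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.bn1 = BatchNorm2d(cout)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.bn2 = BatchNorm2d(cout)
        self.project = stride != 1 or cin != cout
        if self.project:
            self.conv_skip = Conv2d(cin, cout, 1, stride, 0, rng)
            self.bn_skip = BatchNorm2d(cout)
        self.relu_out = ReLU()

    def forward(self, x, train: bool = True):
        h = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train), train)
        h = self.bn2.forward(self.conv2.forward(h, train), train)
        skip = (
            self.bn_skip.forward(self.conv_skip.forward(x, train), train)
            if self.project
            else x
        )
        return self.relu_out.forward(h + skip, train)

    def backward(self, dout):
        dsum = self.relu_out.backward(dout)
        dh = self.conv2.backward(self.bn2.backward(dsum))
        dh = self.conv1.backward(self.bn1.backward(self.relu1.backward(dh)))
        if self.project:
            dskip = self.conv_skip.backward(self.bn_skip.backward(dsum))
        else:
            dskip = dsum
        return dh + dskip


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the GAN-standard defaults (lr 2e-4, betas 0.5/0.999)."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 2e-4,
        betas: tuple[float, float] = (0.5, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def iter_modules(obj) -> list[Module]:
    """All Module instances reachable from ``obj``'s attributes (depth-first)."""
    found: list[Module] = []
    stack = [obj]
    while stack:
        m = stack.pop()
        if isinstance(m, Module):
            found.append(m)
        for v in vars(m).values():
            if isinstance(v, Module):
                stack.append(v)
            elif isinstance(v, (list, tuple)):
                stack.extend(item for item in v if isinstance(item, Module))
    return found


def get_state(obj) -> list[np.ndarray]:
    """Snapshot all parameters and batch-norm running statistics."""
    state: list[np.ndarray] = []
    for m in iter_modules(obj):
        for v in vars(m).values():
            if isinstance(v, Param):
                state.append(v.data.copy())
        if isinstance(m, BatchNorm2d):
            state.append(m.running_mean.copy())
            state.append(m.running_var.copy())
    return state


def set_state(obj, state: list[np.ndarray]) -> None:
    """Restore a snapshot taken by :func:`get_state`."""
    it = iter(state)
    for m in iter_modules(obj):
        for v in vars(m).values():
            if isinstance(v, Param):
                v.data[...] = next(it)
        if isinstance(m, BatchNorm2d):
            m.running_mean = next(it).copy()
            m.running_var = next(it).copy()
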