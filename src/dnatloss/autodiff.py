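"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operator set the segmentation stack needs:
broadcasting arithmetic, matmul, pointwise nonlinearities, log-gamma,
2-D convolution, pooling, nearest ×2 upsampling, bilinear resizing and
channel concatenation.  Gradients are accumulated by a topological sweep
over the recorded graph, in the style of classic define-by-run autograd.

Dtypes are preserved end to end: the loss kernels are verified in
float64, while networks train in float32 to halve memory traffic on the
convolution stack (the dominant CPU cost).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import digamma, expit, gammaln


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if not np.issubdtype(data.dtype, np.floating):
            data = data.astype(np.float64)
        self.data = data
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # -- graph traversal -----------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def _accum(self, grad):
        # keep each subgraph's gradients in its own dtype (a float32 network
        # under a float64 loss must not silently upcast its backward pass)
        grad = _unbroadcast(grad, self.data.shape).astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / other.data**2)

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ g)

        out._backward = bwd
        return out

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape))

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(
            g.reshape(self.data.shape)
        )
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise functions -----------------------------------------------------

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.exp(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g / x.data)
    return out


def log1p(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.log1p(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g / (1.0 + x.data))
    return out


def sqrt(x: Tensor) -> Tensor:
    return as_tensor(x) ** 0.5


def abs_(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.abs(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * np.sign(x.data))
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = expit(x.data)
    out = Tensor(s, parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    # log(1+e^x) computed stably for both tails
    out = Tensor(np.logaddexp(0.0, x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * expit(x.data))
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is passed through inside [lo, hi] and zero outside."""
    x = as_tensor(x)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))
    mask = (x.data >= lo) & (x.data <= hi)
    out._backward = lambda g: x.requires_grad and x._accum(g * mask)
    return out


def loggamma(x: Tensor) -> Tensor:
    """ln Γ(x) for x > 0, with d/dx = ψ(x) (digamma)."""
    x = as_tensor(x)
    out = Tensor(gammaln(x.data), parents=(x,))
    out._backward = lambda g: x.requires_grad and x._accum(g * digamma(x.data))
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        start = 0
        for t, n in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + n)
            if t.requires_grad:
                t._accum(g[tuple(sl)])
            start += n

    out._backward = bwd
    return out


# -- convolution and pooling -------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh, kw, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d6 = dcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    x, weight = as_tensor(x), as_tensor(weight)
    o, cin, kh, kw = weight.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(o, -1)
    out_data = np.matmul(wmat, cols).reshape(x.shape[0], o, ho, wo)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, o, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, parents=parents)

    def bwd(g):
        gmat = g.reshape(x.shape[0], o, ho * wo)
        if weight.requires_grad:
            dw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(weight.shape)
            weight._accum(dw)
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, gmat)
            x._accum(_col2im(dcols, x.data.shape, kh, kw, stride, padding, ho, wo))

    out._backward = bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 2, stride: int = 2, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    s0, s1, s2, s3 = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, ho, wo, kernel, kernel),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3), writeable=False)
    flat = win.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        ni, ci, oi, oj = np.indices(arg.shape)
        np.add.at(dxp, (ni, ci, oi * stride + ki, oj * stride + kj), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accum(dxp)

    out._backward = bwd
    return out


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = Tensor(x.data.repeat(2, axis=-2).repeat(2, axis=-1), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    out._backward = bwd
    return out


def global_mean_pool(x: Tensor) -> Tensor:
    """Adaptive average pooling to 1×1: mean over the spatial axes, NCHW → NC."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out = Tensor(x.data.mean(axis=(2, 3)), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape))

    out._backward = bwd
    return out


# -- bilinear resizing -------------------------------------------------------

@lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1-D linear interpolation matrix with pixel-center alignment."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    scale = n_in / n_out
    for i in range(n_out):
        src = min(max((i + 0.5) * scale - 0.5, 0.0), n_in - 1.0)
        i0 = int(np.floor(src))
        i1 = min(i0 + 1, n_in - 1)
        frac = src - i0
        a[i, i0] += 1.0 - frac
        a[i, i1] += frac
    return a


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of the trailing two axes (pixel-center convention)."""
    x = as_tensor(x)
    h, w = x.shape[-2:]
    if (h, w) == (out_h, out_w):
        # identity scale must be bit-exact
        out = Tensor(x.data.copy(), parents=(x,))
        out._backward = lambda g: x.requires_grad and x._accum(g)
        return out
    ar = _interp_matrix(h, out_h).astype(x.data.dtype, copy=False)
    ac = _interp_matrix(w, out_w).astype(x.data.dtype, copy=False)
    out = Tensor(np.matmul(np.matmul(ar, x.data), ac.T), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.matmul(np.matmul(ar.T, g), ac))

    out._backward = bwd
    return out


def nearest_resize(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Nearest-neighbour resize of a plain array (labels; no gradient)."""
    h, w = arr.shape[-2:]
    rows = np.minimum(((np.arange(out_h) + 0.5) * h / out_h).astype(int), h - 1)
    cols = np.minimum(((np.arange(out_w) + 0.5) * w / out_w).astype(int), w - 1)
    return arr[..., rows[:, None], cols[None, :]]
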