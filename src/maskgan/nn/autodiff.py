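"""Minimal reverse-mode autodiff over numpy arrays.

Just enough machinery to train the conditional-GAN networks in this package
on a CPU: broadcast-aware elementwise ops, matmul, reductions, 2D
convolution (with stride / padding / dilation), transposed convolution, and
the usual activations.  Tensors are float32 by default; the tape is built
dynamically and traversed iteratively, so deep networks do not hit the
recursion limit.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

Array = np.ndarray
DTYPE = np.float32


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[Array] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[Array], None]] = None
        self._parents: Tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # ---- autodiff ----------------------------------------------------
    def backward(self, grad: Optional[Array] = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- operators ---------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return mul_scalar(self, -1.0)

    def __sub__(self, other):
        return add(self, -_wrap(other))

    def __rsub__(self, other):
        return add(-self, _wrap(other))

    def __mul__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, float(other))
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if np.isscalar(other):
            return mul_scalar(self, 1.0 / float(other))
        return div(self, _wrap(other))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: Array):
    if not (t.requires_grad or t._parents):
        return
    g = np.asarray(g, dtype=DTYPE)
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def _unbroadcast(grad: Array, shape: Tuple[int, ...]) -> Array:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _make(data: Array, parents: Sequence[Tensor],
          backward: Optional[Callable[[Array], None]]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---- elementwise ------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))
    return _make(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))
    return _make(a.data * b.data, (a, b), bw)


def div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, _unbroadcast(g / b.data, a.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))
    return _make(a.data / b.data, (a, b), bw)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    def bw(g):
        _accumulate(a, g * s)
    return _make(a.data * s, (a,), bw)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    def bw(g):
        _accumulate(a, g * mask)
    return _make(a.data * mask, (a,), bw)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    x = a.data
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(DTYPE)
    def bw(g):
        _accumulate(a, g * out * (1.0 - out))
    return _make(out, (a,), bw)


def exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    def bw(g):
        _accumulate(a, g * out)
    return _make(out, (a,), bw)


def log(a: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, g / a.data)
    return _make(np.log(a.data), (a,), bw)


def sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    def bw(g):
        _accumulate(a, g * 0.5 / out)
    return _make(out, (a,), bw)


def absolute(a: Tensor) -> Tensor:
    sign = np.sign(a.data)
    def bw(g):
        _accumulate(a, g * sign)
    return _make(np.abs(a.data), (a,), bw)


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the interval."""
    inside = (a.data >= lo) & (a.data <= hi)
    def bw(g):
        _accumulate(a, g * inside)
    return _make(np.clip(a.data, lo, hi), (a,), bw)


# ---- reductions and shape ---------------------------------------------

def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(g):
        if axis is None:
            _accumulate(a, np.broadcast_to(g, a.shape))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, np.broadcast_to(g, a.shape))
    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul_scalar(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    def bw(g):
        _accumulate(a, g.reshape(old))
    return _make(a.data.reshape(shape), (a,), bw)


def transpose(a: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)
    def bw(g):
        _accumulate(a, g.transpose(inv))
    return _make(a.data.transpose(axes), (a,), bw)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accumulate(t, piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def softmax_cols(a: Tensor) -> Tensor:
    """Column-wise softmax of a 2D tensor (normalizes over axis 0).

    Stabilized by subtracting the per-column maximum (a constant with zero
    gradient contribution, by shift invariance).
    """
    shift = Tensor(a.data.max(axis=0, keepdims=True))
    e = exp(a - shift)
    return div(e, tsum(e, axis=0, keepdims=True))


# ---- convolution -------------------------------------------------------

class ConvGeom:
    """Spatial geometry of a 2D convolution and its index caches."""

    def __init__(self, in_shape: Tuple[int, int, int], kernel: int,
                 stride: int, padding: int, dilation: int = 1):
        c, h, w = in_shape
        self.c, self.h, self.w = c, h, w
        self.kernel, self.stride, self.padding, self.dilation = (
            kernel, stride, padding, dilation)
        eff = dilation * (kernel - 1) + 1
        self.h_out = (h + 2 * padding - eff) // stride + 1
        self.w_out = (w + 2 * padding - eff) // stride + 1
        if self.h_out < 1 or self.w_out < 1:
            raise ValueError("convolution output would be empty")
        self.hp, self.wp = h + 2 * padding, w + 2 * padding
        self._flat_idx: Optional[Array] = None

    # im2col via a strided view: no giant index arrays on the forward path.
    def im2col(self, x: Array) -> Array:
        n = x.shape[0]
        k, s, d = self.kernel, self.stride, self.dilation
        if self.padding:
            p = self.padding
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        sn, sc, sh, sw = x.strides
        view = np.lib.stride_tricks.as_strided(
            x,
            shape=(n, self.c, self.h_out, self.w_out, k, k),
            strides=(sn, sc, s * sh, s * sw, d * sh, d * sw),
            writeable=False,
        )
        # (n, c*k*k, h_out*w_out)
        return np.ascontiguousarray(view.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, self.c * k * k, self.h_out * self.w_out)

    def flat_idx(self) -> Array:
        """Flat scatter indices of each column entry into the padded image."""
        if self._flat_idx is None:
            k, s, d = self.kernel, self.stride, self.dilation
            ch = np.repeat(np.arange(self.c), k * k)[:, None]
            di = d * np.tile(np.repeat(np.arange(k), k), self.c)[:, None]
            dj = d * np.tile(np.tile(np.arange(k), k), self.c)[:, None]
            bi = s * np.repeat(np.arange(self.h_out), self.w_out)[None, :]
            bj = s * np.tile(np.arange(self.w_out), self.h_out)[None, :]
            self._flat_idx = ((ch * self.hp + di + bi) * self.wp + dj + bj).ravel()
        return self._flat_idx

    def col2im(self, cols: Array) -> Array:
        """Scatter-add columns back to images (inverse of im2col's gather)."""
        n = cols.shape[0]
        idx = self.flat_idx()
        size = self.c * self.hp * self.wp
        out = np.empty((n, self.c, self.hp, self.wp), dtype=DTYPE)
        for i in range(n):
            out[i] = np.bincount(idx, weights=cols[i].ravel(),
                                 minlength=size).reshape(self.c, self.hp, self.wp)
        p = self.padding
        if p:
            out = out[:, :, p:-p, p:-p]
        return np.ascontiguousarray(out)


_GEOM_CACHE: Dict[Tuple, ConvGeom] = {}


def _geom(in_shape, kernel, stride, padding, dilation) -> ConvGeom:
    key = (in_shape, kernel, stride, padding, dilation)
    g = _GEOM_CACHE.get(key)
    if g is None:
        if len(_GEOM_CACHE) > 64:  # keep canonical-size index caches bounded
            _GEOM_CACHE.clear()
        g = _GEOM_CACHE[key] = ConvGeom(in_shape, kernel, stride, padding, dilation)
    return g


def conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2D convolution; x (N,C,H,W), weight (C_out, C_in, k, k)."""
    n, c, h, w = x.shape
    c_out, c_in, k, _ = weight.shape
    if c_in != c:
        raise ValueError(f"channel mismatch: input {c}, weight expects {c_in}")
    geom = _geom((c, h, w), k, stride, padding, dilation)
    cols = geom.im2col(x.data)                       # (n, c*k*k, L)
    wmat = weight.data.reshape(c_out, c_in * k * k)  # (c_out, c*k*k)
    out = np.matmul(wmat, cols)                      # (n, c_out, L)
    out = out.reshape(n, c_out, geom.h_out, geom.w_out)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.reshape(n, c_out, -1)
        if weight.requires_grad or weight._parents:
            dw = np.einsum("nol,ncl->oc", gmat, cols, optimize=True)
            _accumulate(weight, dw.reshape(weight.shape))
        if bias is not None:
            _accumulate(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dcols = np.matmul(wmat.T, gmat)          # (n, c*k*k, L)
            _accumulate(x, geom.col2im(dcols))

    return _make(out.astype(DTYPE, copy=False), parents, bw)


def conv_transpose2d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
                     stride: int = 2, padding: int = 1) -> Tensor:
    """Transposed 2D convolution; x (N,C_in,H,W), weight (C_in, C_out, k, k).

    Output side = (H - 1) * stride - 2 * padding + k.  Implemented as the
    adjoint of :func:`conv2d`'s input path (col2im scatter), so a stride-2
    kernel-4 block exactly doubles the side — and reproduces the chessboard
    artifact transposed convolutions are known for early in GAN training.
    """
    n, c_in, h, w = x.shape
    c_in_w, c_out, k, _ = weight.shape
    if c_in_w != c_in:
        raise ValueError(f"channel mismatch: input {c_in}, weight expects {c_in_w}")
    h_out = (h - 1) * stride - 2 * padding + k
    w_out = (w - 1) * stride - 2 * padding + k
    geom = _geom((c_out, h_out, w_out), k, stride, padding, 1)
    if (geom.h_out, geom.w_out) != (h, w):
        raise ValueError("inconsistent transposed-convolution geometry")
    wmat = weight.data.reshape(c_in, c_out * k * k)
    xmat = x.data.reshape(n, c_in, -1)               # (n, c_in, L), L = h*w
    cols = np.matmul(wmat.T, xmat)                   # (n, c_out*k*k, L)
    out = geom.col2im(cols)                          # (n, c_out, h_out, w_out)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gcols = geom.im2col(g)                       # (n, c_out*k*k, L)
        if weight.requires_grad or weight._parents:
            dw = np.einsum("nkl,ncl->ck", gcols, xmat, optimize=True)
            _accumulate(weight, dw.reshape(weight.shape))
        if bias is not None:
            _accumulate(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            dx = np.matmul(wmat, gcols)              # (n, c_in, L)
            _accumulate(x, dx.reshape(x.shape))

    return _make(out, parents, bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        _accumulate(a, np.matmul(g, np.swapaxes(b.data, -1, -2)))
        _accumulate(b, np.matmul(np.swapaxes(a.data, -1, -2), g))
    return _make(np.matmul(a.data, b.data), (a, b), bw)
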