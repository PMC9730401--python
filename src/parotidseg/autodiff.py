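"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network needs: elementwise
arithmetic with broadcasting, ReLU/sigmoid, reductions, reshape/concat, 3x3 and
1x1 convolution (im2col), 2x2 max pooling and bilinear resampling. Gradients
are accumulated by topological traversal of the recorded tape; `no_grad`
disables taping for inference.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None):
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in zip(t._parents, t._backward(g)):
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- operators --------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        if isinstance(other, (int, float, bool)):
            return add(self, -other)
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return mul(self, pow_(other, -1.0))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __pow__(self, exponent):
        return pow_(self, exponent)

    def __neg__(self):
        return mul(self, -1.0)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if like is not None and isinstance(x, (int, float, bool)):
        # keep python scalars in the companion dtype: a 0-d float64 array would
        # silently promote every float32 activation under NumPy 2 casting rules
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(
        p.requires_grad or p._parents for p in parents
    ):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise ----------------------------------------------------------


def add(a, b) -> Tensor:
    if not isinstance(a, Tensor) and isinstance(b, Tensor):
        a, b = b, a
    a = as_tensor(a)
    b = as_tensor(b, like=a)
    data = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    if not isinstance(a, Tensor) and isinstance(b, Tensor):
        a, b = b, a
    a = as_tensor(a)
    b = as_tensor(b, like=a)
    data = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        )

    return _make(data, (a, b), backward)


def pow_(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        return (g * exponent * a.data ** (exponent - 1.0),)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    data = np.maximum(a.data, 0)

    def backward(g):
        return (g * (a.data > 0),)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    data = np.empty_like(a.data)
    pos = a.data >= 0
    data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    data[~pos] = ex / (1.0 + ex)

    def backward(g):
        return (g * data * (1.0 - data),)

    return _make(data, (a,), backward)


# -- reductions / shape ---------------------------------------------------


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).astype(a.data.dtype, copy=False),)

    return _make(data, (a,), backward)


def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        return (g.reshape(a.shape),)

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        return (g.transpose(inv),)

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(data, tuple(tensors), backward)


# -- convolution ----------------------------------------------------------

# Row-strip size for im2col during inference keeps the unfolded buffer small
# even on 512x512 feature maps.
_COL_BUDGET = 32 * 1024 * 1024  # elements


def _im2col(xp: np.ndarray, kh: int, kw: int, out_h: int, out_w: int) -> np.ndarray:
    """(N, C, Hp, Wp) padded input -> (N, C*kh*kw, out_h*out_w) patch matrix."""
    N, C = xp.shape[:2]
    cols = np.empty((N, C, kh, kw, out_h, out_w), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + out_h, j : j + out_w]
    return cols.reshape(N, C * kh * kw, out_h * out_w)


def _col2im(dcols: np.ndarray, shape_padded, kh: int, kw: int, out_h: int, out_w: int):
    """Adjoint of `_im2col`: fold (N, C*kh*kw, out_h*out_w) back to padded grid."""
    N, C = shape_padded[:2]
    dxp = np.zeros(shape_padded, dtype=dcols.dtype)
    dcols = dcols.reshape(N, C, kh, kw, out_h, out_w)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + out_h, j : j + out_w] += dcols[:, :, i, j]
    return dxp


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """1x1 convolution as one channel-mixing matmul (no patch extraction)."""
    N, C, H, W = x.shape
    F = weight.shape[0]
    wmat = weight.data.reshape(F, C)
    xmat = x.data.reshape(N, C, H * W)
    out = np.matmul(wmat, xmat).reshape(N, F, H, W)
    out += bias.data.reshape(1, F, 1, 1)

    def backward(g):
        gn = g.reshape(N, F, H * W)
        db = g.sum(axis=(0, 2, 3))
        dw = np.tensordot(gn, xmat, axes=([0, 2], [0, 2])).reshape(weight.shape)
        dx = np.matmul(wmat.T, gn).reshape(N, C, H, W)
        return dx, dw, db

    return _make(out, (x, weight, bias), backward)


def conv2d(x, weight, bias, padding: int | None = None) -> Tensor:
    """Stride-1 2D convolution: (N,C,H,W) * (F,C,kh,kw) -> (N,F,H,W).

    Padding defaults to `k // 2` so 3x3 and 1x1 kernels preserve shape.
    """
    x, weight, bias = as_tensor(x), as_tensor(weight), as_tensor(bias)
    N, C, H, W = x.shape
    F, Cw, kh, kw = weight.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    if kh == 1 and kw == 1 and not padding:
        return _conv1x1(x, weight, bias)
    if padding is None:
        padding = kh // 2
    out_h, out_w = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
    wmat = weight.data.reshape(F, C * kh * kw)
    xp = (
        np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        if padding
        else x.data
    )
    tape = _GRAD_ENABLED and (
        x.requires_grad or x._parents or weight.requires_grad or bias.requires_grad
    )
    if tape:
        cols = _im2col(xp, kh, kw, out_h, out_w)
        out = np.matmul(wmat, cols).reshape(N, F, out_h, out_w)
    else:
        # strip over rows to bound the unfolded buffer on large feature maps
        out = np.empty((N, F, out_h, out_w), dtype=x.data.dtype)
        strip = max(1, int(_COL_BUDGET // max(1, N * C * kh * kw * out_w)))
        for r0 in range(0, out_h, strip):
            r1 = min(r0 + strip, out_h)
            part = _im2col(xp[:, :, r0 : r1 + kh - 1, :], kh, kw, r1 - r0, out_w)
            out[:, :, r0:r1, :] = np.matmul(wmat, part).reshape(N, F, r1 - r0, out_w)
    out += bias.data.reshape(1, F, 1, 1)

    def backward(g):
        gn = g.reshape(N, F, out_h * out_w)
        db = g.sum(axis=(0, 2, 3))
        dw = np.tensordot(gn, cols, axes=([0, 2], [0, 2]))
        dxp = _col2im(np.matmul(wmat.T, gn), xp.shape, kh, kw, out_h, out_w)
        dx = (
            dxp[:, :, padding : padding + H, padding : padding + W]
            if padding
            else dxp
        )
        return dx, dw.reshape(weight.shape), db

    return _make(out, (x, weight, bias), backward)


# -- pooling / resampling -------------------------------------------------


def max_pool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2 on (N,C,H,W); H and W must be even."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    win = x.data.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(N, C, H // 2, W // 2, 4)
    idx = win.argmax(axis=-1)
    data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros((N, C, H // 2, W // 2, 4), dtype=g.dtype)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = (
            dwin.reshape(N, C, H // 2, W // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(N, C, H, W)
        )
        return (dx,)

    return _make(data, (x,), backward)


def _linear_coeffs(n_in: int, n_out: int):
    """Bilinear sampling indices/weights, half-pixel-center convention."""
    coord = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    coord = np.clip(coord, 0, n_in - 1)
    i0 = np.floor(coord).astype(np.int64)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = (coord - i0).astype(np.float64)
    return i0, i1, w


def resize_bilinear(x, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (N,C,H,W) to (N,C,out_h,out_w)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    r0, r1, wr = _linear_coeffs(H, out_h)
    c0, c1, wc = _linear_coeffs(W, out_w)
    wr_ = wr.astype(x.data.dtype)[None, None, :, None]
    wc_ = wc.astype(x.data.dtype)[None, None, None, :]
    top = x.data[:, :, r0, :] * (1 - wr_) + x.data[:, :, r1, :] * wr_
    data = top[:, :, :, c0] * (1 - wc_) + top[:, :, :, c1] * wc_

    def backward(g):
        dtop = np.zeros((N, C, out_h, W), dtype=g.dtype)
        np.add.at(dtop, (slice(None), slice(None), slice(None), c0), g * (1 - wc_))
        np.add.at(dtop, (slice(None), slice(None), slice(None), c1), g * wc_)
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), slice(None), r0), dtop * (1 - wr_))
        np.add.at(dx, (slice(None), slice(None), r1), dtop * wr_)
        return (dx,)

    return _make(data, (x,), backward)
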