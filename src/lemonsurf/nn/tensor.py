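"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the detector family are implemented:
2-D convolution (stride / padding / dilation), batch normalisation,
pooling, nearest upsampling, channel concat/slice, the usual pointwise
nonlinearities, and a handful of reductions and gather ops used by the
training losses.  Everything is float32.

Gradients flow through a tape of closures; ``Tensor.backward`` runs a
topological sweep.  ``no_grad()`` disables taping for inference.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _as_f32(x):
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """A numpy array plus (optionally) a node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads = {id(self): _as_f32(grad)}
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
                if id(parent) in grads:
                    grads[id(parent)] += pg
                else:
                    grads[id(parent)] = pg

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_wrap(other), self)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_tape(*ts):
    if not _grad_enabled:
        return False
    return any(isinstance(t, Tensor) and (t.requires_grad or t._parents or t._backward)
               for t in ts)


def _make(data, parents, backward):
    out = Tensor(data)
    if _needs_tape(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (reverse numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.astype(np.float32, copy=False)


# -- pointwise ------------------------------------------------------------

def add(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data + b.data

    def bwd(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(out, (a, b), bwd)


def mul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data * b.data

    def bwd(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _make(out, (a, b), bwd)


def div(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data / b.data

    def bwd(g):
        return (_unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out, (a, b), bwd)


def power(a, p: float):
    a = _wrap(a)
    out = a.data ** p

    def bwd(g):
        return (g * p * a.data ** (p - 1),)

    return _make(out, (a,), bwd)


def sqrt(a):
    a = _wrap(a)
    out = np.sqrt(a.data)

    def bwd(g):
        return (g * 0.5 / np.maximum(out, 1e-12),)

    return _make(out, (a,), bwd)


def exp(a):
    a = _wrap(a)
    out = np.exp(a.data)

    def bwd(g):
        return (g * out,)

    return _make(out, (a,), bwd)


def log(a):
    a = _wrap(a)
    out = np.log(a.data)

    def bwd(g):
        return (g / a.data,)

    return _make(out, (a,), bwd)


def sigmoid(a):
    a = _wrap(a)
    with np.errstate(over="ignore"):    # saturated logits -> exact 0/1
        out = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        return (g * out * (1.0 - out),)

    return _make(out, (a,), bwd)


def silu(a):
    a = _wrap(a)
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-a.data))
    out = a.data * s

    def bwd(g):
        return (g * (s * (1.0 + a.data * (1.0 - s))),)

    return _make(out, (a,), bwd)


def relu(a):
    a = _wrap(a)
    out = np.maximum(a.data, 0.0)

    def bwd(g):
        return (g * (a.data > 0),)

    return _make(out, (a,), bwd)


def atan(a):
    a = _wrap(a)
    out = np.arctan(a.data)

    def bwd(g):
        return (g / (1.0 + a.data * a.data),)

    return _make(out, (a,), bwd)


def minimum(a, b):
    a, b = _wrap(a), _wrap(b)
    out = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(np.float32)

    def bwd(g):
        return (_unbroadcast(g * mask, a.data.shape),
                _unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(out, (a, b), bwd)


def maximum(a, b):
    a, b = _wrap(a), _wrap(b)
    out = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(np.float32)

    def bwd(g):
        return (_unbroadcast(g * mask, a.data.shape),
                _unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(out, (a, b), bwd)


def clamp_min(a, lo: float):
    a = _wrap(a)
    out = np.maximum(a.data, lo)

    def bwd(g):
        return (g * (a.data >= lo),)

    return _make(out, (a,), bwd)


# -- shape ops ------------------------------------------------------------

def reshape(a, shape):
    a = _wrap(a)
    out = a.data.reshape(shape)

    def bwd(g):
        return (g.reshape(a.data.shape),)

    return _make(out, (a,), bwd)


def transpose(a, axes):
    a = _wrap(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def bwd(g):
        return (np.transpose(g, inv),)

    return _make(out, (a,), bwd)


def concat(tensors, axis=1):
    ts = [_wrap(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        return tuple(np.ascontiguousarray(p) for p in np.split(g, splits, axis=axis))

    return _make(out, tuple(ts), bwd)


def getitem(a, idx):
    a = _wrap(a)
    out = a.data[idx]

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _make(out, (a,), bwd)


def narrow_channels(a, start, stop):
    """Channel slice x[:, start:stop] with a cheap backward."""
    a = _wrap(a)
    out = a.data[:, start:stop]

    def bwd(g):
        ga = np.zeros_like(a.data)
        ga[:, start:stop] = g
        return (ga,)

    return _make(out, (a,), bwd)


def matmul(a, b):
    a, b = _wrap(a), _wrap(b)
    out = a.data @ b.data

    def bwd(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _make(out, (a, b), bwd)


# -- reductions -----------------------------------------------------------

def reduce_sum(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).astype(np.float32),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).astype(np.float32),)

    return _make(out, (a,), bwd)


def reduce_mean(a, axis=None, keepdims=False):
    a = _wrap(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[i] for i in ax]))

    def bwd(g):
        if axis is None:
            return (np.broadcast_to(g / n, a.data.shape).astype(np.float32),)
        if not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g / n, a.data.shape).astype(np.float32),)

    return _make(out, (a,), bwd)


def channel_max(a):
    """Max over the channel axis of an NCHW tensor -> [N,1,H,W]."""
    a = _wrap(a)
    idx = a.data.argmax(axis=1, keepdims=True)
    out = np.take_along_axis(a.data, idx, axis=1)

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, idx, g, axis=1)
        return (ga,)

    return _make(out, (a,), bwd)


def spatial_max(a):
    """Global max pool over H,W of an NCHW tensor -> [N,C,1,1]."""
    a = _wrap(a)
    n, c, h, w = a.data.shape
    flat = a.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=2)
    out = np.take_along_axis(flat, idx[..., None], axis=2).reshape(n, c, 1, 1)

    def bwd(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g.reshape(n, c, 1), axis=2)
        return (gf.reshape(a.data.shape),)

    return _make(out, (a,), bwd)


def softmax(a, axis=-1):
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        s = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - s),)

    return _make(out, (a,), bwd)


def log_softmax(a, axis=-1):
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def bwd(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return _make(out, (a,), bwd)


def select_col(a, j: int):
    """Column j of a 2-D tensor -> 1-D tensor."""
    a = _wrap(a)
    out = a.data[:, j]

    def bwd(g):
        ga = np.zeros_like(a.data)
        ga[:, j] = g
        return (ga,)

    return _make(out, (a,), bwd)


def stack_cols(ts):
    """Stack 1-D tensors into the columns of a 2-D tensor."""
    ts = [_wrap(t) for t in ts]
    out = np.stack([t.data for t in ts], axis=1)

    def bwd(g):
        return tuple(np.ascontiguousarray(g[:, i]) for i in range(len(ts)))

    return _make(out, tuple(ts), bwd)


def gather_rows(a, idx):
    """Select rows of a 2-D tensor; backward scatter-adds."""
    a = _wrap(a)
    idx = np.asarray(idx)
    out = a.data[idx]

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _make(out, (a,), bwd)


# -- convolution ----------------------------------------------------------

def _im2col(x, kh, kw, sh, sw, ph, pw, dh, dw):
    n, c, h, w = x.shape
    oh = (h + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    ow = (w + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if ph or pw:
        xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=x.dtype)
        xp[:, :, ph:ph + h, pw:pw + w] = x
    else:
        xp = x
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        hi = i * dh
        for j in range(kw):
            wj = j * dw
            cols[:, :, i, j] = xp[:, :, hi:hi + sh * oh:sh, wj:wj + sw * ow:sw]
    return cols.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(gcols, xshape, kh, kw, sh, sw, ph, pw, dh, dw, oh, ow):
    n, c, h, w = xshape
    gx = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=gcols.dtype)
    gcols = gcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        hi = i * dh
        for j in range(kw):
            wj = j * dw
            gx[:, :, hi:hi + sh * oh:sh, wj:wj + sw * ow:sw] += gcols[:, :, i, j]
    if ph or pw:
        gx = gx[:, :, ph:ph + h, pw:pw + w]
    return gx


def _tap_slices(h, w, sa, sb):
    """Index ranges for accumulating a (sa, sb)-shifted same-size map."""
    ya0, ya1 = max(0, -sa), min(h, h - sa)
    yb0, yb1 = max(0, -sb), min(w, w - sb)
    return (slice(ya0, ya1), slice(yb0, yb1),
            slice(ya0 + sa, ya1 + sa), slice(yb0 + sb, yb1 + sb))


def _conv_s1_forward(x, w, dil):
    """Stride-1 same-padding conv as k*k shifted 1x1 GEMMs (no im2col)."""
    n, c, h, wd = x.shape
    cout, cin, kh, kw = w.shape
    xf = x.reshape(n, c, h * wd)
    y = np.zeros((n, cout, h, wd), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            t = np.matmul(w[:, :, i, j][None], xf).reshape(n, cout, h, wd)
            sa, sb = (i - (kh - 1) // 2) * dil, (j - (kw - 1) // 2) * dil
            ra, rb, xa, xb = _tap_slices(h, wd, sa, sb)
            y[:, :, ra, rb] += t[:, :, xa, xb]
    return y


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """NCHW convolution.  w: [C_out, C_in, kh, kw]; b: [C_out] or None.

    1x1 convs are plain GEMMs; stride-1 k x k convs with same padding use a
    shift-accumulate scheme (one GEMM per kernel tap on the contiguous
    input); strided convs fall back to im2col + GEMM.
    """
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    s, p, d = int(stride), int(padding), int(dilation)
    cout, cin, kh, kw = w.data.shape
    n, _, h, wd = x.data.shape
    need_x_grad = _grad_enabled and (x.requires_grad or x._parents or x._backward)
    parents = (x, w) if b is None else (x, w, b)

    if kh == kw == 1 and s == 1 and p == 0:
        xf = x.data.reshape(n, cin, h * wd)
        wmat = w.data.reshape(cout, cin)
        y = np.matmul(wmat[None], xf)
        if b is not None:
            y += b.data.reshape(1, cout, 1)
        y = y.reshape(n, cout, h, wd)

        def bwd_1x1(g):
            gy = g.reshape(n, cout, h * wd)
            gw = np.einsum("nol,ncl->oc", gy, xf, optimize=True)
            gx = (np.matmul(wmat.T[None], gy).reshape(x.data.shape)
                  if need_x_grad else None)
            if b is None:
                return gx, gw.reshape(w.data.shape)
            return gx, gw.reshape(w.data.shape), gy.sum(axis=(0, 2))

        return _make(y, parents, bwd_1x1)

    if s == 1 and p == d * (kh - 1) // 2 and kh == kw:
        y = _conv_s1_forward(x.data, w.data, d)
        if b is not None:
            y += b.data.reshape(1, cout, 1, 1)

        def bwd_s1(g):
            gf = g.reshape(n, cout, h * wd)
            gw = np.empty_like(w.data)
            gx = np.zeros_like(x.data) if need_x_grad else None
            wdat = w.data
            for i in range(kh):
                for j in range(kw):
                    sa = (i - (kh - 1) // 2) * d
                    sb = (j - (kw - 1) // 2) * d
                    ra, rb, xa, xb = _tap_slices(h, wd, sa, sb)
                    gsub = g[:, :, ra, rb]
                    xsub = x.data[:, :, xa, xb]
                    gw[:, :, i, j] = np.einsum("noab,ncab->oc", gsub, xsub,
                                               optimize=True)
                    if need_x_grad:
                        t = np.matmul(wdat[:, :, i, j].T[None], gf)
                        gx[:, :, xa, xb] += t.reshape(n, cin, h, wd)[:, :, ra, rb]
            if b is None:
                return gx, gw
            return gx, gw, g.sum(axis=(0, 2, 3))

        return _make(y, parents, bwd_s1)

    cols, oh, ow = _im2col(x.data, kh, kw, s, s, p, p, d, d)
    wmat = w.data.reshape(cout, cin * kh * kw)
    y = np.matmul(wmat[None], cols)          # [N, Cout, OH*OW]
    if b is not None:
        y += b.data.reshape(1, cout, 1)
    y = y.reshape(n, cout, oh, ow)

    def bwd(g):
        gy = g.reshape(n, cout, oh * ow)
        gw = np.einsum("ncl,nkl->ck", gy, cols, optimize=True).reshape(w.data.shape)
        if need_x_grad:
            gcols = np.matmul(wmat.T[None], gy)
            gx = _col2im(gcols, x.data.shape, kh, kw, s, s, p, p, d, d, oh, ow)
        else:
            gx = None
        if b is None:
            return gx, gw
        return gx, gw, gy.sum(axis=(0, 2))

    return _make(y, parents, bwd)


def max_pool2d(x, kernel=5, stride=1, padding=2):
    x = _wrap(x)
    n, c, h, w = x.data.shape
    k = kernel
    xp = np.full((n, c, h + 2 * padding, w + 2 * padding), -np.inf, dtype=x.data.dtype)
    xp[:, :, padding:padding + h, padding:padding + w] = x.data
    oh = (h + 2 * padding - k) // stride + 1
    ow = (w + 2 * padding - k) // stride + 1
    stack = np.empty((n, c, k * k, oh, ow), dtype=x.data.dtype)
    t = 0
    for i in range(k):
        for j in range(k):
            stack[:, :, t] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
            t += 1
    idx = stack.argmax(axis=2)
    out = np.take_along_axis(stack, idx[:, :, None], axis=2)[:, :, 0]

    def bwd(g):
        gstack = np.zeros_like(stack)
        np.put_along_axis(gstack, idx[:, :, None], g[:, :, None], axis=2)
        gxp = np.zeros((n, c, h + 2 * padding, w + 2 * padding), dtype=g.dtype)
        t = 0
        for i in range(k):
            for j in range(k):
                gxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += gstack[:, :, t]
                t += 1
        return (gxp[:, :, padding:padding + h, padding:padding + w],)

    return _make(out, (x,), bwd)


def avg_pool2d(x, kernel=5, stride=1, padding=2):
    """Average pooling with zero padding (count includes padded cells)."""
    x = _wrap(x)
    n, c, h, w = x.data.shape
    k = kernel
    cols, oh, ow = _im2col(x.data.reshape(n * c, 1, h, w), k, k, stride, stride,
                           padding, padding, 1, 1)
    out = cols.mean(axis=1).reshape(n, c, oh, ow)

    def bwd(g):
        gy = (g.reshape(n * c, 1, oh * ow) / (k * k)).astype(np.float32)
        gcols = np.broadcast_to(gy, (n * c, k * k, oh * ow))
        gx = _col2im(gcols, (n * c, 1, h, w), k, k, stride, stride,
                     padding, padding, 1, 1, oh, ow)
        return (gx.reshape(n, c, h, w),)

    return _make(out, (x,), bwd)


def global_avg_pool(x):
    return reduce_mean(x, axis=(2, 3), keepdims=True)


def upsample2x(x):
    """Nearest-neighbour 2x upsampling."""
    x = _wrap(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bwd(g):
        return (g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)),)

    return _make(out, (x,), bwd)


# -- fused training ops ---------------------------------------------------

def batch_norm(x, gamma, beta, running_mean, running_var, training,
               momentum=0.03, eps=1e-3):
    """Batch normalisation over N,H,W per channel.

    running_mean / running_var are plain numpy arrays updated in place
    during training (they are buffers, not parameters).
    """
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    if training:
        axes = (0, 2, 3)
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        nelem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * m
        running_var *= (1 - momentum)
        running_var += momentum * v * (nelem / max(nelem - 1, 1))
        inv = 1.0 / np.sqrt(v + eps)
        xhat = (x.data - m.reshape(1, -1, 1, 1)) * inv.reshape(1, -1, 1, 1)
        out = gamma.data.reshape(1, -1, 1, 1) * xhat + beta.data.reshape(1, -1, 1, 1)

        def bwd(g):
            gg = (g * xhat).sum(axis=axes)
            gb = g.sum(axis=axes)
            gxh = g * gamma.data.reshape(1, -1, 1, 1)
            gx = (inv.reshape(1, -1, 1, 1) / nelem) * (
                nelem * gxh
                - gxh.sum(axis=axes, keepdims=True)
                - xhat * (gxh * xhat).sum(axis=axes, keepdims=True)
            )
            return gx.astype(np.float32), gg, gb

        return _make(out, (x, gamma, beta), bwd)

    inv = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv).reshape(1, -1, 1, 1)
    shift = (beta.data - gamma.data * running_mean * inv).reshape(1, -1, 1, 1)
    out = x.data * scale + shift
    xhat = None

    def bwd_eval(g):
        gg = (g * (x.data - running_mean.reshape(1, -1, 1, 1))
              * inv.reshape(1, -1, 1, 1)).sum(axis=(0, 2, 3))
        gb = g.sum(axis=(0, 2, 3))
        return g * scale, gg, gb

    return _make(out, (x, gamma, beta), bwd_eval)


def bce_with_logits(logits, targets, weight=None):
    """Numerically stable elementwise binary cross-entropy, summed.

    targets / weight are plain arrays (no gradient)."""
    logits = _wrap(logits)
    z, t = logits.data, np.asarray(targets, dtype=np.float32)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if weight is not None:
        loss = loss * weight
    out = loss.sum()

    def bwd(g):
        dz = 1.0 / (1.0 + np.exp(-z)) - t
        if weight is not None:
            dz = dz * weight
        return (g * dz,)

    return _make(out, (logits,), bwd)
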