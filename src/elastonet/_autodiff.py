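"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The unsupervised training objective used here (local normalized
cross-correlation of a warped RF frame, strain-gradient regularisation,
strain consistency) has to be differentiated with respect to convolutional
network weights. This module provides the small set of differentiable
operations the networks and losses need: broadcasting arithmetic,
activations, reductions, slicing, 2D convolution (im2col + BLAS matmul),
2x2 transpose convolution, 2x2 max pooling, bilinear resizing, bilinear
warping by a displacement field, and sliding-window box sums for local
moment computations.

Tensors wrap ``numpy.ndarray`` data of any float dtype; gradients are
accumulated in the same dtype. The graph is built eagerly on every forward
pass and freed after ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "sigmoid",
    "tanh",
    "leaky_relu",
    "maximum",
    "sqrt",
    "absolute",
    "conv2d",
    "conv_transpose2x2",
    "maxpool2x2",
    "resize_bilinear",
    "warp_bilinear",
    "boxsum",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (gs, ss) in enumerate(zip(grad.shape, shape)):
        if ss == 1 and gs != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_prev", "_bwd")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _bwd=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _prev
        )
        self._prev = tuple(_prev)
        self._bwd = _bwd

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data.item())

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)
            # free graph references early
            node._bwd = None
            node._prev = ()

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.shape)
                )

        out._bwd = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        out._bwd = bwd
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._bwd = bwd
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._bwd = bwd
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        out._bwd = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._bwd = bwd
    return out


# ------------------------------------------------------------------ pointwise
def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * y * (1.0 - y))

    out._bwd = bwd
    return out


def tanh(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.tanh(x.data)
    out = Tensor(y, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (1.0 - y * y))

    out._bwd = bwd
    return out


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    x = as_tensor(x)
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, slope * x.data), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.where(pos, g, slope * g))

    out._bwd = bwd
    return out


def maximum(x: Tensor, c: float) -> Tensor:
    """Elementwise max with a scalar (gradient passes where x > c)."""
    x = as_tensor(x)
    mask = x.data > c
    out = Tensor(np.where(mask, x.data, c), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.where(mask, g, 0.0))

    out._bwd = bwd
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.sqrt(x.data)
    out = Tensor(y, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * 0.5 / np.maximum(y, np.finfo(y.dtype).tiny))

    out._bwd = bwd
    return out


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sign(x.data)
    out = Tensor(np.abs(x.data), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * s)

    out._bwd = bwd
    return out


# -------------------------------------------------------------- convolutions
def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*H*W, C*kh*kw) patch matrix, H = Hp-kh+1."""
    n, c, hp, wp = xp.shape
    h, w = hp - kh + 1, wp - kw + 1
    cols = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # N,C,H,W,kh,kw
    cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


def _conv2d_fwd(x: np.ndarray, w: np.ndarray, b, return_cols: bool = False):
    f, c, kh, kw = w.shape
    ph, pw = kh // 2, kw // 2
    n, _, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)
    out = cols @ w.reshape(f, -1).T
    out = out.reshape(n, h, wd, f).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.reshape(1, f, 1, 1)
    out = np.ascontiguousarray(out)
    return (out, cols) if return_cols else out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 2D convolution (cross-correlation).

    x: (N, C, H, W); w: (F, C, kh, kw) with odd kernel; b: (F,) or None.
    The forward patch matrix is kept alive while the graph exists and
    reused for the weight gradient.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    f, c, kh, kw = w.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("conv2d requires odd kernel sizes")
    prev = (x, w) if b is None else (x, w, b)
    keep_cols = w.requires_grad
    if keep_cols:
        y, cols = _conv2d_fwd(x.data, w.data,
                              None if b is None else b.data, True)
    else:
        y = _conv2d_fwd(x.data, w.data, None if b is None else b.data)
        cols = None
    out = Tensor(y, _prev=prev)

    def bwd(g):
        n, _, h, wd = x.shape
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            g2 = g.transpose(0, 2, 3, 1).reshape(n * h * wd, f)
            dw = g2.T @ cols
            w._accumulate(dw.reshape(w.shape))
        if x.requires_grad:
            wf = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            x._accumulate(_conv2d_fwd(g, np.ascontiguousarray(wf), None))

    out._bwd = bwd
    return out


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-2, kernel-2 transpose convolution: (N,C,H,W) -> (N,F,2H,2W).

    w: (C, F, 2, 2).
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n, c, h, wd = x.shape
    _, f, _, _ = w.shape
    tmp = np.tensordot(x.data, w.data, axes=([1], [0]))  # N,H,W,F,2,2
    y = tmp.transpose(0, 3, 1, 4, 2, 5).reshape(n, f, 2 * h, 2 * wd)
    if b is not None:
        y = y + b.data.reshape(1, f, 1, 1)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(y), _prev=prev)

    def bwd(g):
        g6 = g.reshape(n, f, h, 2, wd, 2).transpose(0, 2, 4, 1, 3, 5)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.tensordot(g6, w.data, axes=([3, 4, 5], [1, 2, 3]))
            x._accumulate(np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            dw = np.tensordot(x.data, g6, axes=([0, 2, 3], [0, 1, 2]))
            w._accumulate(dw)

    out._bwd = bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    xf = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = xf.argmax(axis=-1)
    y = np.take_along_axis(xf, idx[..., None], axis=-1)[..., 0]
    out = Tensor(np.ascontiguousarray(y), _prev=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gf = np.zeros_like(xf)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.ascontiguousarray(gx.reshape(n, c, h, w)))

    out._bwd = bwd
    return out


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Dense 1D bilinear interpolation matrix.

    Half-pixel-centre sampling (the "align_corners=False" convention)
    with edge clamping: integer-factor resizing is then translation
    covariant, which the decoder's 2x feature upsampling relies on.
    A same-size resize is the identity.
    """
    a = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 2)
    t = src - i0
    a[np.arange(n_out), i0] += 1.0 - t
    a[np.arange(n_out), i0 + 1] += t
    return a


def resize_bilinear(x: Tensor, out_shape: tuple[int, int]) -> Tensor:
    """Bilinear resize of the trailing two axes of (..., H, W)."""
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    h2, w2 = out_shape
    a = _interp_matrix(h2, h, x.dtype)
    bmat = _interp_matrix(w2, w, x.dtype)
    y = np.matmul(np.matmul(a, x.data), bmat.T)
    out = Tensor(y, _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(np.matmul(np.matmul(a.T, g), bmat))

    out._bwd = bwd
    return out


# ------------------------------------------------------------------- warping
def _warp_coords(shape, disp_ax: np.ndarray, disp_lat: np.ndarray):
    h, w = shape
    yy, xx = np.meshgrid(np.arange(h, dtype=disp_ax.dtype),
                         np.arange(w, dtype=disp_ax.dtype), indexing="ij")
    iy = yy + disp_ax
    ix = xx + disp_lat
    valid = (iy >= 0) & (iy <= h - 1) & (ix >= 0) & (ix <= w - 1)
    iyc = np.clip(iy, 0, h - 1)
    ixc = np.clip(ix, 0, w - 1)
    y0 = np.clip(np.floor(iyc).astype(int), 0, h - 2)
    x0 = np.clip(np.floor(ixc).astype(int), 0, w - 2)
    ty = iyc - y0
    tx = ixc - x0
    return valid, y0, x0, ty, tx, (iy >= 0) & (iy <= h - 1), (ix >= 0) & (ix <= w - 1)


def warp_bilinear(image: Tensor, disp_ax: Tensor, disp_lat: Tensor):
    """Backward-map a 2D image: out(p) = image(p + d(p)), bilinear, clamped.

    Returns ``(warped, valid)`` where ``valid`` is a plain boolean array
    marking pixels whose sampling location fell inside the grid.
    Differentiable w.r.t. the image and both displacement channels.
    """
    image, disp_ax, disp_lat = map(as_tensor, (image, disp_ax, disp_lat))
    if image.ndim != 2:
        raise ValueError("warp_bilinear expects a 2D image")
    if disp_ax.shape != image.shape or disp_lat.shape != image.shape:
        raise ValueError("displacement shape must match image shape")
    h, w = image.shape
    valid, y0, x0, ty, tx, vy, vx = _warp_coords(
        (h, w), disp_ax.data, disp_lat.data)
    im = image.data
    i00 = im[y0, x0]
    i01 = im[y0, x0 + 1]
    i10 = im[y0 + 1, x0]
    i11 = im[y0 + 1, x0 + 1]
    top = i00 * (1 - tx) + i01 * tx
    bot = i10 * (1 - tx) + i11 * tx
    y = top * (1 - ty) + bot * ty
    out = Tensor(y, _prev=(image, disp_ax, disp_lat))

    def bwd(g):
        if image.requires_grad:
            gi = np.zeros_like(im)
            np.add.at(gi, (y0, x0), g * (1 - ty) * (1 - tx))
            np.add.at(gi, (y0, x0 + 1), g * (1 - ty) * tx)
            np.add.at(gi, (y0 + 1, x0), g * ty * (1 - tx))
            np.add.at(gi, (y0 + 1, x0 + 1), g * ty * tx)
            image._accumulate(gi)
        if disp_ax.requires_grad:
            dy = (bot - top)  # d out / d iy
            disp_ax._accumulate(np.where(vy, g * dy, 0.0))
        if disp_lat.requires_grad:
            dtop = i01 - i00
            dbot = i11 - i10
            dx = dtop * (1 - ty) + dbot * ty
            disp_lat._accumulate(np.where(vx, g * dx, 0.0))

    out._bwd = bwd
    return out, valid


# ------------------------------------------------------------------ box sums
def _boxsum_np(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Valid-mode sliding-window sum over the trailing two axes."""
    acc = x.astype(np.float64, copy=False)
    ii = np.pad(acc, [(0, 0)] * (x.ndim - 2) + [(1, 0), (1, 0)])
    ii = ii.cumsum(axis=-2).cumsum(axis=-1)
    out = (ii[..., kh:, kw:] - ii[..., :-kh, kw:]
           - ii[..., kh:, :-kw] + ii[..., :-kh, :-kw])
    return out.astype(x.dtype, copy=False)


def boxsum(x: Tensor, kh: int, kw: int) -> Tensor:
    """Differentiable valid-mode box sum (output (..., H-kh+1, W-kw+1))."""
    x = as_tensor(x)
    out = Tensor(_boxsum_np(x.data, kh, kw), _prev=(x,))

    def bwd(g):
        if x.requires_grad:
            gp = np.pad(g, [(0, 0)] * (g.ndim - 2)
                        + [(kh - 1, kh - 1), (kw - 1, kw - 1)])
            x._accumulate(_boxsum_np(gp, kh, kw))

    out._bwd = bwd
    return out


# --------------------------------------------------------------- grad checks
def grad_check(fn, tensors, eps: float = 1e-5) -> float:
    """Max relative error between analytic and central-difference gradients.

    ``fn`` maps the tensors to a scalar Tensor. Inputs should be float64.
    """
    out = fn(*tensors)
    for t in tensors:
        t.zero_grad()
    out = fn(*tensors)
    out.backward()
    worst = 0.0
    for t in tensors:
        if not t.requires_grad:
            continue
        g = t.grad.ravel()
        flat = t.data.ravel()
        num = np.zeros_like(flat)
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            fp = fn(*tensors).item()
            flat[i] = orig - eps
            fm = fn(*tensors).item()
            flat[i] = orig
            num[i] = (fp - fm) / (2 * eps)
        scale = max(np.abs(num).max(), np.abs(g).max(), 1e-8)
        worst = max(worst, float(np.abs(num - g).max() / scale))
    return worst
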