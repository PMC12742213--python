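"""Reverse-mode automatic differentiation on numpy arrays.

The registration network is trained by gradient descent on an image-similarity
objective, so every operation between the raw network weights and the scalar
loss must be differentiable: linear maps, layer/batch normalisation, windowed
attention, dilated convolution, the affine matrix construction (sin/cos/tanh of
the geometric parameters), trilinear grid sampling and the box-filtered local
NCC.  This module provides exactly that closed set of operations as a small
reverse-mode tape over ``float64`` numpy arrays.

Design notes
------------
* A :class:`Tensor` wraps one ndarray.  Ops build an implicit DAG; calling
  :meth:`Tensor.backward` on a scalar runs a topological sweep accumulating
  ``.grad`` on every node with ``requires_grad``.
* Elementwise binary ops broadcast like numpy; gradients are summed back to the
  operand shape (``_unbroadcast``).
* The three domain-specific primitives — ``conv3d`` (channels-last, arbitrary
  dilation), ``box_sum3d`` (zero-padded sliding-window sum, self-adjoint) and
  ``grid_sample3d`` (trilinear pull-sampling with zero fill, differentiable in
  both the image and the sample coordinates) — carry hand-written adjoints and
  are verified against finite differences in the test-suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    # -- basic introspection --------------------------------------------------
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bwd(g):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bwd(g):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bwd(g):
            a._accum(_unbroadcast(g / b.data, a.shape))
            b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        pw = float(p)

        def bwd(g):
            a._accum(g * pw * np.power(a.data, pw - 1.0))

        return Tensor._make(np.power(a.data, pw), (a,), bwd)

    # -- elementwise functions ------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * out_data))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * 0.5 / out_data))

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: a._accum(g * (1.0 - out_data ** 2)))

    def sin(self):
        a = self
        return Tensor._make(np.sin(a.data), (a,), lambda g: a._accum(g * np.cos(a.data)))

    def cos(self):
        a = self
        return Tensor._make(np.cos(a.data), (a,), lambda g: a._accum(-g * np.sin(a.data)))

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(np.where(mask, a.data, 0.0), (a,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape))

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        if axis is None:
            n = a.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([a.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self

        def bwd(g):
            a._accum(g.reshape(a.shape))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes: Sequence[int]):
        a = self
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        order = list(range(self.ndim))
        order[ax1], order[ax2] = order[ax2], order[ax1]
        return self.transpose(order)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            gg = np.zeros(a.shape, dtype=np.float64)
            np.add.at(gg, idx, g)
            a._accum(gg)

        return Tensor._make(a.data[idx], (a,), bwd)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        a = self
        pw = tuple((int(lo), int(hi)) for lo, hi in pad_width)
        sl = tuple(slice(lo, lo + n) for (lo, _hi), n in zip(pw, a.shape))

        def bwd(g):
            a._accum(g[sl])

        return Tensor._make(np.pad(a.data, pw), (a,), bwd)

    def roll(self, shifts, axes):
        a = self
        shifts = tuple(shifts)
        axes = tuple(axes)
        neg = tuple(-s for s in shifts)

        def bwd(g):
            a._accum(np.roll(g, neg, axis=axes))

        return Tensor._make(np.roll(a.data, shifts, axis=axes), (a,), bwd)

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)

        def bwd(g):
            if b.data.ndim == 1:
                # (..., k) @ (k,) -> (...)
                a._accum(_unbroadcast(g[..., None] * b.data, a.shape))
                b._accum(_unbroadcast((a.data * g[..., None]).sum(axis=tuple(range(a.data.ndim - 1))), b.shape))
            elif a.data.ndim == 1:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
                b._accum(_unbroadcast(np.outer(a.data, g), b.shape))
            else:
                a._accum(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
                b._accum(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- composite / special ops ----------------------------------------------
    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            a._accum((g - (g * y).sum(axis=axis, keepdims=True)) * y)

        return Tensor._make(y, (a,), bwd)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bwd)


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [Tensor.as_tensor(t) for t in tensors]

    def bwd(g):
        for i, t in enumerate(ts):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(np.stack([t.data for t in ts], axis=axis), ts, bwd)


def conv3d(x: Tensor, w: Tensor, dilation: int = 1) -> Tensor:
    """'Same' 3-D convolution, channels-last.

    ``x``: (X, Y, Z, Cin); ``w``: (k, k, k, Cin, Cout) with odd k.  Spatial
    shape is preserved via symmetric zero padding of ``dilation*(k-1)/2``.
    """
    x = Tensor.as_tensor(x)
    w = Tensor.as_tensor(w)
    k = w.shape[0]
    d = int(dilation)
    pad = d * (k - 1) // 2
    xp = np.pad(x.data, ((pad, pad),) * 3 + ((0, 0),))
    X, Y, Z, _ = x.shape
    out = np.zeros(x.shape[:3] + (w.shape[-1],), dtype=np.float64)
    for i in range(k):
        for j in range(k):
            for l in range(k):
                xs = xp[i * d:i * d + X, j * d:j * d + Y, l * d:l * d + Z, :]
                out += xs @ w.data[i, j, l]

    def bwd(g):
        if w.requires_grad:
            gw = np.zeros(w.shape, dtype=np.float64)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        xs = xp[i * d:i * d + X, j * d:j * d + Y, l * d:l * d + Z, :]
                        gw[i, j, l] = np.einsum("xyzc,xyzo->co", xs, g)
            w._accum(gw)
        if x.requires_grad:
            gxp = np.zeros(xp.shape, dtype=np.float64)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[i * d:i * d + X, j * d:j * d + Y, l * d:l * d + Z, :] += \
                            g @ w.data[i, j, l].T
            x._accum(gxp[pad:pad + X, pad:pad + Y, pad:pad + Z, :])

    return Tensor._make(out, (x, w), bwd)


def box_sum3d(x: Tensor, size: int) -> Tensor:
    """Sliding-window sum over ``size**3`` neighbourhoods, zero-padded.

    Linear and self-adjoint (symmetric kernel + zero padding), so the adjoint
    is the same filter applied to the upstream gradient.
    """
    x = Tensor.as_tensor(x)
    w = int(size)
    scale = float(w ** 3)

    def filt(a):
        return ndimage.uniform_filter(a, size=w, mode="constant", cval=0.0) * scale

    def bwd(g):
        x._accum(filt(g))

    return Tensor._make(filt(x.data), (x,), bwd)


def grid_sample3d(vol: Tensor, grid: Tensor | np.ndarray) -> Tensor:
    """Trilinear pull-sampling of a 3-D volume at normalized coordinates.

    ``vol``: (X, Y, Z); ``grid``: (N, 3) coordinates in [-1, 1] per axis with
    voxel centres at the interval ends (align-corners convention).  Samples
    outside the volume are zero.  Differentiable in both arguments.
    """
    vol = Tensor.as_tensor(vol)
    grid_is_tensor = isinstance(grid, Tensor)
    gdat = grid.data if grid_is_tensor else np.asarray(grid, dtype=np.float64)
    shape = vol.shape
    n = gdat.shape[0]

    # normalized -> voxel coordinates
    vox = np.empty_like(gdat)
    for ax in range(3):
        vox[:, ax] = (gdat[:, ax] + 1.0) * 0.5 * (shape[ax] - 1)

    f0 = np.floor(vox).astype(np.int64)
    frac = vox - f0

    corners = []  # (idx_flat, valid, weight, dw/dfrac per axis)
    strides = (shape[1] * shape[2], shape[2], 1)
    for cx in (0, 1):
        for cy in (0, 1):
            for cz in (0, 1):
                ix = f0[:, 0] + cx
                iy = f0[:, 1] + cy
                iz = f0[:, 2] + cz
                valid = ((ix >= 0) & (ix < shape[0]) &
                         (iy >= 0) & (iy < shape[1]) &
                         (iz >= 0) & (iz < shape[2]))
                wx = frac[:, 0] if cx else 1.0 - frac[:, 0]
                wy = frac[:, 1] if cy else 1.0 - frac[:, 1]
                wz = frac[:, 2] if cz else 1.0 - frac[:, 2]
                sx = 1.0 if cx else -1.0
                sy = 1.0 if cy else -1.0
                sz = 1.0 if cz else -1.0
                idx = (np.clip(ix, 0, shape[0] - 1) * strides[0]
                       + np.clip(iy, 0, shape[1] - 1) * strides[1]
                       + np.clip(iz, 0, shape[2] - 1))
                corners.append((idx, valid, wx, wy, wz, sx, sy, sz))

    flat = vol.data.ravel()
    out = np.zeros(n, dtype=np.float64)
    for idx, valid, wx, wy, wz, _sx, _sy, _sz in corners:
        val = np.where(valid, flat[idx], 0.0)
        out += wx * wy * wz * val

    def bwd(g):
        if vol.requires_grad:
            gv = np.zeros(vol.data.size, dtype=np.float64)
            for idx, valid, wx, wy, wz, _sx, _sy, _sz in corners:
                contrib = np.where(valid, g * wx * wy * wz, 0.0)
                gv += np.bincount(idx, weights=contrib, minlength=vol.data.size)
            vol._accum(gv.reshape(shape))
        if grid_is_tensor and grid.requires_grad:
            gg = np.zeros((n, 3), dtype=np.float64)
            for idx, valid, wx, wy, wz, sx, sy, sz in corners:
                val = np.where(valid, flat[idx], 0.0)
                gv = g * val
                gg[:, 0] += gv * sx * wy * wz
                gg[:, 1] += gv * wx * sy * wz
                gg[:, 2] += gv * wx * wy * sz
            for ax in range(3):
                gg[:, ax] *= 0.5 * (shape[ax] - 1)
            grid._accum(gg)

    parents = (vol, grid) if grid_is_tensor else (vol,)
    return Tensor._make(out, parents, bwd)
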