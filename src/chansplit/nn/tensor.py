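"""Minimal reverse-mode autodiff on NumPy arrays.

Supports exactly the operations needed by the splitting encoder-decoder:
stride-1 N-d convolution (im2col + BLAS), block average pooling,
nearest-neighbour upsampling, centred zero-padding/cropping, concatenation,
slicing, ELU, exp, and the usual arithmetic. float32 throughout.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # ------------------------------------------------------------------ #
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if not (self.requires_grad or self._parents):
            return
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float32, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------------ #
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return self * other ** -1.0

    def __pow__(self, p):
        assert np.isscalar(p)
        out = Tensor(self.data ** p, _parents=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def exp(self):
        ex = np.exp(self.data)
        out = Tensor(ex, _parents=(self,))
        out._backward = lambda g: self._accum(g * ex)
        return out

    def sum(self):
        out = Tensor(self.data.sum(), _parents=(self,))
        out._backward = lambda g: self._accum(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def elu(self):
        d = self.data
        ex = np.exp(np.minimum(d, 0.0))
        out = Tensor(np.where(d > 0, d, ex - 1.0), _parents=(self,))
        out._backward = lambda g: self._accum(g * np.where(d > 0, 1.0, ex))
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def detach(self):
        return Tensor(self.data.copy())


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g, shape):
    """Reduce gradient g back to `shape` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------- #
# structural ops
# ---------------------------------------------------------------------- #

def concat(tensors, axis=1):
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    out._backward = bw
    return out


def pad_center(x, target_spatial):
    """Zero-pad the trailing spatial axes of x symmetrically to target size.

    Odd differences put the extra pixel on the trailing side (mirror of the
    centre-crop convention).
    """
    nd = len(target_spatial)
    src = x.shape[-nd:]
    pads = [(0, 0)] * (x.ndim - nd)
    for s, t in zip(src, target_spatial):
        if t < s:
            raise ValueError(f"pad_center target {t} smaller than source {s}")
        d = t - s
        pads.append((d // 2, d - d // 2))
    out = Tensor(np.pad(x.data, pads), _parents=(x,))
    sl = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, x.shape))

    def bw(g):
        x._accum(g[sl])

    out._backward = bw
    return out


def center_crop(x, target_spatial):
    """Centre-crop trailing spatial axes; odd extra dropped from trailing side."""
    nd = len(target_spatial)
    sl = [slice(None)] * (x.ndim - nd)
    for s, t in zip(x.shape[-nd:], target_spatial):
        if t > s:
            raise ValueError(f"center_crop target {t} larger than source {s}")
        start = (s - t) // 2
        sl.append(slice(start, start + t))
    return x[tuple(sl)]


def avg_pool(x, factors):
    """Block average over the trailing spatial axes by integer factors."""
    nd = len(factors)
    lead = x.shape[: x.ndim - nd]
    spatial = x.shape[-nd:]
    for s, f in zip(spatial, factors):
        if s % f:
            raise ValueError(f"spatial dim {s} not divisible by pool factor {f}")
    newshape = list(lead)
    red_axes = []
    for i, (s, f) in enumerate(zip(spatial, factors)):
        newshape += [s // f, f]
        red_axes.append(len(lead) + 2 * i + 1)
    y = x.data.reshape(newshape).mean(axis=tuple(red_axes))
    out = Tensor(y, _parents=(x,))
    scale = 1.0 / np.prod(factors)

    def bw(g):
        gg = g
        for ax, f in zip(range(x.ndim - nd, x.ndim), factors):
            gg = np.repeat(gg, f, axis=ax)
        x._accum(gg * scale)

    out._backward = bw
    return out


def upsample_nearest(x, factors):
    y = x.data
    nd = len(factors)
    for ax, f in zip(range(x.ndim - nd, x.ndim), factors):
        y = np.repeat(y, f, axis=ax)
    out = Tensor(y, _parents=(x,))
    lead = x.shape[: x.ndim - nd]

    def bw(g):
        shp = list(lead)
        red = []
        for i, (s, f) in enumerate(zip(x.shape[-nd:], factors)):
            shp += [s, f]
            red.append(len(lead) + 2 * i + 1)
        x._accum(g.reshape(shp).sum(axis=tuple(red)))

    out._backward = bw
    return out


# ---------------------------------------------------------------------- #
# convolution
# ---------------------------------------------------------------------- #

def conv_nd(x, w, b, pad=None):
    """Stride-1 'same' N-d convolution (cross-correlation).

    x: (N, Cin, *S); w: (Cout, Cin, *K) with odd K; b: (Cout,) or None.
    Implemented as a sum over kernel offsets of (Cout, Cin) x (Cin, N*S)
    GEMMs, which avoids large im2col transposes on the CPU.
    """
    ksp = w.shape[2:]
    nd = len(ksp)
    if pad is None:
        pad = tuple(k // 2 for k in ksp)
    padspec = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    xp = np.pad(x.data, padspec)
    n, cin = x.shape[:2]
    cout = w.shape[0]
    sout = tuple(xp.shape[2 + i] - ksp[i] + 1 for i in range(nd))
    nspatial = int(np.prod(sout))

    def _shift(arr, kidx, sizes):
        sl = (slice(None), slice(None)) + tuple(
            slice(kidx[i], kidx[i] + sizes[i]) for i in range(nd)
        )
        return arr[sl]

    def _cols(kidx):
        # (Cin, N * nspatial) contiguous column matrix for one kernel offset
        xs = _shift(xp, kidx, sout)
        return np.ascontiguousarray(np.moveaxis(xs, 1, 0)).reshape(cin, -1)

    # forward: y (N, Cout, *Sout)
    y = np.zeros((cout, n) + sout, dtype=np.float32)
    ymat = y.reshape(cout, n * nspatial)
    for kidx in np.ndindex(*ksp):
        # (Cout, Cin) @ (Cin, N*S)
        ymat += w.data[(...,) + kidx] @ _cols(kidx)
    y = np.ascontiguousarray(np.moveaxis(y, 0, 1))
    if b is not None:
        y += b.data.reshape((1, cout) + (1,) * nd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _parents=parents)

    def bw(g):
        gt = np.ascontiguousarray(np.moveaxis(g, 1, 0)).reshape(cout, -1)
        gw = np.empty_like(w.data)
        for kidx in np.ndindex(*ksp):
            gw[(...,) + kidx] = gt @ _cols(kidx).T
        w._accum(gw)
        if b is not None:
            b._accum(gt.sum(axis=1))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            gb = gt.reshape(cout, n, nspatial)
            for kidx in np.ndindex(*ksp):
                contrib = np.tensordot(w.data[(...,) + kidx], gb, axes=(0, 0))
                # contrib: (Cin, N, *S) -> accumulate into shifted window
                _shift(gxp, kidx, sout)[...] += np.moveaxis(
                    contrib.reshape((cin, n) + sout), 0, 1
                )
            unpad = (slice(None), slice(None)) + tuple(
                slice(p, xp.shape[2 + i] - p) for i, p in enumerate(pad)
            )
            x._accum(gxp[unpad])

    out._backward = bw
    return out


def custom_grad(value, inputs, grads):
    """Build a Tensor with externally supplied value and input gradients.

    `grads` maps each input Tensor to the (already evaluated) local gradient
    array d(value)/d(input); used to splice non-autodiff likelihoods (e.g.
    fitted noise models) into the graph.  The chain rule multiplies by the
    incoming gradient element-wise.
    """
    out = Tensor(value, _parents=tuple(inputs))

    def bw(g):
        for t in inputs:
            t._accum(g * grads[t])

    out._backward = bw
    return out
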