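"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine implements exactly the primitives the translation networks need:
elementwise arithmetic with broadcasting, reductions, the activations used by
the generators and discriminators, channel concatenation, and N-dimensional
convolution / transposed convolution with zero, reflect or edge padding.
Gradients are accumulated by topological traversal of the recorded tape.

Arrays are float32 throughout; spatial layout is channels-first,
``(N, C, z, y, x)`` in 3D and ``(N, C, y, x)`` in 2D.
"""

from __future__ import annotations

import contextlib
from itertools import product as _product
from math import prod as _prod

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (inference / detached data)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------------ info
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------- lifecycle
    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # iterative topological sort (graphs can be deep for many-layer nets)
        topo, visited, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- arithmetic
def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _node(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def reduce_sum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _node(data, (a,), backward)


def reduce_mean(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = _prod(a.data.shape[ax] for ax in axes)
    return mul(reduce_sum(a, axis, keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _node(data, (a,), backward)


# --------------------------------------------------------------- activations
def tanh(a) -> Tensor:
    a = _as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - data * data))

    return _node(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, 0.0).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _node(data, (a,), backward)


def leaky_relu(a, negative_slope: float = 0.2) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, negative_slope * a.data).astype(np.float32)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(mask, 1.0, negative_slope).astype(np.float32))

    return _node(data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def backward(g):
        offset = 0
        for t, size in zip(tensors, sizes):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(offset, offset + size)
                t._accumulate(g[tuple(sl)])
            offset += size

    return _node(data, tuple(tensors), backward)


# ------------------------------------------------------------------- padding
def _pad_spatial(x: np.ndarray, pad: int, mode: str):
    """Pad the spatial axes (all but the first two) of ``x``.

    Returns the padded array and the per-axis index maps needed for the
    adjoint (``None`` for zero padding, handled by cropping).
    """
    if pad == 0:
        return x, None
    nd = x.ndim - 2
    widths = [(0, 0), (0, 0)] + [(pad, pad)] * nd
    if mode == "zeros":
        return np.pad(x, widths, mode="constant"), None
    np_mode = {"reflect": "reflect", "edge": "edge"}[mode]
    maps = []
    for ax in range(2, x.ndim):
        maps.append(np.pad(np.arange(x.shape[ax]), pad, mode=np_mode))
    return np.pad(x, widths, mode=np_mode), maps


def _unpad_spatial(g: np.ndarray, pad: int, orig_shape: tuple, maps):
    """Adjoint of :func:`_pad_spatial`."""
    if pad == 0:
        return g
    nd = g.ndim - 2
    if maps is None:  # zero padding: crop
        sl = (slice(None), slice(None)) + tuple(slice(pad, -pad) for _ in range(nd))
        return g[sl]
    for ax in range(2, g.ndim):
        idx = maps[ax - 2]
        gm = np.moveaxis(g, ax, 0)
        out = np.zeros((orig_shape[ax],) + gm.shape[1:], dtype=np.float32)
        np.add.at(out, idx, gm)
        g = np.moveaxis(out, 0, ax)
    return g


# --------------------------------------------------------------- convolution
def conv(x, weight, bias=None, stride: int = 1, padding: int = 0,
         pad_mode: str = "zeros") -> Tensor:
    """N-dimensional convolution (cross-correlation).

    ``x``: ``(N, Cin, *S)``; ``weight``: ``(Cout, Cin, *K)``; ``bias``: ``(Cout,)``.
    Implemented as a sum over kernel offsets of batched channel matmuls, which
    keeps peak memory at one input copy regardless of kernel size.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    bias = _as_tensor(bias) if bias is not None else None
    nd = weight.data.ndim - 2
    if x.data.ndim != nd + 2:
        raise ValueError(f"conv: input ndim {x.data.ndim} incompatible with {nd}D kernel")
    kernel = weight.data.shape[2:]
    xp, maps = _pad_spatial(x.data, padding, pad_mode)
    n, cin = xp.shape[:2]
    cout = weight.data.shape[0]
    out_sp = tuple((xp.shape[2 + i] - kernel[i]) // stride + 1 for i in range(nd))
    for i in range(nd):
        if out_sp[i] < 1:
            raise ValueError(
                f"conv: spatial size {x.data.shape[2:]} too small for kernel {kernel}"
            )
    npos = _prod(out_sp)
    out = np.zeros((n, cout, npos), dtype=np.float32)

    def _slices(off):
        return (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + stride * (out_sp[i] - 1) + 1, stride) for i in range(nd)
        )

    for off in _product(*[range(k) for k in kernel]):
        xs = np.ascontiguousarray(xp[_slices(off)]).reshape(n, cin, npos)
        w_off = weight.data[(slice(None), slice(None)) + off]  # (Cout, Cin)
        out += np.matmul(w_off, xs)
    if bias is not None:
        out += bias.data[None, :, None]
    data = out.reshape((n, cout) + out_sp)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gf = g.reshape(n, cout, npos)
        gxp = np.zeros_like(xp) if x.requires_grad else None
        gw = np.zeros_like(weight.data) if weight.requires_grad else None
        for off in _product(*[range(k) for k in kernel]):
            sl = _slices(off)
            w_off = weight.data[(slice(None), slice(None)) + off]
            if gw is not None:
                xs = np.ascontiguousarray(xp[sl]).reshape(n, cin, npos)
                gw[(slice(None), slice(None)) + off] += np.tensordot(
                    gf, xs, axes=([0, 2], [0, 2])
                )
            if gxp is not None:
                contrib = np.matmul(w_off.T, gf)  # (N, Cin, P)
                gxp[sl] += contrib.reshape((n, cin) + out_sp)
        if gw is not None:
            weight._accumulate(gw)
        if gxp is not None:
            x._accumulate(_unpad_spatial(gxp, padding, x.data.shape, maps))
        if bias is not None and bias.requires_grad:
            bias._accumulate(gf.sum(axis=(0, 2)))

    return _node(data, parents, backward)


def conv_transpose(x, weight, bias=None, stride: int = 2, padding: int = 1,
                   output_padding: int = 1) -> Tensor:
    """N-dimensional transposed convolution (fractionally strided).

    ``x``: ``(N, Cin, *S)``; ``weight``: ``(Cin, Cout, *K)``.
    Output spatial size per axis: ``stride*(S-1) + K - 2*padding + output_padding``.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    bias = _as_tensor(bias) if bias is not None else None
    nd = weight.data.ndim - 2
    kernel = weight.data.shape[2:]
    n, cin = x.data.shape[:2]
    cout = weight.data.shape[1]
    in_sp = x.data.shape[2:]
    full_sp = tuple(stride * (in_sp[i] - 1) + kernel[i] + output_padding for i in range(nd))
    out_sp = tuple(
        stride * (in_sp[i] - 1) + kernel[i] - 2 * padding + output_padding for i in range(nd)
    )
    npos = _prod(in_sp)
    xf = x.data.reshape(n, cin, npos)
    full = np.zeros((n, cout) + full_sp, dtype=np.float32)

    def _slices(off):
        return (slice(None), slice(None)) + tuple(
            slice(off[i], off[i] + stride * (in_sp[i] - 1) + 1, stride) for i in range(nd)
        )

    for off in _product(*[range(k) for k in kernel]):
        w_off = weight.data[(slice(None), slice(None)) + off]  # (Cin, Cout)
        full[_slices(off)] += np.matmul(w_off.T, xf).reshape((n, cout) + in_sp)
    crop = (slice(None), slice(None)) + tuple(
        slice(padding, padding + out_sp[i]) for i in range(nd)
    )
    data = full[crop]
    if bias is not None:
        data = data + bias.data[(None, slice(None)) + (None,) * nd]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gfull = np.zeros((n, cout) + full_sp, dtype=np.float32)
        gfull[crop] = g
        if x.requires_grad:
            gx = np.zeros((n, cin, npos), dtype=np.float32)
        if weight.requires_grad:
            gw = np.zeros_like(weight.data)
        for off in _product(*[range(k) for k in kernel]):
            gview = np.ascontiguousarray(gfull[_slices(off)]).reshape(n, cout, npos)
            w_off = weight.data[(slice(None), slice(None)) + off]
            if x.requires_grad:
                gx += np.matmul(w_off, gview)
            if weight.requires_grad:
                gw[(slice(None), slice(None)) + off] += np.tensordot(
                    xf, gview, axes=([0, 2], [0, 2])
                )
        if x.requires_grad:
            x._accumulate(gx.reshape(x.data.shape))
        if weight.requires_grad:
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0,) + tuple(range(2, g.ndim))))

    return _node(data, parents, backward)
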