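"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar loss walks the tape in
reverse topological order and accumulates gradients into every tensor with
``requires_grad=True``.  Only the operations needed by the segmentation
networks are provided: broadcast arithmetic, matmul, activations,
concatenation, pooling, and the 2-D convolution family (standard, depthwise,
and stride-2 transposed, all in NHWC layout).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "concat",
    "reshape",
    "mean_axes",
    "max_axes",
    "conv2d",
    "depthwise_conv2d",
    "conv2d_transpose",
    "depthwise_conv2d_transpose",
    "maxpool2x2",
]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topo sort; graphs are deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operator sugar used by the layers
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def sum(self):
        return sum_all(self)


def _needs_graph(*ts):
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward):
    if _needs_graph(*parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# -- arithmetic -----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(-_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


def sum_all(a: Tensor) -> Tensor:
    out_data = np.asarray(a.data.sum())

    def backward(g):
        a._accumulate(np.broadcast_to(g, a.shape).astype(a.dtype, copy=True))

    return _make(out_data, (a,), backward)


# -- activations ----------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable two-sided formulation
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                        np.exp(np.clip(x, None, 0)) / (1.0 + np.exp(np.clip(x, None, 0))))
    out_data = out_data.astype(x.dtype)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


# -- shape ops ------------------------------------------------------------

def concat(tensors, axis=-1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.shape))

    return _make(out_data, (a,), backward)


def mean_axes(a: Tensor, axes, keepdims=True) -> Tensor:
    axes = tuple(axes)
    out_data = a.data.mean(axis=axes, keepdims=keepdims)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        a._accumulate(np.broadcast_to(g / n, a.shape).astype(a.dtype, copy=True))

    return _make(out_data, (a,), backward)


def max_axes(a: Tensor, axes, keepdims=True) -> Tensor:
    axes = tuple(axes)
    out_data = a.data.max(axis=axes, keepdims=True)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axes)
        hit = (a.data == out_data)
        # split gradient evenly among tied maxima
        count = hit.sum(axis=axes, keepdims=True)
        a._accumulate(np.broadcast_to(g, a.shape) * hit / count)

    res_data = out_data if keepdims else out_data.squeeze(axis=axes)
    return _make(res_data, (a,), backward)


# -- convolution family (NHWC) -------------------------------------------

def _pad_same(x, k):
    p0, p1 = k // 2, k - 1 - k // 2
    return np.pad(x, ((0, 0), (p0, p1), (p0, p1), (0, 0)))


def _windows(xp, k):
    # (N, H, W, k, k, C) view over the padded input
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return np.ascontiguousarray(np.moveaxis(w, 3, 5))


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 convolution; ``w`` has shape (k, k, C_in, C_out)."""
    k = w.shape[0]
    n, h, wd, cin = x.shape
    cout = w.shape[3]
    xp = _pad_same(x.data, k)
    cols = _windows(xp, k).reshape(n * h * wd, k * k * cin)
    wf = w.data.reshape(k * k * cin, cout)
    out_data = (cols @ wf + b.data).reshape(n, h, wd, cout)

    def backward(g):
        gf = g.reshape(n * h * wd, cout)
        if w.requires_grad or w._parents:
            w._accumulate((cols.T @ gf).reshape(w.shape))
        if b.requires_grad or b._parents:
            b._accumulate(gf.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = (gf @ wf.T).reshape(n, h, wd, k, k, cin)
            dxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    dxp[:, di:di + h, dj:dj + wd, :] += dcols[:, :, :, di, dj, :]
            p0 = k // 2
            x._accumulate(dxp[:, p0:p0 + h, p0:p0 + wd, :])

    return _make(out_data, (x, w, b), backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 per-channel convolution; ``w`` shape (k, k, C)."""
    k = w.shape[0]
    n, h, wd, c = x.shape
    xp = _pad_same(x.data, k)
    win = _windows(xp, k)  # (N,H,W,k,k,C)
    out_data = np.einsum("nhwijc,ijc->nhwc", win, w.data) + b.data

    def backward(g):
        if w.requires_grad or w._parents:
            w._accumulate(np.einsum("nhwijc,nhwc->ijc", win, g))
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    dxp[:, di:di + h, dj:dj + wd, :] += g * w.data[di, dj]
            p0 = k // 2
            x._accumulate(dxp[:, p0:p0 + h, p0:p0 + wd, :])

    return _make(out_data, (x, w, b), backward)


def conv2d_transpose(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution; ``w`` shape (2, 2, C_in, C_out).

    With kernel == stride the output sub-pixels do not overlap, so the op is
    an einsum followed by an interleaving reshape.
    """
    n, h, wd, cin = x.shape
    cout = w.shape[3]
    t = np.einsum("nhwc,abcf->nhawbf", x.data, w.data)
    out_data = t.reshape(n, 2 * h, 2 * wd, cout) + b.data

    def backward(g):
        gt = g.reshape(n, h, 2, wd, 2, cout)
        if w.requires_grad or w._parents:
            w._accumulate(np.einsum("nhwc,nhawbf->abcf", x.data, gt))
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            x._accumulate(np.einsum("nhawbf,abcf->nhwc", gt, w.data))

    return _make(out_data, (x, w, b), backward)


def depthwise_conv2d_transpose(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 per-channel transposed convolution; ``w`` shape (2, 2, C)."""
    n, h, wd, c = x.shape
    t = np.einsum("nhwc,abc->nhawbc", x.data, w.data)
    out_data = t.reshape(n, 2 * h, 2 * wd, c) + b.data

    def backward(g):
        gt = g.reshape(n, h, 2, wd, 2, c)
        if w.requires_grad or w._parents:
            w._accumulate(np.einsum("nhwc,nhawbc->abc", x.data, gt))
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            x._accumulate(np.einsum("nhawbc,abc->nhwc", gt, w.data))

    return _make(out_data, (x, w, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, h, w, c = x.shape
    xr = x.data.reshape(n, h // 2, 2, w // 2, 2, c)
    out_data = xr.max(axis=(2, 4))

    def backward(g):
        hit = (xr == out_data[:, :, None, :, None, :])
        count = hit.sum(axis=(2, 4), keepdims=True)
        dxr = hit / count * g[:, :, None, :, None, :]
        x._accumulate(dxr.reshape(n, h, w, c))

    return _make(out_data, (x,), backward)
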