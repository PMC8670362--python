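"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the motion/EQ networks need: 3D
convolution with ceil-mode stride-2 halving, elementwise nonlinearities,
channel concatenation/slicing, linear layers, dropout and the two losses.
Gradients are verified against finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "conv3d",
    "linear",
    "relu",
    "sigmoid",
    "tanh",
    "add",
    "mul",
    "concat",
    "narrow",
    "reshape",
    "dropout",
    "mse_loss",
    "softmax_cross_entropy",
    "softmax",
]

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


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

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


def _make(data, parents, backward):
    """Create a result tensor, wiring the graph only when grads are on."""
    track = _grad_enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=track)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- elementwise


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x) -> Tensor:
    x = _as_tensor(x)
    data = np.maximum(x.data, 0)

    def backward(g):
        x._accumulate(g * (x.data > 0))

    return _make(data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    # numerically stable two-sided form (no overflow for large |x|)
    pos = x.data >= 0
    e = np.exp(np.where(pos, -x.data, x.data))
    data = np.where(pos, 1.0 / (1.0 + e), e / (1.0 + e))

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _make(data, (x,), backward)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - data**2))

    return _make(data, (x,), backward)


# ------------------------------------------------------------- shape plumbing


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(data, (x,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def backward(g):
        for t, o, s in zip(tensors, offsets, sizes):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(int(o), int(o + s))
                t._accumulate(g[tuple(idx)])

    return _make(data, tuple(tensors), backward)


def narrow(x, axis: int, start: int, length: int) -> Tensor:
    x = _as_tensor(x)
    idx = [slice(None)] * x.data.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    data = x.data[idx]

    def backward(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return _make(data, (x,), backward)


# ------------------------------------------------------------------- dropout


def dropout(x, rate: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    x = _as_tensor(x)
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    mask = mask.astype(x.data.dtype)
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


# -------------------------------------------------------------------- linear


def linear(x, w, b=None) -> Tensor:
    """x (B, F) @ w (F, O) + b (O,)."""
    x, w = _as_tensor(x), _as_tensor(w)
    data = x.data @ w.data
    if b is not None:
        b = _as_tensor(b)
        data = data + b.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=0))

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


# -------------------------------------------------------------------- conv3d


def ceil_conv_pad(d: int, k: int, s: int):
    """(pad_lo, pad_hi, out_size) for ceil-mode 'same'-style convolution."""
    out = -(-d // s)
    pad_total = max((out - 1) * s + k - d, 0)
    return pad_total // 2, pad_total - pad_total // 2, out


def conv_output_shape(spatial, k: int, s: int):
    return tuple(ceil_conv_pad(d, k, s)[2] for d in spatial)


def conv3d(x, w, b=None, stride: int = 1) -> Tensor:
    """3D convolution (cross-correlation) with ceil-mode zero padding.

    x: (B, C, D1, D2, D3), w: (O, C, k, k, k), b: (O,).  Output spatial size
    is ceil(d / stride) along each axis.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, C = x.data.shape[:2]
    O, Cw, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    if C != Cw:
        raise ValueError(f"input has {C} channels, weight expects {Cw}")
    s = int(stride)
    pads, outs = [], []
    for d in x.data.shape[2:]:
        lo, hi, out = ceil_conv_pad(d, k, s)
        pads.append((lo, hi))
        outs.append(out)
    xp = np.pad(x.data, [(0, 0), (0, 0)] + pads)

    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    win = win[:, :, ::s, ::s, ::s]  # (B, C, O1, O2, O3, k, k, k)
    data = np.tensordot(win, w.data, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
    data = np.moveaxis(data, -1, 1)  # (B, O, O1, O2, O3)
    data = np.ascontiguousarray(data)
    if b is not None:
        b = _as_tensor(b)
        data += b.data.reshape(1, O, 1, 1, 1)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            gw = np.tensordot(win, g, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
            # (C, k, k, k, O) -> (O, C, k, k, k)
            w._accumulate(np.moveaxis(gw, -1, 0))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        contrib = np.tensordot(g, w.data[:, :, i, j, l], axes=([1], [0]))
                        contrib = np.moveaxis(contrib, -1, 1)
                        gxp[
                            :,
                            :,
                            i : i + s * outs[0] : s,
                            j : j + s * outs[1] : s,
                            l : l + s * outs[2] : s,
                        ] += contrib
            slc = tuple(
                slice(lo, lo + d) for (lo, _), d in zip(pads, x.data.shape[2:])
            )
            x._accumulate(gxp[(slice(None), slice(None)) + slc])

    parents = (x, w) if b is None else (x, w, b)
    return _make(data, parents, backward)


# -------------------------------------------------------------------- losses


def mse_loss(pred, target) -> Tensor:
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=pred.data.dtype)
    diff = pred.data - target
    data = np.array((diff**2).mean(), dtype=pred.data.dtype)

    def backward(g):
        pred._accumulate(g * 2.0 * diff / diff.size)

    return _make(data, (pred,), backward)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits, labels) -> Tensor:
    """Mean cross-entropy of softmax(logits (B, T)) against integer labels (B,)."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=int)
    B = logits.data.shape[0]
    p = softmax(logits.data, axis=1)
    eps = np.finfo(p.dtype).tiny
    data = np.array(-np.mean(np.log(p[np.arange(B), labels] + eps)))

    def backward(g):
        grad = p.copy()
        grad[np.arange(B), labels] -= 1.0
        logits._accumulate(g * grad / B)

    return _make(data, (logits,), backward)
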