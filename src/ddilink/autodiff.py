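"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module provides the numerical core for the GCN encoders, the
self-supervised pretraining losses and the DDI training objective: a
``Tensor`` wrapping an ndarray with a gradient slot, a small set of
differentiable operations (dense and batched matrix products, ReLU,
log/exp, reductions, row gathering, a numerically safe L2 norm and
log-softmax), and an Adam optimizer.

All operations dispatch on type: called with plain ndarrays they return
ndarrays; as soon as one argument is a ``Tensor`` the operation records
itself on the tape and returns a ``Tensor``. Gradients are accumulated
by :meth:`Tensor.backward`, which walks the tape iteratively (no
recursion limit on deep graphs).
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
    "log",
    "exp",
    "power",
    "tsum",
    "tmean",
    "div",
    "sqrt",
    "l2norm",
    "reshape",
    "take_rows",
    "stack_rows",
    "log_softmax",
    "softplus",
    "clamp_min",
    "Adam",
]


class Tensor:
    """An ndarray with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = np.zeros_like(self.data)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        # iterative topological sort (graphs can be thousands of nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; use mul + power")
        return mul(self, 1.0 / other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, k):
        return power(self, k)

    def sum(self, axis=None):
        return tsum(self, axis=axis)

    def mean(self, axis=None):
        return tmean(self, axis=axis)

    def relu(self):
        return relu(self)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


def _wrap(data, parents, backward):
    parents = tuple(p for p in parents if _is_tensor(p))
    req = any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = parents
        out._backward = backward
    return out


def _accum(t, g):
    if _is_tensor(t) and t.requires_grad:
        t.grad += _unbroadcast(g, t.data.shape)


# -- elementwise --------------------------------------------------------


def add(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.add(_data(a), _data(b))
    out_data = _data(a) + _data(b)

    def backward(g):
        _accum(a, g)
        _accum(b, g)

    return _wrap(out_data, (a, b), backward)


def sub(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.subtract(_data(a), _data(b))
    out_data = _data(a) - _data(b)

    def backward(g):
        _accum(a, g)
        _accum(b, -g)

    return _wrap(out_data, (a, b), backward)


def mul(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.multiply(_data(a), _data(b))
    da, db = _data(a), _data(b)
    out_data = da * db

    def backward(g):
        _accum(a, g * db)
        _accum(b, g * da)

    return _wrap(out_data, (a, b), backward)


def matmul(a, b):
    """Matrix product, supporting batched operands via ``np.matmul`` broadcasting."""
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.matmul(_data(a), _data(b))
    da, db = _data(a), _data(b)
    out_data = np.matmul(da, db)

    def backward(g):
        if _is_tensor(a) and a.requires_grad:
            ga = np.matmul(g, np.swapaxes(db, -1, -2))
            a.grad += _unbroadcast(ga, da.shape)
        if _is_tensor(b) and b.requires_grad:
            gb = np.matmul(np.swapaxes(da, -1, -2), g)
            b.grad += _unbroadcast(gb, db.shape)

    return _wrap(out_data, (a, b), backward)


def relu(x):
    if not _is_tensor(x):
        return np.maximum(_data(x), 0.0)
    mask = x.data > 0

    def backward(g):
        _accum(x, g * mask)

    return _wrap(np.where(mask, x.data, 0.0), (x,), backward)


def log(x):
    if not _is_tensor(x):
        return np.log(_data(x))
    d = x.data

    def backward(g):
        _accum(x, g / d)

    return _wrap(np.log(d), (x,), backward)


def exp(x):
    if not _is_tensor(x):
        return np.exp(_data(x))
    out_data = np.exp(x.data)

    def backward(g):
        _accum(x, g * out_data)

    return _wrap(out_data, (x,), backward)


def power(x, k):
    """Elementwise integer power ``x**k`` (k >= 1)."""
    k = int(k)
    if not _is_tensor(x):
        return _data(x) ** k
    d = x.data

    def backward(g):
        _accum(x, g * k * d ** (k - 1))

    return _wrap(d**k, (x,), backward)


def clamp_min(x, lo: float):
    """max(x, lo); gradient flows only through unclamped entries."""
    if not _is_tensor(x):
        return np.maximum(_data(x), lo)
    mask = x.data >= lo

    def backward(g):
        _accum(x, g * mask)

    return _wrap(np.where(mask, x.data, lo), (x,), backward)


# -- reductions ---------------------------------------------------------


def tsum(x, axis=None, keepdims=False):
    if not _is_tensor(x):
        return np.sum(_data(x), axis=axis, keepdims=keepdims)
    d = x.data
    out_data = d.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            x.grad += np.broadcast_to(g, d.shape)
        elif keepdims:
            x.grad += np.broadcast_to(g, d.shape)
        else:
            x.grad += np.broadcast_to(np.expand_dims(g, axis), d.shape)

    return _wrap(out_data, (x,), backward)


def tmean(x, axis=None, keepdims=False):
    d = _data(x)
    n = d.size if axis is None else d.shape[axis]
    return mul(tsum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def div(a, b):
    """Elementwise division with broadcasting."""
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.divide(_data(a), _data(b))
    da, db = _data(a), _data(b)
    out_data = da / db

    def backward(g):
        _accum(a, g / db)
        _accum(b, -g * da / (db * db))

    return _wrap(out_data, (a, b), backward)


def sqrt(x):
    if not _is_tensor(x):
        return np.sqrt(_data(x))
    out_data = np.sqrt(x.data)

    def backward(g):
        _accum(x, g / (2.0 * out_data))

    return _wrap(out_data, (x,), backward)


def l2norm(x, eps: float = 1e-12):
    """Euclidean norm of all entries; exact forward, ``eps``-guarded backward.

    The forward value is exactly ``sqrt(sum(x**2))`` (no epsilon added),
    so a zero input yields exactly 0; the subgradient at 0 is taken as 0.
    """
    if not _is_tensor(x):
        return float(np.sqrt(np.sum(_data(x) ** 2)))
    d = x.data
    val = float(np.sqrt(np.sum(d**2)))

    def backward(g):
        _accum(x, g * d / max(val, eps))

    return _wrap(val, (x,), backward)


# -- indexing / shaping -------------------------------------------------


def reshape(x, shape):
    if not _is_tensor(x):
        return _data(x).reshape(shape)
    orig = x.data.shape

    def backward(g):
        _accum(x, g.reshape(orig))

    return _wrap(x.data.reshape(shape), (x,), backward)


def take_rows(x, idx):
    """Gather rows (first-axis indexing) with scatter-add backward.

    ``idx`` may be any integer array shape; output shape is
    ``idx.shape + x.shape[1:]``.
    """
    idx = np.asarray(idx, dtype=np.intp)
    if not _is_tensor(x):
        return _data(x)[idx]
    d = x.data

    def backward(g):
        if x.requires_grad:
            np.add.at(x.grad, idx, g)

    return _wrap(d[idx], (x,), backward)


def stack_rows(tensors):
    """Stack 1-D tensors/arrays into a matrix (row per input)."""
    if not any(_is_tensor(t) for t in tensors):
        return np.stack([_data(t) for t in tensors])
    out_data = np.stack([_data(t) for t in tensors])

    def backward(g):
        for i, t in enumerate(tensors):
            _accum(t, g[i])

    return _wrap(out_data, tuple(tensors), backward)


def log_softmax(x):
    """Row-wise log-softmax over the last axis (numerically stable)."""
    d = _data(x)
    shifted = d - d.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(shifted).sum(axis=-1, keepdims=True))
    out_data = shifted - lse
    if not _is_tensor(x):
        return out_data
    soft = np.exp(out_data)

    def backward(g):
        _accum(x, g - soft * g.sum(axis=-1, keepdims=True))

    return _wrap(out_data, (x,), backward)


def softplus(x):
    """Stable ``log(1 + exp(x))``; gradient is the sigmoid (never vanishes)."""
    if not _is_tensor(x):
        return np.logaddexp(0.0, _data(x))
    out_data = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * sig)

    return _wrap(out_data, (x,), backward)


def sigmoid(x):
    if not _is_tensor(x):
        d = _data(x)
        return 1.0 / (1.0 + np.exp(-d))
    s = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        _accum(x, g * s * (1.0 - s))

    return _wrap(s, (x,), backward)


# -- optimization -------------------------------------------------------


class Adam:
    """Adam optimizer over a list/dict of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        if isinstance(params, dict):
            params = list(params.values())
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
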