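"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the age-prediction network needs: broadcasted
add/mul, (batched) matmul, ReLU/tanh, last-axis softmax, reductions, reshape,
concatenation, valid 2D convolution, per-batch node gathering for top-K
pooling, and an Adam optimizer with independent learning-rate groups.

Everything is float64 and CPU-only; determinism is inherited from NumPy.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "relu",
    "tanh",
    "reciprocal",
    "sqrt",
    "square",
    "softmax",
    "tsum",
    "tmean",
    "reshape",
    "concat",
    "conv2d",
    "gather_nodes",
    "gather_vec",
    "Adam",
]


class Tensor:
    """An ndarray plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph mechanics -----------------------------------------------
    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray):
        if not self.requires_grad and self._backward is None:
            return  # constant leaf: no gradient needed
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(other, self)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- elementwise ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    data = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _make(data, (x,), backward)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - data * data))

    return _make(data, (x,), backward)


def reciprocal(x) -> Tensor:
    x = as_tensor(x)
    data = 1.0 / x.data

    def backward(g):
        x._accumulate(-g * data * data)

    return _make(data, (x,), backward)


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    data = np.sqrt(x.data)

    def backward(g):
        x._accumulate(g * 0.5 / data)

    return _make(data, (x,), backward)


def square(x) -> Tensor:
    x = as_tensor(x)
    data = x.data * x.data

    def backward(g):
        x._accumulate(g * 2.0 * x.data)

    return _make(data, (x,), backward)


def softmax(x) -> Tensor:
    """Softmax over the last axis."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        dot = (g * data).sum(axis=-1, keepdims=True)
        x._accumulate(data * (g - dot))

    return _make(data, (x,), backward)


# -- reductions / shape ---------------------------------------------------

def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _make(data, (x,), backward)


def tmean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.mean(axis=axis, keepdims=keepdims)
    denom = x.data.size if axis is None else x.data.shape[axis]

    def backward(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g / denom, x.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g / denom, x.data.shape).copy())

    return _make(data, (x,), backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _make(data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    return _make(data, ts, backward)


# -- convolution -----------------------------------------------------------

def conv2d(x, w, b) -> Tensor:
    """Valid 2D convolution (really cross-correlation, the CNN convention).

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,).
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    B, Cin, H, W = x.data.shape
    Cout, Cin2, kh, kw = w.data.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin} vs kernel {Cin2}")
    Ho, Wo = H - kh + 1, W - kw + 1
    if Ho < 1 or Wo < 1:
        raise ValueError(f"kernel ({kh}x{kw}) larger than input ({H}x{W})")
    data = np.zeros((B, Cout, Ho, Wo))
    for u in range(kh):
        for v in range(kw):
            data += np.einsum(
                "bcij,oc->boij", x.data[:, :, u : u + Ho, v : v + Wo], w.data[:, :, u, v]
            )
    data += b.data[None, :, None, None]

    def backward(g):
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for u in range(kh):
            for v in range(kw):
                gx[:, :, u : u + Ho, v : v + Wo] += np.einsum(
                    "boij,oc->bcij", g, w.data[:, :, u, v]
                )
                gw[:, :, u, v] = np.einsum(
                    "boij,bcij->oc", g, x.data[:, :, u : u + Ho, v : v + Wo]
                )
        x._accumulate(gx)
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(data, (x, w, b), backward)


# -- per-batch gathers (top-K pooling) -------------------------------------

def gather_nodes(h, idx: np.ndarray) -> Tensor:
    """Induced submatrix per batch element: out[b] = h[b][idx[b]][:, idx[b]]."""
    h = as_tensor(h)
    idx = np.asarray(idx)
    B = h.data.shape[0]
    bix = np.arange(B)[:, None, None]
    data = h.data[bix, idx[:, :, None], idx[:, None, :]]

    def backward(g):
        gh = np.zeros_like(h.data)
        np.add.at(gh, (bix, idx[:, :, None], idx[:, None, :]), g)
        h._accumulate(gh)

    return _make(data, (h,), backward)


def gather_vec(s, idx: np.ndarray) -> Tensor:
    """Per-batch row gather: out[b] = s[b][idx[b]]."""
    s = as_tensor(s)
    idx = np.asarray(idx)
    B = s.data.shape[0]
    bix = np.arange(B)[:, None]
    data = s.data[bix, idx]

    def backward(g):
        gs = np.zeros_like(s.data)
        np.add.at(gs, (bix, idx), g)
        s._accumulate(gs)

    return _make(data, (s,), backward)


# -- optimizer --------------------------------------------------------------

class Adam:
    """Adam with independent learning rates per parameter group."""

    def __init__(self, groups, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        # groups: iterable of {"params": [Tensor, ...], "lr": float}
        self.groups = [
            {"params": list(g["params"]), "lr": float(g["lr"])} for g in groups
        ]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {}
        self._v = {}
        for g in self.groups:
            for p in g["params"]:
                self._m[id(p)] = np.zeros_like(p.data)
                self._v[id(p)] = np.zeros_like(p.data)

    def zero_grad(self):
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m[id(p)]
                v = self._v[id(p)]
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad * p.grad
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
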