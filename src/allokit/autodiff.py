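"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the relational-inference model needs:
broadcasting arithmetic, matmul (with leading batch dimensions),
elementwise nonlinearities, reductions, reshape/transpose/concatenate,
and a numerically stable softmax/log-softmax pair. Gradients are
accumulated on a topologically sorted tape.

Tensors are float64 by default; float32 data is kept as float32 (the
training presets use it for speed — on one core the workload is
memory-bound). Determinism follows from numpy's.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "relu", "elu", "tanh", "exp", "log",
           "softmax", "log_softmax", "matmul"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over broadcast (size-1) axes
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, data, requires_grad: bool = False):
        data = np.asarray(data)
        if data.dtype not in (np.float32, np.float64):
            data = data.astype(np.float64)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ---- construction helpers -------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _lift_like(self, x) -> "Tensor":
        """Lift, casting bare scalars to this tensor's dtype so
        float32 graphs are not silently promoted to float64."""
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x)
        if arr.ndim == 0 and arr.dtype != self.data.dtype:
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- arithmetic ------------------------------------------------
    def __add__(self, other):
        other = self._lift_like(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift_like(other))

    def __rsub__(self, other):
        return self._lift_like(other) + (-self)

    def __mul__(self, other):
        other = self._lift_like(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift_like(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __pow__(self, p: float):
        def backward(g, out):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data ** p, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        def backward(g, out):
            if self.requires_grad:
                acc = np.zeros_like(self.data)
                np.add.at(acc, key, g)
                self._accum(acc)

        return self._make(self.data[key], (self,), backward)

    # ---- shape ops -------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g, out):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- autodiff driver -------------------------------------------
    def _accum(self, g: np.ndarray):
        # first contribution is stored as-is (contributions are freshly
        # allocated by the backward rules); later ones add out-of-place
        # so an aliased first array is never mutated
        if self.grad is None:
            self.grad = g if g.shape == self.data.shape \
                else np.broadcast_to(g, self.data.shape).copy()
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from long rollouts get deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = (np.ones_like(self.data) if grad is None
                     else np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad, node)


# ---- free functions ------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with broadcasting over leading axes."""
    a, b = Tensor._lift(a), Tensor._lift(b)

    def backward(g, out):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accum(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accum(_unbroadcast(gb, b.shape))

    return a._make(a.data @ b.data, (a, b), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return tensors[0]._make(data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    mask = x.data > 0

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * mask)

    return x._make(x.data * mask, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = Tensor._lift(x)
    pos = x.data > 0
    data = x.data.copy()
    neg_exp = alpha * np.exp(x.data[~pos])  # = d/dx on the negative branch
    data[~pos] = neg_exp - alpha            # α(exp(x) − 1)

    def backward(g, out):
        if x.requires_grad:
            gx = g.copy()
            gx[~pos] *= neg_exp
            x._accum(gx)

    return x._make(data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    t = np.tanh(x.data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * (1.0 - t ** 2))

    return x._make(t, (x,), backward)


def exp(x: Tensor) -> Tensor:
    x = Tensor._lift(x)
    e = np.exp(x.data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * e)

    return x._make(e, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = Tensor._lift(x)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g / x.data)

    return x._make(np.log(x.data), (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out_data = shifted - lse
    sm = np.exp(out_data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor._lift(x)
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g, out):
        if x.requires_grad:
            inner = (g * s).sum(axis=axis, keepdims=True)
            x._accum(s * (g - inner))

    return x._make(s, (x,), backward)
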