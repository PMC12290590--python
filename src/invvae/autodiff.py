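"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training objective of the invariant graph VAE is a composition of dense
linear maps, elementwise nonlinearities, reductions and gathers.  This module
provides exactly those primitives on a :class:`Tensor` wrapper around float64
numpy arrays, with gradients accumulated by topological-order backpropagation,
plus the Adam optimizer used by the training loop.

Every primitive's gradient is exercised against central finite differences in
the test suite; relative agreement better than 1e-6 at double precision is
typical, and 1e-4 is asserted.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softplus",
    "Adam",
    "clip_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # axes of size 1 that were stretched
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A float64 array node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if id(node) in seen:
                continue
            if expanded:
                seen.add(id(node))
                topo.append(node)
            else:
                stack.append((node, True))
                for p in node._parents:
                    if id(p) not in seen and p.requires_grad:
                        stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * p * self.data ** (p - 1.0), self.data.shape))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(np.matmul(self.data, other.data), _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                if other.data.ndim == 1:
                    ga = np.outer(g, other.data) if g.ndim == 1 else np.einsum(
                        "...i,j->...ij", g, other.data
                    )
                elif g.ndim == 1:  # vector @ matrix
                    ga = g @ other.data.T
                else:
                    ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g) if g.ndim == 1 else np.einsum(
                        "i,...j->...ij", self.data, g
                    )
                elif g.ndim == 1:
                    gb = self.data.T @ g
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- elementwise functions --------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def tanh(self):
        val = np.tanh(self.data)
        out = Tensor(val, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - val * val))

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; the gradient passes only where no clamping occurred."""
        mask = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    # -- reductions and shape ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def take(self, indices, axis: int):
        """Gather along ``axis`` with a fixed integer index array (axis 0 or 1)."""
        if axis not in (0, 1):
            raise ValueError("take supports axis 0 or 1")
        indices = np.asarray(indices)
        out = Tensor(np.take(self.data, indices, axis=axis), _parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            gp = np.zeros_like(self.data)
            if axis == 0:
                np.add.at(gp, indices, g)
            else:
                np.add.at(gp, (slice(None), indices), g)
            self._accum(gp)

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis), _parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p._accum(g[tuple(sl)])

    out._backward = bw
    return out


def softplus(x: Tensor) -> Tensor:
    """Numerically stable log(1 + exp(x)); gradient is the logistic sigmoid."""
    x = Tensor._lift(x)
    val = np.logaddexp(0.0, x.data)
    out = Tensor(val, _parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(g / (1.0 + np.exp(-x.data)))

    out._backward = bw
    return out


class Adam:
    """Adam with bias correction; operates in place on parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / (1.0 - self.b1 ** self.t)
            vhat = v / (1.0 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_grad_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float(np.sum(p.grad * p.grad))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm
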