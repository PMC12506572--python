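"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients into every reachable leaf.  Only the
operations the network layers in :mod:`utropt._nn` need are provided —
broadcasting elementwise arithmetic, 2-D/batched matmul, a handful of
nonlinearities, reductions, slicing and a stride-1 same-padding 1-D
convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "softmax", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free interior gradients/graph as we go
                node._backward = None

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / other)

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        out._backward = bwd
        return out

    # -- nonlinearities --------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        # clip to keep exp in range; saturated values are exactly 0/1 anyway
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500.0, 500.0)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        y = np.where(self.data > 0, self.data, neg)
        out = Tensor(y, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.where(self.data > 0, 1.0, neg + alpha))

        out._backward = bwd
        return out

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.data.shape))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        basic = isinstance(idx, (slice, int)) or (
            isinstance(idx, tuple) and all(isinstance(i, (slice, int)) for i in idx))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # disjoint view: plain accumulate is safe and fast
                    full[idx] += g
                else:
                    np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bwd
        return out

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stable softmax along ``axis`` with exact Jacobian-vector backward."""
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            dot = (g * y).sum(axis=axis, keepdims=True)
            x._accum(y * (g - dot))

    out._backward = bwd
    return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    out._backward = bwd
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Stride-1 same-padding 1-D convolution.

    ``x``: (B, L, C_in); ``w``: (K, C_in, C_out); ``b``: (C_out,).
    Output: (B, L, C_out).  Length is always preserved.
    """
    B, L, Cin = x.data.shape
    K, _, Cout = w.data.shape
    pl = (K - 1) // 2
    pr = K - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    y = np.zeros((B, L, Cout))
    for k in range(K):
        y += xp[:, k:k + L] @ w.data[k]
    y += b.data
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for k in range(K):
                dw[k] = np.einsum("bli,blo->io", xp[:, k:k + L], g)
            w._accum(dw)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(K):
                dxp[:, k:k + L] += g @ w.data[k].T
            x._accum(dxp[:, pl:pl + L])

    out._backward = bwd
    return out
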