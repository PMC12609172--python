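"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the synergy model needs: broadcast
arithmetic, (batched) matrix products, reshape/transpose/concatenate,
sigmoid / softmax / log, reductions, row gathering for embedding lookups
and elementwise masking for dropout.  Gradients are accumulated by a
topologically ordered backward sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "concat", "stack2"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), backward)

    def square(self):
        def backward(g, out):
            self._accum(2.0 * self.data * g)

        return self._make(self.data**2, (self,), backward)

    def matmul(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def backward(g, out):
            if self.requires_grad:
                if b.ndim == 1:
                    ga = np.multiply.outer(g, b) if a.ndim > 1 else g * b
                else:
                    ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, a.shape))
            if other.requires_grad:
                if a.ndim == 1:
                    gb = np.multiply.outer(a, g)
                else:
                    gb = np.swapaxes(a, -1, -2) @ g
                other._accum(_unbroadcast(gb, b.shape))

        return self._make(a @ b, (self, other), backward)

    __matmul__ = matmul

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def backward(g, out):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(range(self.data.ndim))[::-1]
        inv = np.argsort(axes)

        def backward(g, out):
            self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def swapaxes(self, a, b):
        axes = list(range(self.data.ndim))
        axes[a], axes[b] = axes[b], axes[a]
        return self.transpose(*axes)

    # -- nonlinearities and reductions ----------------------------------------
    def sigmoid(self):
        y = np.empty_like(self.data)
        np.exp(-np.abs(self.data), out=y)
        pos = self.data >= 0
        y[pos] = 1.0 / (1.0 + y[pos])
        y[~pos] = y[~pos] / (1.0 + y[~pos])

        def backward(g, out):
            self._accum(g * out.data * (1.0 - out.data))

        return self._make(y, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            self._accum(g * mask)

        return self._make(np.where(mask, self.data, 0.0), (self,), backward)

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g, out):
            s = (g * out.data).sum(axis=axis, keepdims=True)
            self._accum((g - s) * out.data)

        return self._make(y, (self,), backward)

    def log(self):
        def backward(g, out):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def clip(self, lo, hi):
        mask = (self.data >= lo) & (self.data <= hi)

        def backward(g, out):
            self._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), backward)

    def sum(self, axis=None, keepdims=False):
        shape = self.data.shape

        def backward(g, out):
            if axis is None:
                self._accum(np.broadcast_to(g, shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- lookup ---------------------------------------------------------------
    def take_rows(self, indices: np.ndarray):
        """Gather rows (embedding lookup); grad scatter-adds into the table."""
        idx = np.asarray(indices)

        def backward(g, out):
            gt = np.zeros_like(self.data)
            np.add.at(gt, idx.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accum(gt)

        return self._make(self.data[idx], (self,), backward)

    # -- backward machinery -----------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad, node)

    def item(self):
        return float(self.data.reshape(()))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return as_tensor(x)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(t for t in tensors if t.requires_grad)

        def backward(g, o):
            pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
            for t, piece in zip(tensors, pieces):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def stack2(a: Tensor, b: Tensor, axis: int) -> Tensor:
    """Stack two tensors along a new axis (used by gated FM/DNN fusion)."""
    ea = a.reshape(*a.shape[:axis], 1, *a.shape[axis:])
    eb = b.reshape(*b.shape[:axis], 1, *b.shape[axis:])
    return concat([ea, eb], axis=axis)
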