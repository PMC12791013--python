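"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations producing it;
``Tensor.backward()`` walks the graph in reverse topological order and
accumulates gradients.  The op set is exactly what the sequence models in
this package need (broadcast arithmetic, batched matmul, indexing, reductions
and the usual nonlinearities) — it is not a general DL framework.

Gradient correctness is pinned by finite-difference tests; everything is
single-threaded NumPy, so results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape))
                 if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward_fn=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._parents = parents if self.requires_grad else ()
        self._backward_fn = backward_fn if self.requires_grad else None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _binary(a: "Tensor", b: "Tensor", data, backward_fn) -> "Tensor":
        req = a.requires_grad or b.requires_grad
        return Tensor(data, req, (a, b), backward_fn)

    @staticmethod
    def _unary(a: "Tensor", data, backward_fn) -> "Tensor":
        return Tensor(data, a.requires_grad, (a,), backward_fn)

    def _accum(self, g: np.ndarray) -> None:
        # gradients live in the tensor's own dtype (float32 models stay
        # float32 end-to-end; float64 tests keep full precision)
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g.astype(self.data.dtype, copy=False)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data + b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._binary(a, b, out_data, bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)
        return Tensor._unary(a, -a.data, bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data * b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._binary(a, b, out_data, bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data / b.data

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
        return Tensor._binary(a, b, out_data, bw)

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accum(g * p * a.data ** (p - 1))
        return Tensor._unary(a, out_data, bw)

    def __matmul__(self, other):
        a, b = self, _as_tensor(other)
        out_data = a.data @ b.data

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))
        return Tensor._binary(a, b, out_data, bw)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)
        return Tensor._unary(a, out_data, bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)
        return Tensor._unary(a, np.log(a.data), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accum(g * 0.5 / out_data)
        return Tensor._unary(a, out_data, bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accum(g * (1.0 - out_data ** 2))
        return Tensor._unary(a, out_data, bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * out_data * (1.0 - out_data))
        return Tensor._unary(a, out_data, bw)

    def relu(self):
        a = self
        pos = a.data > 0

        def bw(g):
            a._accum(g * pos)
        return Tensor._unary(a, a.data * pos, bw)

    def softplus(self):
        """log(1 + exp(x)), numerically stable."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            a._accum(g / (1.0 + np.exp(-a.data)))
        return Tensor._unary(a, out_data, bw)

    def abs(self):
        a = self
        s = np.sign(a.data)

        def bw(g):
            a._accum(g * s)
        return Tensor._unary(a, np.abs(a.data), bw)

    # -- reductions / shaping --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        return Tensor._unary(a, out_data, bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bw(g):
            a._accum(g.reshape(a.data.shape))
        return Tensor._unary(a, a.data.reshape(shape), bw)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))
        return Tensor._unary(a, a.data.transpose(axes), bw)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice)) for i in idx))

        def bw(g):
            full = np.zeros_like(a.data)
            if basic:  # no duplicate positions: plain accumulation is fine
                full[idx] += g
            else:
                np.add.at(full, idx, g)
            a._accum(full)
        return Tensor._unary(a, out_data, bw)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [_as_tensor(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, o, s in zip(tensors, offsets[:-1], sizes):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(o, o + s)
                    t._accum(g[tuple(sl)])
        req = any(t.requires_grad for t in tensors)
        return Tensor(out_data, req, tuple(tensors), bw)

    def pad_axis(self, axis: int, before: int, after: int = 0):
        """Zero-pad along one axis (used for causal convolutions)."""
        a = self
        pad = [(0, 0)] * a.data.ndim
        pad[axis] = (before, after)
        out_data = np.pad(a.data, pad)

        def bw(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(before, before + a.data.shape[axis])
            a._accum(g[tuple(sl)])
        return Tensor._unary(a, out_data, bw)

    def softmax(self, axis: int = -1):
        """Fused softmax (single graph node; memory matters for attention)."""
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            a._accum((g - dot) * out_data)
        return Tensor._unary(a, out_data, bw)

    # -- backprop ----------------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=np.float64)
        for node in reversed(topo):
            if node._backward_fn is not None and node.grad is not None:
                node._backward_fn(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
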