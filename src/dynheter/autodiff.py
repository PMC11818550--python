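"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's graph encoders and the dynamic-threshold heterogeneous graph
need gradients with respect to every parameter, including the two edge
thresholds that reshape the dataset-level graph during training.  This module
provides a small tape-based :class:`Tensor` with exactly the operations those
models need (dense linear algebra, elementwise nonlinearities, row gather,
segment reductions for message passing) plus an Adam optimizer.

All arithmetic is float64.  Graphs of operations are built eagerly; calling
:meth:`Tensor.backward` on a scalar walks the tape in reverse topological
order and accumulates ``grad`` on every tensor created with
``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "segment_sum",
    "segment_softmax",
    "gather_rows",
    "stop_gradient",
    "glorot",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autodiff core --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an argument needs a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; model tapes can exceed recursion depth
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

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self):
        self.grad = None

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accum(-g) if self.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = bw
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    # -- linear algebra -------------------------------------------------------
    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _parents=(self,))
        out._backward = lambda g: self._accum(g.T) if self.requires_grad else None
        return out

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), _parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(orig)) if self.requires_grad else None
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
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

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _parents=(self,))
        out._backward = lambda g: self._accum(g * mask) if self.requires_grad else None
        return out

    def leaky_relu(self, slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * factor, _parents=(self,))
        out._backward = lambda g: self._accum(g * factor) if self.requires_grad else None
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * (1.0 - y**2)) if self.requires_grad else None
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * y * (1.0 - y)) if self.requires_grad else None
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _parents=(self,))
        out._backward = lambda g: self._accum(g * y) if self.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), _parents=(self,))
        out._backward = lambda g: self._accum(g / self.data) if self.requires_grad else None
        return out

    # -- slicing --------------------------------------------------------------
    def __getitem__(self, key):
        out = Tensor(self.data[key], _parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, key, g)
                self._accum(full)

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def stop_gradient(x: Tensor) -> Tensor:
    """Detach ``x`` from the tape (its value flows forward, no gradient back)."""
    return Tensor(np.array(as_tensor(x).data, copy=True))


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def gather_rows(x: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``x[index]`` (index may repeat; gradients accumulate)."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(x.data[index], _parents=(x,))

    def bw(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, index, g)
            x._accum(full)

    out._backward = bw
    return out


def segment_sum(x: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``num_segments`` buckets given per-row ids."""
    segments = np.asarray(segments, dtype=np.intp)
    data = np.zeros((num_segments,) + x.data.shape[1:], dtype=np.float64)
    np.add.at(data, segments, x.data)
    out = Tensor(data, _parents=(x,))
    out._backward = lambda g: x._accum(g[segments]) if x.requires_grad else None
    return out


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax over rows of ``scores`` grouped by segment id.

    Used for attention normalization over each node's neighborhood.  The
    per-segment max shift is treated as a constant (softmax is shift
    invariant, so gradients are exact).
    """
    segments = np.asarray(segments, dtype=np.intp)
    shift = np.full((num_segments,) + scores.data.shape[1:], -np.inf)
    np.maximum.at(shift, segments, scores.data)
    z = (scores - Tensor(shift[segments])).exp()
    denom = segment_sum(z, segments, num_segments)
    return z / gather_rows(denom, segments)


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g**2
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
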