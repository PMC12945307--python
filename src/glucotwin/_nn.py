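"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical engine behind the physics-informed state networks and the
offline RL agents: a small tape-based autograd (:class:`Tensor`), dense layers,
and an Adam optimizer.  Only the handful of primitives the package needs are
implemented; every primitive's gradient is exercised by finite-difference checks
in the test suite.

All arithmetic is float64 and single-threaded-deterministic given a seeded
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "minimum", "Dense", "MLP", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    # -- helpers -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(-g)
        out._backward = back
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                          other.data.shape))
        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))
        out._backward = back
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def back(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = back
        return out

    # -- elementwise nonlinearities ---------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))
        out._backward = back
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))
        out._backward = back
        return out

    def relu(self):
        y = np.maximum(self.data, 0.0)
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0.0))
        out._backward = back
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g * y)
        out._backward = back
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g / self.data)
        out._backward = back
        return out

    def clip(self, lo: float, hi: float):
        """Clamp; gradient passes only through the unclamped region."""
        y = np.clip(self.data, lo, hi)
        out = Tensor(y, self.requires_grad, (self,))
        inside = (self.data > lo) & (self.data < hi)

        def back(g):
            if self.requires_grad:
                self._accum(g * inside)
        out._backward = back
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))
        out._backward = back
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def back(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)
        out._backward = back
        return out

    # -- backward ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])
    out._backward = back
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise minimum; subgradient assigns ties to the first argument."""
    take_a = a.data <= b.data
    out = Tensor(np.where(take_a, a.data, b.data),
                 a.requires_grad or b.requires_grad, (a, b))

    def back(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * take_a, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~take_a, b.data.shape))
    out._backward = back
    return out


# ---------------------------------------------------------------------------
# Layers and optimizer
# ---------------------------------------------------------------------------

class Dense:
    """Fully connected layer, `uniform(-1/sqrt(fan_in), 1/sqrt(fan_in))` init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = Tensor(rng.uniform(-bound, bound, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(rng.uniform(-bound, bound, (n_out,)), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


_ACTIVATIONS = {
    "tanh": Tensor.tanh,
    "relu": Tensor.relu,
    "sigmoid": Tensor.sigmoid,
}


class MLP:
    """Feed-forward network; hidden activations applied between Dense layers."""

    def __init__(self, sizes, rng: np.random.Generator, activation: str = "relu",
                 out_activation: str | None = None):
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.activation = activation
        self.out_activation = out_activation

    def __call__(self, x: Tensor) -> Tensor:
        act = _ACTIVATIONS[self.activation]
        for layer in self.layers[:-1]:
            x = act(layer(x))
        x = self.layers[-1](x)
        if self.out_activation is not None:
            x = _ACTIVATIONS[self.out_activation](x)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    # weight-space helpers for target networks / checkpointing -------------
    def get_weights(self):
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights):
        for p, w in zip(self.parameters(), weights):
            p.data = w.copy()

    def soft_update_from(self, other: "MLP", tau: float):
        for pt, ps in zip(self.parameters(), other.parameters()):
            pt.data = (1.0 - tau) * pt.data + tau * ps.data


class Adam:
    """Adam with fixed hyperparameters; `zero_grad` clears tapes between steps."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
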