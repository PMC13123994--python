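"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine provides exactly the operations the epitope network needs:
dense matmul, broadcast arithmetic, ReLU/tanh/sigmoid, log/exp/sqrt,
axis reductions, concatenation and row masking.  Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward`, which topologically sorts
the tape.  Everything is float64; graphs here are small (hundreds of
residues), so clarity wins over speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "glorot_uniform", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = np.zeros_like(t.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _coerce(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += -g

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(
                    -g * self.data / other.data**2, other.data.shape
                )

        return self._make(self.data / other.data, (self, other), bwd)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self.grad += g @ other.data.T
            if other.requires_grad:
                other.grad += self.data.T @ g

        return self._make(self.data @ other.data, (self, other), bwd)

    def __pow__(self, exponent: float):
        def bwd(g):
            if self.requires_grad:
                self.grad += g * exponent * self.data ** (exponent - 1)

        return self._make(self.data**exponent, (self,), bwd)

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self.grad += g * mask

        return self._make(self.data * mask, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * (1.0 - out_data**2)

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data * (1.0 - out_data)

        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            if self.requires_grad:
                self.grad += g * out_data

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            if self.requires_grad:
                self.grad += g / self.data

        return self._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        return self**0.5

    # -- reductions & shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self.grad += np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.data.shape)

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def bwd(g):
            if self.requires_grad:
                self.grad += g.reshape(self.data.shape)

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx)

        def bwd(g):
            if self.requires_grad:
                np.add.at(self.grad, idx, g)

        return self._make(self.data[idx], (self,), bwd)

    # -- composites ------------------------------------------------------
    def softmax_vec(self):
        """Softmax over a 1-D tensor (shift-invariant, numerically stable)."""
        shifted = self - float(self.data.max())
        e = shifted.exp()
        return e / e.sum()

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Per-row layer normalization over the last axis."""
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return centered / (var + eps).sqrt() * gamma + beta


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t.grad += piece

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bwd
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam optimizer over a list of Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
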