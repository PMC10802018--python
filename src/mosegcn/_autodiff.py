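"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to train the attention autoencoder and the
mean-teacher GCN by gradient descent: a tape of 2-D/0-D tensors supporting
matmul, broadcast add, elementwise arithmetic, row softmax, row layer-norm,
ReLU, dropout, concatenation and reductions, plus an Adam optimizer.
Gradients are accumulated into ``Tensor.grad`` by ``backward()`` in reverse
topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(value, parents, backward) -> "Tensor":
        out = Tensor(value)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(1.0)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        a, b = self, other
        value = a.value + b.value

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.value.shape))

        return self._node(value, (a, b), bwd)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        a, b = self, other
        value = a.value - b.value

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g, b.value.shape))

        return self._node(value, (a, b), bwd)

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self, other
        value = a.value * b.value

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.value, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.value, b.value.shape))

        return self._node(value, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self, other
        value = a.value / b.value

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.value, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.value / b.value**2, b.value.shape))

        return self._node(value, (a, b), bwd)

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = self._lift(other)
        a, b = self, other
        value = a.value @ b.value

        def bwd(g):
            if a.requires_grad:
                a._accum(g @ b.value.T)
            if b.requires_grad:
                b._accum(a.value.T @ g)

        return self._node(value, (a, b), bwd)

    @property
    def T(self) -> "Tensor":
        a = self
        value = a.value.T

        def bwd(g):
            a._accum(g.T)

        return self._node(value, (a,), bwd)

    # ------------------------------------------------------------ nonlinear
    def relu(self) -> "Tensor":
        a = self
        mask = a.value > 0
        value = a.value * mask

        def bwd(g):
            a._accum(g * mask)

        return self._node(value, (a,), bwd)

    def square(self) -> "Tensor":
        return self * self

    def log_clamped(self, eps: float = 1e-12) -> "Tensor":
        """log(max(x, eps)); gradient 1/max(x, eps) where x > eps else 0."""
        a = self
        clamped = np.maximum(a.value, eps)
        value = np.log(clamped)

        def bwd(g):
            grad = np.where(a.value > eps, g / clamped, 0.0)
            a._accum(grad)

        return self._node(value, (a,), bwd)

    def softmax_rows(self) -> "Tensor":
        """Row-wise softmax of a 2-D tensor."""
        a = self
        shifted = a.value - a.value.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=1, keepdims=True)

        def bwd(g):
            # dL/dx = s * (g - sum(g * s, axis=1, keepdims))
            dot = (g * s).sum(axis=1, keepdims=True)
            a._accum(s * (g - dot))

        return self._node(s, (a,), bwd)

    def layer_norm_rows(self, eps: float = 1e-6) -> "Tensor":
        """Row-wise standardisation (zero mean, unit variance per row)."""
        a = self
        x = a.value
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        var = (xc**2).mean(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        y = xc * inv
        d = x.shape[1]

        def bwd(g):
            gy = g
            # standard layer-norm backward over the row axis
            gxc = gy * inv
            gvar = (gy * xc * (-0.5) * inv**3).sum(axis=1, keepdims=True)
            gmu = (-gxc).sum(axis=1, keepdims=True) + gvar * (-2.0 / d) * xc.sum(
                axis=1, keepdims=True
            )
            a._accum(gxc + gvar * 2.0 * xc / d + gmu / d)

        return self._node(y, (a,), bwd)

    def dropout(self, rate: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; draws the mask from ``rng`` at call time."""
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        if rate == 0.0:
            return self
        a = self
        keep = 1.0 - rate
        mask = (rng.random(a.value.shape) < keep) / keep

        def bwd(g):
            a._accum(g * mask)

        return self._node(a.value * mask, (a,), bwd)

    # ------------------------------------------------------------ reshaping
    def concat_cols(self, others: list["Tensor"]) -> "Tensor":
        parts = [self] + [self._lift(o) for o in others]
        value = np.concatenate([p.value for p in parts], axis=1)
        widths = [p.value.shape[1] for p in parts]

        def bwd(g):
            offset = 0
            for p, w in zip(parts, widths):
                if p.requires_grad:
                    p._accum(g[:, offset : offset + w])
                offset += w

        return self._node(value, tuple(parts), bwd)

    def concat_rows(self, others: list["Tensor"]) -> "Tensor":
        parts = [self] + [self._lift(o) for o in others]
        value = np.concatenate([p.value for p in parts], axis=0)
        heights = [p.value.shape[0] for p in parts]

        def bwd(g):
            offset = 0
            for p, h in zip(parts, heights):
                if p.requires_grad:
                    p._accum(g[offset : offset + h, :])
                offset += h

        return self._node(value, tuple(parts), bwd)

    def rows(self, index: np.ndarray) -> "Tensor":
        """Select rows by integer index array."""
        a = self
        index = np.asarray(index)
        value = a.value[index]

        def bwd(g):
            full = np.zeros_like(a.value)
            np.add.at(full, index, g)
            a._accum(full)

        return self._node(value, (a,), bwd)

    def reshape(self, *shape) -> "Tensor":
        a = self
        value = a.value.reshape(*shape)
        orig = a.value.shape

        def bwd(g):
            a._accum(g.reshape(orig))

        return self._node(value, (a,), bwd)

    # ------------------------------------------------------------ reductions
    def sum(self) -> "Tensor":
        a = self
        value = a.value.sum()

        def bwd(g):
            a._accum(np.full_like(a.value, float(g)))

        return self._node(value, (a,), bwd)

    def mean(self) -> "Tensor":
        a = self
        n = a.value.size
        value = a.value.mean()

        def bwd(g):
            a._accum(np.full_like(a.value, float(g) / n))

        return self._node(value, (a,), bwd)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
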