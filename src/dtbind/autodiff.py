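"""Reverse-mode automatic differentiation over NumPy arrays.

This is the numerical substrate for every trainable component in the
package: a :class:`Tensor` wrapping a float64 ``ndarray`` together with
the small set of differentiable operations the graph encoders and
attention decoders need (dense algebra, row gather/scatter, segment
reductions for message passing, softmax, layer normalisation) and an
:class:`Adam` optimizer.

All arithmetic is float64. Gradients are accumulated by a topological
backward sweep; every primitive is exercised by numerical gradient
checks in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "segment_sum",
    "segment_softmax",
    "softmax",
    "layer_norm",
    "dropout",
    "Adam",
]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
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
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- basic protocol -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape),
                                 dtype=np.float64)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        a, b = self.data, other.data

        def bw(g):
            # promote 1-d operands to row/column matrices, as matmul does
            g2 = g.reshape((1,) + g.shape) if a.ndim == 1 and g.ndim < 2 else g
            g2 = (g2.reshape(g2.shape + (1,))
                  if b.ndim == 1 and g.ndim < a.ndim else g2)
            a2 = a.reshape(1, -1) if a.ndim == 1 else a
            b2 = b.reshape(-1, 1) if b.ndim == 1 else b
            if self.requires_grad:
                ga = g2 @ np.swapaxes(b2, -1, -2)
                self._accumulate(_unbroadcast(ga.reshape(-1) if a.ndim == 1
                                              else ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(a2, -1, -2) @ g2
                other._accumulate(_unbroadcast(gb.reshape(-1) if b.ndim == 1
                                               else gb, other.shape))

        out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), parents=(self,))
        inv = np.argsort(axes) if axes else None

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int):
        """Max along ``axis``; subgradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.max(self.data, axis=axis), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis),
                              np.expand_dims(g, axis), axis)
            self._accumulate(full)

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------
    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * value)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bw
        return out

    def sigmoid(self):
        value = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * value * (1.0 - value))

        out._backward = bw
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - value * value))

        out._backward = bw
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0.0, 1.0, slope)
        out = Tensor(self.data * mask, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bw
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside the interval."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * inside)

        out._backward = bw
        return out


# -- free functions ------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def gather_rows(t: Tensor, index: np.ndarray) -> Tensor:
    """Select rows ``t[index]``; backward scatter-adds into the source."""
    index = np.asarray(index, dtype=np.intp)
    out = Tensor(t.data[index], parents=(t,))

    def bw(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            np.add.at(full, index, g)
            t._accumulate(full)

    out._backward = bw
    return out


def segment_sum(t: Tensor, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given per-row ids."""
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    value = np.zeros((num_segments,) + t.shape[1:], dtype=np.float64)
    np.add.at(value, segment_ids, t.data)
    out = Tensor(value, parents=(t,))

    def bw(g):
        if t.requires_grad:
            t._accumulate(g[segment_ids])

    out._backward = bw
    return out


def segment_softmax(scores: Tensor, segment_ids: np.ndarray,
                    num_segments: int) -> Tensor:
    """Softmax of a 1-d score vector within each segment.

    Used for attention coefficients normalised over each node's
    neighborhood in the graph encoders.
    """
    ids = np.asarray(segment_ids, dtype=np.intp)
    # per-segment max offset for numerical stability (constant wrt grad)
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, ids, scores.data)
    seg_max[~np.isfinite(seg_max)] = 0.0
    shifted = scores - Tensor(seg_max[ids])
    e = shifted.exp()
    denom = segment_sum(e, ids, num_segments)
    return e / gather_rows(denom, ids)


def softmax(t: Tensor, axis: int = -1) -> Tensor:
    shift = t - Tensor(np.max(t.data, axis=axis, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(t: Tensor, gain: Tensor, bias: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis with learnable gain/bias."""
    mu = t.mean(axis=-1, keepdims=True)
    centered = t - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered * (var + eps) ** -0.5 * gain + bias


def dropout(t: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return t
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


class Adam:
    """Adam optimizer over a flat list of parameter tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
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
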