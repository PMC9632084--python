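"""A small reverse-mode automatic differentiation engine over NumPy arrays.

The model components in this package (tiny encoder, combined feature
attention, tagging head) are expressed as compositions of the primitives
defined here. The engine is deliberately minimal: float64 arrays, dynamic
graphs, no broadcasting surprises beyond NumPy's own rules, and gradients
accumulated into ``.grad`` buffers by :meth:`Tensor.backward`.

Primitives: elementwise arithmetic, matmul (with batched leading axes),
row gathering (embedding lookup with scatter-add gradient), concatenation,
axis sums/means, relu/tanh, a masked softmax, and a fused stable
softmax-cross-entropy. Each primitive's gradient is exercised against numeric
differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "masked_softmax", "cross_entropy"]

ArrayLike = Union[np.ndarray, float, int, Sequence]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward

    # -- graph -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self, seed: Optional[np.ndarray] = None) -> None:
        """Accumulate d(self)/d(leaf) into every reachable ``requires_grad`` leaf."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed requires a scalar output")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(seed, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad += g
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _lift(value: Union["Tensor", ArrayLike]) -> "Tensor":
        return value if isinstance(value, Tensor) else Tensor(value)

    def _track(self, *parents: "Tensor") -> bool:
        return any(p.requires_grad or p._parents for p in parents)

    def _make(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad or p._parents for p in parents):
            return Tensor(data, parents=parents, backward=backward)
        return Tensor(data)

    # -- arithmetic ------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self.data + other.data

        def backward(g):
            return (
                (self, _unbroadcast(g, self.shape)),
                (other, _unbroadcast(g, other.shape)),
            )

        return self._make(out, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g):
            return ((self, -g),)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self.data * other.data

        def backward(g):
            return (
                (self, _unbroadcast(g * other.data, self.shape)),
                (other, _unbroadcast(g * self.data, other.shape)),
            )

        return self._make(out, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, scalar: float) -> "Tensor":
        return self * (1.0 / float(scalar))

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out = self.data @ other.data

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (
                (self, _unbroadcast(ga, self.shape)),
                (other, _unbroadcast(gb, other.shape)),
            )

        return self._make(out, (self, other), backward)

    # -- shape / reduction ----------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return ((self, np.broadcast_to(g, self.shape).copy()),)

        return self._make(out, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / count

    def reshape(self, *shape) -> "Tensor":
        out = self.data.reshape(*shape)
        original = self.shape

        def backward(g):
            return ((self, g.reshape(original)),)

        return self._make(out, (self,), backward)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = np.swapaxes(self.data, a, b)

        def backward(g):
            return ((self, np.swapaxes(g, a, b)),)

        return self._make(out, (self,), backward)

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Gather rows along axis 0 (embedding lookup); gradient scatter-adds."""
        idx = np.asarray(indices)
        out = self.data[idx]

        def backward(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            return ((self, acc),)

        return self._make(out, (self,), backward)

    # -- nonlinearities --------------------------------------------------

    def relu(self) -> "Tensor":
        out = np.maximum(self.data, 0.0)

        def backward(g):
            return ((self, g * (self.data > 0)),)

        return self._make(out, (self,), backward)

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)

        def backward(g):
            return ((self, g * (1.0 - out * out)),)

        return self._make(out, (self,), backward)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data: ArrayLike):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    """Concatenate along ``axis``; the gradient splits back into the parts."""
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        parts = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * g.ndim
            index[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            parts.append((t, g[tuple(index)]))
        return tuple(parts)

    if any(t.requires_grad or t._parents for t in tensors):
        return Tensor(out, parents=tuple(tensors), backward=backward)
    return Tensor(out)


def masked_softmax(logits: Tensor, mask: Optional[np.ndarray] = None, axis: int = -1) -> Tensor:
    """Numerically stable softmax along ``axis``; masked entries get weight 0.

    ``mask`` is a boolean array broadcastable to ``logits`` with True marking
    valid entries. Every softmax row must contain at least one valid entry.
    """
    x = logits.data
    if mask is not None:
        x = np.where(mask, x, -np.inf)
    x_max = np.max(x, axis=axis, keepdims=True)
    # Rows with all -inf would produce NaN; forbidden by the m_i >= 1 contract.
    e = np.exp(x - x_max)
    total = e.sum(axis=axis, keepdims=True)
    s = e / total

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return ((logits, s * (g - dot)),)

    if logits.requires_grad or logits._parents:
        return Tensor(s, parents=(logits,), backward=backward)
    return Tensor(s)


def cross_entropy(
    logits: Tensor, targets: np.ndarray, mask: Optional[np.ndarray] = None
) -> Tensor:
    """Mean negative log-softmax of the target class over unmasked rows.

    ``logits`` has shape ``(n, C)``, ``targets`` integer shape ``(n,)`` and
    ``mask`` boolean shape ``(n,)`` (True = contributes to the loss).
    """
    x = logits.data
    n = x.shape[0]
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("cross_entropy: all positions are masked")
    x_max = x.max(axis=1, keepdims=True)
    lse = x_max[:, 0] + np.log(np.exp(x - x_max).sum(axis=1))
    nll = lse - x[np.arange(n), targets]
    loss = float((nll * mask).sum() / count)

    def backward(g):
        soft = np.exp(x - x_max)
        soft /= soft.sum(axis=1, keepdims=True)
        soft[np.arange(n), targets] -= 1.0
        soft *= (mask / count)[:, None] * g
        return ((logits, soft),)

    if logits.requires_grad or logits._parents:
        return Tensor(loss, parents=(logits,), backward=backward)
    return Tensor(loss)
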