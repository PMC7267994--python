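"""A minimal reverse-mode automatic-differentiation engine over numpy arrays.

Only the operations needed by the relation model are provided: broadcasting
arithmetic, matrix products, the usual pointwise nonlinearities, embedding
lookup, concatenation/stacking, masked max-pooling and a fused softmax
cross-entropy.  Everything is float64 and deterministic, which keeps the
finite-difference gradient checks in the test suite tight.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: Array | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[Array], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, grad: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: Array | None = None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------

    def __add__(self, other: "Tensor | float") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other: "Tensor | float") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other: "Tensor | float") -> "Tensor":
        return self + (-as_tensor(other))

    def __matmul__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g: Array) -> None:
            if self.requires_grad:
                grad = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                grad = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(grad, other.shape))

        out._backward = backward
        return out


def as_tensor(value: "Tensor | Array | float") -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)
    out = Tensor(t, parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(g * (1.0 - t * t))

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g: Array) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * g.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(g[tuple(index)])

    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def backward(g: Array) -> None:
        slabs = np.split(g, len(tensors), axis=axis)
        for t, slab in zip(tensors, slabs):
            if t.requires_grad:
                t._accumulate(np.squeeze(slab, axis=axis))

    out._backward = backward
    return out


def narrow(x: Tensor, start: int, size: int, axis: int = -1) -> Tensor:
    """Slice ``size`` elements starting at ``start`` along ``axis``."""
    index = [slice(None)] * x.data.ndim
    index[axis] = slice(start, start + size)
    index_t = tuple(index)
    out = Tensor(x.data[index_t], parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[index_t] = g
            x._accumulate(full)

    out._backward = backward
    return out


def timestep(x: Tensor, t: int) -> Tensor:
    """Select ``x[:, t, :]`` from a (batch, time, dim) tensor."""
    out = Tensor(x.data[:, t, :], parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x._accumulate(full)

    out._backward = backward
    return out


def embedding(table: Tensor, idx: Array) -> Tensor:
    """Row lookup ``table[idx]``; gradients accumulate into the looked-up rows."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(table.data[idx], parents=(table,))

    def backward(g: Array) -> None:
        if table.requires_grad:
            grad = np.zeros_like(table.data)
            np.add.at(grad, idx, g)
            table._accumulate(grad)

    out._backward = backward
    return out


def masked_max(x: Tensor, mask: Array, axis: int = 1) -> Tensor:
    """Max over ``axis`` restricted to positions where ``mask`` is true.

    ``mask`` broadcasts against ``x`` (typically (B, T) against (B, T, D)).
    Every slice must contain at least one unmasked position.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim == x.data.ndim - 1:
        mask = np.expand_dims(mask, -1)
    mask = np.broadcast_to(mask, x.data.shape)
    if not mask.any(axis=axis).all():
        raise ValueError("masked_max over an empty set")
    masked = np.where(mask, x.data, -np.inf)
    out_data = masked.max(axis=axis)
    argmax = masked.argmax(axis=axis)
    out = Tensor(out_data, parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.put_along_axis(full, np.expand_dims(argmax, axis), np.expand_dims(g, axis), axis)
            x._accumulate(full)

    out._backward = backward
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or ``p == 0``."""
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: Array) -> tuple[Tensor, Array]:
    """Mean cross-entropy over a (B, C) batch; returns (loss, probabilities)."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    batch = logits.data.shape[0]
    nll = -np.log(np.clip(probs[np.arange(batch), labels], 1e-300, None))
    out = Tensor(nll.mean(), parents=(logits,))

    def backward(g: Array) -> None:
        if logits.requires_grad:
            grad = probs.copy()
            grad[np.arange(batch), labels] -= 1.0
            logits._accumulate(g * grad / batch)

    out._backward = backward
    return out, probs


def mean(x: Tensor) -> Tensor:
    out = Tensor(x.data.mean(), parents=(x,))

    def backward(g: Array) -> None:
        if x.requires_grad:
            x._accumulate(np.full_like(x.data, g / x.data.size))

    out._backward = backward
    return out
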