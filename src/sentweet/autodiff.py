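"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough tensor calculus for the classifier zoo: broadcasting arithmetic,
matmul (2-d and batched 3-d x 2-d), the activations and reductions the
architectures need, slicing/concatenation for gate splitting and filter
merging, and a fused softmax cross-entropy with per-class weights.  Graphs
are built eagerly by the forward pass; ``Tensor.backward()`` runs a
topological sweep accumulating gradients.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph machinery ---------------------------------------------------

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
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(grad * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __matmul__(self, other):
        other = self._coerce(other)
        out = self.data @ other.data

        def backward(grad):
            if self.requires_grad:
                self._accumulate(_unbroadcast(grad @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ grad, other.shape)
                )

        return Tensor(out, parents=(self, other), backward=backward)

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * mask)

        return Tensor(self.data * mask, parents=(self,), backward=backward)

    def tanh(self):
        out = np.tanh(self.data)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * (1.0 - out**2))

        return Tensor(out, parents=(self,), backward=backward)

    def sigmoid(self):
        out = np.empty_like(self.data)
        pos = self.data >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        ex = np.exp(self.data[~pos])
        out[~pos] = ex / (1.0 + ex)

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad * out * (1.0 - out))

        return Tensor(out, parents=(self,), backward=backward)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.shape

        def backward(grad):
            if self.requires_grad:
                self._accumulate(grad.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def __getitem__(self, key):
        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = grad
                self._accumulate(full)

        return Tensor(self.data[key], parents=(self,), backward=backward)

    def max(self, axis: int):
        """Max reduction along ``axis`` (gradient flows to first argmax)."""
        idx = np.expand_dims(np.argmax(self.data, axis=axis), axis)
        out = np.take_along_axis(self.data, idx, axis=axis).squeeze(axis)

        def backward(grad):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, idx, np.expand_dims(grad, axis), axis=axis)
                self._accumulate(full)

        return Tensor(out, parents=(self,), backward=backward)

    def sum(self, axis=None):
        def backward(grad):
            if self.requires_grad:
                if axis is None:
                    self._accumulate(np.full_like(self.data, grad))
                else:
                    self._accumulate(np.broadcast_to(np.expand_dims(grad, axis), self.shape).copy())

        return Tensor(self.data.sum(axis=axis), parents=(self,), backward=backward)

    def mean(self, axis=None):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis) * (1.0 / n)


def concatenate(tensors: list[Tensor], axis: int = -1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0, *sizes])

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                index = [slice(None)] * grad.ndim
                index[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(index)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def pad_time_left(t: Tensor, amount: int) -> Tensor:
    """Zero-pad a (batch, time, channels) tensor on the left of the time axis."""
    if amount == 0:
        return t

    def backward(grad):
        if t.requires_grad:
            t._accumulate(grad[:, amount:, :])

    padded = np.pad(t.data, ((0, 0), (amount, 0), (0, 0)))
    return Tensor(padded, parents=(t,), backward=backward)


def dropout(t: Tensor, rate: float, rng: np.random.Generator, train: bool) -> Tensor:
    """Inverted dropout; identity at inference or rate 0."""
    if not train or rate <= 0.0:
        return t
    mask = (rng.random(t.shape) >= rate) / (1.0 - rate)
    return t * Tensor(mask)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: Tensor, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> Tensor:
    """Mean (class-weighted) categorical cross-entropy over a batch.

    ``labels`` are integer class indices; ``class_weights`` reweights each
    example by the weight of its gold class.
    """
    probs = softmax(logits.data)
    n = logits.shape[0]
    weights = np.ones(n) if class_weights is None else class_weights[labels]
    losses = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None))
    total_weight = weights.sum()
    loss = float((weights * losses).sum() / total_weight)

    def backward(grad):
        if logits.requires_grad:
            g = probs.copy()
            g[np.arange(n), labels] -= 1.0
            g *= (weights / total_weight)[:, None]
            logits._accumulate(grad * g)

    return Tensor(loss, parents=(logits,), backward=backward)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer (beta1 0.9, beta2 0.999, eps 1e-8)."""

    def __init__(self, params: list[Parameter], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
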