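"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Just enough machinery for a small vision transformer: broadcasting
elementwise arithmetic, matmul, ReLU/GELU, numerically stable sigmoid and
softmax, layer normalization, reshape/transpose, reductions, and a fused
binary cross-entropy-with-logits loss. Gradients are accumulated on leaf
tensors by :meth:`Tensor.backward` via a topological sweep of the tape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ---------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, _parents=parents)
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        grad = _unbroadcast(grad, self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(g)
            other._accum(g)

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        a, b = self.data, other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(b, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(a, -1, -2) @ g)

        return self._make(a @ b, (self, other), backward)

    __matmul__ = matmul

    # -- nonlinearities ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def gelu(self) -> "Tensor":
        # tanh approximation; exact enough for a trained-from-scratch model
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        inner = c * (x + 0.044715 * x**3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def backward(g):
            dinner = c * (1.0 + 3 * 0.044715 * x**2)
            dt = (1.0 - t**2) * dinner
            self._accum(g * (0.5 * (1.0 + t) + 0.5 * x * dt))

        return self._make(out, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500))),
            np.exp(np.clip(self.data, -500, 500))
            / (1.0 + np.exp(np.clip(self.data, -500, 500))),
        )

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def softmax(self) -> "Tensor":
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=-1, keepdims=True)
            self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    def layer_norm(self, gain: "Tensor", bias: "Tensor", eps: float = 1e-6) -> "Tensor":
        """Normalize over the last axis, then scale and shift."""
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = xhat * gain.data + bias.data

        def backward(g):
            if gain.requires_grad:
                gain._accum((g * xhat).reshape(-1, x.shape[-1]).sum(axis=0))
            if bias.requires_grad:
                bias._accum(g.reshape(-1, x.shape[-1]).sum(axis=0))
            if self.requires_grad:
                n = x.shape[-1]
                gx = g * gain.data
                dxhat_sum = gx.sum(axis=-1, keepdims=True)
                dxhat_dot = (gx * xhat).sum(axis=-1, keepdims=True)
                self._accum(inv * (gx - dxhat_sum / n - xhat * dxhat_dot / n))

        return self._make(out, (self, gain, bias), backward)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward(g):
            self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                g2 = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g2, self.data.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- losses --------------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray, pos_weight: float = 1.0) -> "Tensor":
        """Weighted-mean binary cross-entropy on logits (numerically stable).

        ``pos_weight`` > 1 upweights foreground pixels, the usual remedy for
        sparse segmentation targets; 1.0 gives the plain mean.
        """
        z = self.data
        t = np.asarray(targets, dtype=np.float64)
        w = np.where(t > 0.5, pos_weight, 1.0)
        loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))) * w
        total_w = w.sum()

        def backward(g):
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
            self._accum(g * w * (s - t) / total_w)

        return self._make(loss.sum() / total_w, (self,), backward)

    # -- backward ------------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
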