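"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the operations needed by the segmentation and regression networks are
implemented.  Tensors are unbatched: activations are ``(C, H, W)`` arrays
(gradient accumulation across samples replaces batching, which the
variable angular resolution of polar images makes impossible anyway).

All floating point work is float32; gradients are accumulated in the
``grad`` attribute of leaf tensors.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data : np.ndarray
        Value of the node (float32).
    parents : tuple of (Tensor, callable)
        Each callable maps the output gradient to the parent's gradient
        contribution.
    requires_grad : bool
        Leaves with ``requires_grad`` collect gradients in ``.grad``.
    """

    __slots__ = ("data", "grad", "parents", "requires_grad", "_ctx")

    def __init__(self, data, parents=(), requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.parents = parents
        self.requires_grad = requires_grad
        self._ctx = None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def backward(self, grad=None):
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=np.float32)

        # topological order
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                if id(parent) not in seen:
                    stack.append((parent, False))

        grads = {id(self): grad}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, backfn in node.parents:
                pg = backfn(g)
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(g, other.shape)),
            ),
        )
        return out

    __radd__ = __add__

    def __sub__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data - other.data,
            parents=(
                (self, lambda g: _unbroadcast(g, self.shape)),
                (other, lambda g: _unbroadcast(-g, other.shape)),
            ),
        )

    def __rsub__(self, other):
        return _as_tensor(other) - self

    def __mul__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data * other.data,
            parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return Tensor(
            self.data / other.data,
            parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / (other.data**2), other.shape
                    ),
                ),
            ),
        )

    def __neg__(self):
        return Tensor(-self.data, parents=((self, lambda g: -g),))

    # -- nonlinearities --------------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor(self.data * mask, parents=((self, lambda g: g * mask),))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor(s, parents=((self, lambda g: g * s * (1.0 - s)),))

    def softplus(self):
        # numerically stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        x = self.data
        out = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))
        sig = 1.0 / (1.0 + np.exp(-x))
        return Tensor(out, parents=((self, lambda g: g * sig),))

    def log(self):
        return Tensor(
            np.log(self.data), parents=((self, lambda g: g / self.data),)
        )

    def abs(self):
        sign = np.sign(self.data)
        return Tensor(np.abs(self.data), parents=((self, lambda g: g * sign),))

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def back(g):
            if axis is None:
                return np.broadcast_to(g, shape).astype(np.float32)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, shape).astype(np.float32)

        return Tensor(out_data, parents=((self, back),))

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor(
            self.data.reshape(*shape),
            parents=((self, lambda g: g.reshape(orig)),),
        )

    def __getitem__(self, idx):
        shape = self.shape

        def back(g):
            out = np.zeros(shape, dtype=np.float32)
            np.add.at(out, idx, g)
            return out

        return Tensor(self.data[idx], parents=((self, back),))


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self):
        self.grad = None


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.astype(np.float32).reshape(shape)
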