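"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to train the encoder stack: broadcast-aware
elementwise ops, batched matmul, reductions with max/argmax routing, an
unfold (im2col) primitive that conv1d and max-pooling are built from,
row gather/update for the sparse-attention active set, and a fused
softmax-cross-entropy loss.  Gradients accumulate into ``Tensor.grad`` after
calling ``backward()`` on a scalar.

Everything is CPU NumPy; float32 is used for model parameters, but the
engine itself follows the dtype of its inputs.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "cross_entropy", "unfold", "gather_rows",
           "row_update"]


def _unbroadcast(grad: np.ndarray, shape) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- helpers ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, g))
        self.grad += _unbroadcast(g, self.data.shape)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # scalar fast path: python scalars promote weakly, preserving
            # the tensor dtype (float32 stays float32)
            out_data = self.data + other

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g)

            return self._make(out_data, (self,), backward_s)
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)
        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out_data = self.data * other

            def backward_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            return self._make(out_data, (self,), backward_s)
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = self._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(g @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)
        return self._make(np.log(self.data), (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(np.where(mask, self.data, 0), (self,), backward)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        neg_part = alpha * (np.exp(np.minimum(self.data, 0)) - 1.0)
        out_data = np.where(pos, self.data, neg_part)

        def backward(g):
            if self.requires_grad:
                self._accum(g * np.where(pos, 1.0, neg_part + alpha))

        return self._make(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max along one axis; gradient routes to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis),
                                      axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            grad = np.zeros_like(self.data)
            np.put_along_axis(grad, np.expand_dims(idx, axis), gg, axis=axis)
            self._accum(grad)

        return self._make(out_data, (self,), backward)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))
        return self._make(np.swapaxes(self.data, a, b), (self,), backward)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(np.transpose(g, inv))

        return self._make(np.transpose(self.data, axes), (self,), backward)

    # -- softmax (fused primitive: one output array, memory-lean) -------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        np.exp(z, out=z)
        z /= z.sum(axis=axis, keepdims=True)
        out_data = z

        def backward(g):
            if not self.requires_grad:
                return
            s = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - s))

        return self._make(out_data, (self,), backward)

    # -- autodiff driver -------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# Structured primitives
# ---------------------------------------------------------------------------

def unfold(x: Tensor, kernel: int, stride: int, pad: int,
           fill: float = 0.0) -> Tensor:
    """im2col along axis 1: ``[N, L, C] -> [N, L', K, C]`` windows.

    ``fill`` pads the boundary (0 for convolution, -inf for max pooling).
    Backward scatter-adds window gradients back into the padded frame.
    """
    N, L, C = x.data.shape
    Lp = L + 2 * pad
    Lo = (Lp - kernel) // stride + 1
    padded = np.full((N, Lp, C), fill, dtype=x.data.dtype)
    padded[:, pad:pad + L] = x.data
    view = np.lib.stride_tricks.sliding_window_view(padded, kernel, axis=1)
    # view: [N, Lp-K+1, C, K] -> stride and reorder to [N, Lo, K, C]
    out_data = np.ascontiguousarray(
        view[:, ::stride][:, :Lo].transpose(0, 1, 3, 2))

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.zeros((N, Lp, C), dtype=g.dtype)
        for k in range(kernel):
            # for fixed k the strided targets are distinct, so += is safe
            gp[:, k:k + stride * Lo:stride] += g[:, :, k, :]
        x._accum(gp[:, pad:pad + L])

    return x._make(out_data, (x,), backward)


def gather_rows(x: Tensor, idx: np.ndarray, axis: int) -> Tensor:
    """Take rows ``idx`` along ``axis``; backward scatter-adds them back."""
    idx = np.asarray(idx)
    out_data = np.take(x.data, idx, axis=axis)

    def backward(g):
        if not x.requires_grad:
            return
        grad = np.zeros_like(x.data)
        sl = [slice(None)] * x.data.ndim
        sl[axis] = idx
        np.add.at(grad, tuple(sl), g)
        x._accum(grad)

    return x._make(out_data, (x,), backward)


def row_update(base: Tensor, rows: Tensor, idx: np.ndarray,
               axis: int) -> Tensor:
    """Overwrite ``base`` rows ``idx`` (along ``axis``) with ``rows``.

    Gradient to the overwritten base rows is zero; ``rows`` receives the
    gradient of its slots.
    """
    idx = np.asarray(idx)
    out_data = np.array(base.data, copy=True)
    sl = [slice(None)] * base.data.ndim
    sl[axis] = idx
    out_data[tuple(sl)] = rows.data

    def backward(g):
        if base.requires_grad:
            gb = np.array(g, copy=True)
            gb[tuple(sl)] = 0
            base._accum(gb)
        if rows.requires_grad:
            rows._accum(g[tuple(sl)])

    return base._make(out_data, (base, rows), backward)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy over a batch, fused with softmax.

    ``logits``: [N, K]; ``labels``: int array [N].  Backward is the textbook
    ``(softmax - onehot) / N``.
    """
    labels = np.asarray(labels)
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    nll = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300))
    out_data = np.array(nll.mean(), dtype=z.dtype)

    def backward(g):
        if not logits.requires_grad:
            return
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(np.asarray(g) * grad / n)

    return logits._make(out_data, (logits,), backward)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment optimiser with bias correction (standard defaults)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
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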