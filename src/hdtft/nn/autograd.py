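"""Minimal reverse-mode autograd over numpy arrays.

Implements exactly the operations the model needs: broadcasting
arithmetic, batched matmul, ELU/sigmoid/tanh, reductions, concatenation,
indexing (for embeddings) and a masked softmax that produces *exact* zeros
at masked positions, which makes causal masking and previous-session
masking exact rather than approximate.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_grad_enabled = True


@contextmanager
def no_grad():
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


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
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make numpy defer to the reflected operators instead of building
    # object arrays when an ndarray meets a Tensor
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------ plumbing

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----------------------------------------------------------- operators

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw_safe(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw_safe)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other.reciprocal()
        return self * (1.0 / other)

    def reciprocal(self):
        a = self
        out_data = 1.0 / a.data

        def bw(g):
            a._accumulate(_unbroadcast(-g * out_data * out_data, a.data.shape))

        return Tensor._make(out_data, (a,), bw)

    def matmul(self, other):
        a, b = self, Tensor._wrap(other)

        def bw(g):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    __matmul__ = matmul

    def grouped_linear(self, weight: "Tensor") -> "Tensor":
        """Per-group linear map: x[..., V, n_in] @ W[V, n_in, n_out] ->
        [..., V, n_out], contracting batch dimensions directly (no
        broadcast-matmul intermediates)."""
        a, b = self, Tensor._wrap(weight)
        V, n_in, n_out = b.data.shape
        lead = a.data.shape[:-2]
        # [..., V, n_in] -> [V, batch, n_in] so matmul dispatches to BLAS
        xt = np.moveaxis(a.data, -2, 0).reshape(V, -1, n_in)

        def bw(g):
            gt = np.moveaxis(g, -2, 0).reshape(V, -1, n_out)
            if a.requires_grad:
                gx = np.matmul(gt, np.swapaxes(b.data, -1, -2))
                a._accumulate(
                    np.moveaxis(gx.reshape(V, *lead, n_in), 0, -2)
                )
            if b.requires_grad:
                b._accumulate(np.matmul(np.swapaxes(xt, -1, -2), gt))

        out = np.moveaxis(
            np.matmul(xt, b.data).reshape(V, *lead, n_out), 0, -2
        )
        return Tensor._make(np.ascontiguousarray(out), (a, b), bw)

    # --------------------------------------------------------- activations

    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bw(g):
            a._accumulate(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))

        def bw(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), bw)

    def elu(self, alpha: float = 1.0):
        a = self
        neg = a.data < 0
        out_data = np.where(neg, alpha * np.expm1(np.clip(a.data, -60, 0)), a.data)

        def bw(g):
            local = np.where(neg, out_data + alpha, 1.0)
            a._accumulate(g * local)

        return Tensor._make(out_data, (a,), bw)

    # ----------------------------------------------------------- shape ops

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bw(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(*shape), (a,), bw)

    def swapaxes(self, ax1: int, ax2: int):
        a = self

        def bw(g):
            a._accumulate(np.swapaxes(g, ax1, ax2))

        return Tensor._make(np.swapaxes(a.data, ax1, ax2), (a,), bw)

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._make(
            a.data.sum(axis=axis, keepdims=keepdims), (a,), bw
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw
        )

    def masked_softmax(self, mask: np.ndarray, axis: int = -1) -> "Tensor":
        """Softmax over ``axis`` restricted to positions where ``mask`` is
        True; masked positions get *exactly* 0 probability and contribute
        nothing to the normalization. Rows with no allowed position yield
        all-zero rows."""
        a = self
        mask = np.broadcast_to(np.asarray(mask, dtype=bool), a.data.shape)
        neg = np.where(mask, a.data, -np.inf)
        mx = np.max(neg, axis=axis, keepdims=True)
        mx = np.where(np.isfinite(mx), mx, 0.0)
        e = np.where(mask, np.exp(np.clip(a.data - mx, -700, 60)), 0.0)
        denom = e.sum(axis=axis, keepdims=True)
        safe = np.where(denom > 0, denom, 1.0)
        out_data = e / safe

        def bw(g):
            inner = (g * out_data).sum(axis=axis, keepdims=True)
            a._accumulate(out_data * (g - inner))

        return Tensor._make(out_data, (a,), bw)


def parameter(
    rng: np.random.Generator, *shape: int, scale: float | None = None
) -> Tensor:
    """Glorot-style initialized trainable tensor."""
    if scale is None:
        fan_in = shape[-2] if len(shape) >= 2 else shape[-1]
        scale = 1.0 / np.sqrt(max(fan_in, 1))
    t = Tensor(rng.uniform(-scale, scale, size=shape))
    t.requires_grad = True
    return t


def zeros_parameter(*shape: int) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


class Adam:
    """Adam optimizer over a list of parameters."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
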