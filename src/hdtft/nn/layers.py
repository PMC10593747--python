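"""Neural building blocks: gated residual networks, variable selection,
gated recurrence and single-headed causal attention."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, parameter, zeros_parameter


class Module:
    """Base class with recursive parameter collection."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            p.data = a.copy()


class Dense(Module):
    def __init__(self, rng, n_in: int, n_out: int, bias: bool = True):
        self.W = parameter(rng, n_in, n_out)
        self.b = zeros_parameter(n_out) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out if self.b is None else out + self.b


class GroupedDense(Module):
    """V parallel dense layers with distinct weights, applied along a
    variable axis: input [..., V, n_in] -> [..., V, n_out]."""

    def __init__(self, rng, n_vars: int, n_in: int, n_out: int):
        self.n_in, self.n_out, self.n_vars = n_in, n_out, n_vars
        self.W = parameter(rng, n_vars, n_in, n_out)
        self.b = zeros_parameter(n_vars, n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x.grouped_linear(self.W) + self.b


class LayerNorm(Module):
    """Normalization over the last axis with learnable gain and bias;
    used between pipeline modules to stabilize optimization."""

    def __init__(self, n: int, eps: float = 1e-5):
        self.gain = zeros_parameter(n)
        self.gain.data[:] = 1.0
        self.bias = zeros_parameter(n)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).sqrt().reciprocal()
        return centered * inv * self.gain + self.bias


class GRN(Module):
    """Gated residual network.

    Four dense layers (hidden, projection, gate, value) with an ELU
    nonlinearity and a sigmoid gate deciding whether to pass the transform
    or fall back to the (optionally projected) skip connection:

        h   = ELU(W1 x + Wc c + b1)
        eta = W2 h + b2
        out = skip(x) + sigmoid(W3 eta + b3) * (W4 eta + b4)
    """

    def __init__(
        self,
        rng,
        n_in: int,
        hidden: int,
        n_out: int | None = None,
        context_dim: int | None = None,
    ):
        n_out = hidden if n_out is None else n_out
        self.fc1 = Dense(rng, n_in, hidden)
        self.ctx = (
            Dense(rng, context_dim, hidden, bias=False)
            if context_dim
            else None
        )
        self.fc2 = Dense(rng, hidden, n_out)
        self.gate = Dense(rng, n_out, n_out)
        self.value = Dense(rng, n_out, n_out)
        self.skip = Dense(rng, n_in, n_out) if n_in != n_out else None

    def __call__(self, x: Tensor, context: Tensor | None = None) -> Tensor:
        h = self.fc1(x)
        if context is not None:
            if self.ctx is None:
                raise ValueError("GRN built without a context projection")
            h = h + self.ctx(context)
        eta = self.fc2(h.elu())
        gated = self.gate(eta).sigmoid() * self.value(eta)
        res = x if self.skip is None else self.skip(x)
        return res + gated


class GroupedGRN(Module):
    """Per-variable GRNs (distinct weights per variable) along axis -2."""

    def __init__(self, rng, n_vars: int, n_in: int, hidden: int):
        self.fc1 = GroupedDense(rng, n_vars, n_in, hidden)
        self.fc2 = GroupedDense(rng, n_vars, hidden, hidden)
        self.gate = GroupedDense(rng, n_vars, hidden, hidden)
        self.value = GroupedDense(rng, n_vars, hidden, hidden)
        self.skip = GroupedDense(rng, n_vars, n_in, hidden) if n_in != hidden else None

    def __call__(self, x: Tensor) -> Tensor:
        eta = self.fc2(self.fc1(x).elu())
        gated = self.gate(eta).sigmoid() * self.value(eta)
        res = x if self.skip is None else self.skip(x)
        return res + gated


class VariableSelection(Module):
    """Fuse per-variable embeddings with a learned simplex of weights.

    Weights come from a GRN over the flattened embeddings followed by a
    masked softmax over the variable axis; each variable is independently
    transformed by its own GRN before the weighted sum. Masked variables
    receive exactly zero weight and their embeddings are zeroed, so they
    cannot influence the output.
    """

    def __init__(
        self, rng, n_vars: int, hidden: int, context_dim: int | None = None
    ):
        if n_vars < 1:
            raise ValueError("variable selection needs at least one variable")
        self.n_vars = n_vars
        self.hidden = hidden
        self.weight_grn = GRN(
            rng, n_vars * hidden, hidden, n_out=n_vars, context_dim=context_dim
        )
        self.var_grns = GroupedGRN(rng, n_vars, hidden, hidden)

    def __call__(
        self,
        embeds: Tensor,
        context: Tensor | None = None,
        var_mask: np.ndarray | None = None,
    ) -> tuple[Tensor, Tensor]:
        lead = embeds.shape[:-2]
        if var_mask is None:
            var_mask = np.ones(embeds.shape[:-1], dtype=bool)
        else:
            var_mask = np.broadcast_to(
                np.asarray(var_mask, bool), embeds.shape[:-1]
            )
        embeds = embeds * var_mask[..., None].astype(float)
        flat = embeds.reshape(*lead, self.n_vars * self.hidden)
        logits = self.weight_grn(flat, context)
        weights = logits.masked_softmax(var_mask, axis=-1)
        transformed = self.var_grns(embeds)
        fused = (weights.reshape(*lead, self.n_vars, 1) * transformed).sum(axis=-2)
        return fused, weights


class GRUCell(Module):
    """Gated recurrent unit:

        z = sigmoid(x Wz + h Uz + bz)
        r = sigmoid(x Wr + h Ur + br)
        n = tanh(x Wn + (r * h) Un + bn)
        h' = (1 - z) * h + z * n
    """

    def __init__(self, rng, n_in: int, hidden: int):
        self.xz = Dense(rng, n_in, hidden)
        self.hz = Dense(rng, hidden, hidden, bias=False)
        self.xr = Dense(rng, n_in, hidden)
        self.hr = Dense(rng, hidden, hidden, bias=False)
        self.xn = Dense(rng, n_in, hidden)
        self.hn = Dense(rng, hidden, hidden, bias=False)

    def __call__(self, x: Tensor, h: Tensor) -> Tensor:
        z = (self.xz(x) + self.hz(h)).sigmoid()
        r = (self.xr(x) + self.hr(h)).sigmoid()
        n = (self.xn(x) + self.hn(r * h)).tanh()
        return (1.0 - z) * h + z * n


class GRU(Module):
    """Unidirectional GRU over [B, T, D]; padded steps carry state through
    unchanged so padding never updates the recurrence."""

    def __init__(self, rng, n_in: int, hidden: int):
        self.cell = GRUCell(rng, n_in, hidden)
        self.hidden = hidden

    def __call__(
        self, x: Tensor, h0: Tensor, pad_mask: np.ndarray
    ) -> Tensor:
        B, T, _ = x.shape
        if T == 0:
            raise ValueError("empty sequence")
        h = h0
        outs = []
        for t in range(T):
            xt = x[:, t, :]
            h_new = self.cell(xt, h)
            m = pad_mask[:, t : t + 1].astype(float)
            h = m * h_new + (1.0 - m) * h
            outs.append(h.reshape(B, 1, self.hidden))
        return Tensor.concat(outs, axis=1)


class CausalSelfAttention(Module):
    """Single-headed scaled dot-product attention where query t attends
    only to key positions <= t; future positions receive exactly zero
    weight."""

    def __init__(self, rng, hidden: int):
        self.q = Dense(rng, hidden, hidden)
        self.k = Dense(rng, hidden, hidden)
        self.v = Dense(rng, hidden, hidden)
        self.out = Dense(rng, hidden, hidden)
        self.scale = 1.0 / np.sqrt(hidden)

    def __call__(
        self, x: Tensor, pad_mask: np.ndarray
    ) -> tuple[Tensor, Tensor]:
        B, T, H = x.shape
        q, k, v = self.q(x), self.k(x), self.v(x)
        scores = (q @ k.swapaxes(-1, -2)) * self.scale
        causal = np.tril(np.ones((T, T), dtype=bool))
        allowed = causal[None, :, :] & pad_mask[:, None, :].astype(bool)
        weights = scores.masked_softmax(allowed, axis=-1)
        return self.out(weights @ v), weights


class Embedding(Module):
    """Categorical embedding table."""

    def __init__(self, rng, n_categories: int, hidden: int):
        self.table = parameter(rng, n_categories, hidden, scale=0.1)

    def __call__(self, codes: np.ndarray) -> Tensor:
        return self.table[np.asarray(codes, dtype=int)]


class ContinuousEmbedding(Module):
    """Per-variable linear embedding of scalar values:
    [..., V] -> [..., V, H]."""

    def __init__(self, rng, n_vars: int, hidden: int):
        self.W = parameter(rng, n_vars, hidden, scale=0.5)
        self.b = zeros_parameter(n_vars, hidden)

    def __call__(self, x: Tensor | np.ndarray) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        return x.reshape(*x.shape, 1) * self.W + self.b
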