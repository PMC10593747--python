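"""Modified temporal-fusion classifier for real-time dual outcome
prediction.

Pipeline per Figure-2-style processing: per-variable embeddings ->
variable selection (static and per-timestep temporal) -> gated recurrent
local encoding initialized from static context -> single-headed causally
masked self-attention -> GRN classifier with three sigmoid heads (IDH-1,
IDH-2, IDHTN), one probability triple per recorded timestep.

Previous sessions are pushed through the *same* embedding/selection/
recurrence/attention stack and their terminal representations re-enter the
static variable set of the current session; unavailable slots carry
exactly zero weight and zero value, so they cannot influence predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import FeatureBundle, NormalizationStats
from .nn import (
    Adam,
    CausalSelfAttention,
    ContinuousEmbedding,
    Dense,
    Embedding,
    GRN,
    GRU,
    LayerNorm,
    Module,
    Tensor,
    VariableSelection,
    no_grad,
)
from .schema import CATEGORICAL, VariableSchema

OUTCOME_HEADS = ("idh1", "idh2", "idhtn")


@dataclass
class ModelConfig:
    hidden_size: int = 64
    dropout: float = 0.0
    max_previous_sessions: int = 5
    max_timesteps: int = 24
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 30
    early_stopping_patience: int = 5
    grad_clip: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_size <= 0:
            raise ValueError("hidden_size must be positive")
        if self.max_previous_sessions < 0:
            raise ValueError("max_previous_sessions must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class AttentionReport:
    """Attention weights for one batch/session; each weight group is
    nonnegative and sums to one over its variable (or key) axis."""

    static_variable_weights: np.ndarray   # [B, n_static + K]
    timevarying_variable_weights: np.ndarray  # [B, T, n_temporal]
    temporal_attention: np.ndarray        # [B, T, T], upper triangle == 0


# --------------------------------------------------------------- batching


@dataclass
class Batch:
    static_cont: np.ndarray   # [B, Sc]
    static_cat: np.ndarray    # [B, Scat]
    temporal: np.ndarray      # [B, T, D]
    pad_mask: np.ndarray      # [B, T]
    labels: np.ndarray        # [B, T, 3]
    label_valid: np.ndarray   # [B, T]
    prev_static_cont: np.ndarray  # [B, K, Sc]
    prev_static_cat: np.ndarray   # [B, K, Scat]
    prev_temporal: np.ndarray     # [B, K, T, D]
    prev_pad: np.ndarray          # [B, K, T]
    prev_mask: np.ndarray         # [B, K]
    times: list[np.ndarray]

    @property
    def n_prev_slots(self) -> int:
        return self.prev_mask.shape[1]


def collate(
    bundles: Sequence[FeatureBundle],
    n_prev_slots: int,
    max_timesteps: int = 24,
) -> Batch:
    """Pad bundles to a common length and stack previous-session slots."""
    B = len(bundles)
    if B == 0:
        raise ValueError("empty batch")
    sc = len(bundles[0].static_cont)
    scat = len(bundles[0].static_cat)
    D = bundles[0].temporal.shape[1]
    T = min(max(b.n_timesteps for b in bundles), max_timesteps)
    prev_T_max = 1
    for b in bundles:
        for p in b.previous[:n_prev_slots]:
            if p is not None:
                prev_T_max = max(prev_T_max, p.n_timesteps)
    PT = min(prev_T_max, max_timesteps)
    K = n_prev_slots

    batch = Batch(
        static_cont=np.zeros((B, sc)),
        static_cat=np.zeros((B, scat), dtype=int),
        temporal=np.zeros((B, T, D)),
        pad_mask=np.zeros((B, T), dtype=bool),
        labels=np.zeros((B, T, 3)),
        label_valid=np.zeros((B, T), dtype=bool),
        prev_static_cont=np.zeros((B, K, sc)),
        prev_static_cat=np.zeros((B, K, scat), dtype=int),
        prev_temporal=np.zeros((B, K, PT, D)),
        prev_pad=np.zeros((B, K, PT), dtype=bool),
        prev_mask=np.zeros((B, K), dtype=bool),
        times=[b.times[:T] for b in bundles],
    )
    for i, b in enumerate(bundles):
        t = min(b.n_timesteps, T)
        batch.static_cont[i] = b.static_cont
        batch.static_cat[i] = b.static_cat
        batch.temporal[i, :t] = b.temporal[:t]
        batch.pad_mask[i, :t] = True
        batch.labels[i, :t] = b.labels[:t]
        batch.label_valid[i, :t] = b.label_valid[:t]
        for k in range(min(K, len(b.previous))):
            p = b.previous[k]
            if p is None or not b.previous_mask[k]:
                continue
            pt = min(p.n_timesteps, PT)
            batch.prev_static_cont[i, k] = p.static_cont
            batch.prev_static_cat[i, k] = p.static_cat
            batch.prev_temporal[i, k, :pt] = p.temporal[:pt]
            batch.prev_pad[i, k, :pt] = True
            batch.prev_mask[i, k] = True
    return batch


# ------------------------------------------------------------------ model


class TFTClassifier(Module):
    """The modified temporal-fusion classifier."""

    def __init__(
        self,
        config: ModelConfig,
        schema: VariableSchema,
        stats: NormalizationStats,
    ):
        self.config = config
        self.schema = schema
        H = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self._rng = rng

        self.cont_names = [
            v.name for v in schema.time_invariant if v.dtype != CATEGORICAL
        ]
        self.cat_names = [
            v.name for v in schema.time_invariant if v.dtype == CATEGORICAL
        ]
        self.n_temporal = 2 * len(schema.time_varying) + 2
        K = config.max_previous_sessions

        self.static_cont_embed = ContinuousEmbedding(rng, len(self.cont_names), H)
        self.static_cat_embeds = [
            Embedding(rng, stats.categorical[n].n_levels, H)
            for n in self.cat_names
        ]
        n_static_vars = len(self.cont_names) + len(self.cat_names) + K
        self.static_selection = VariableSelection(rng, n_static_vars, H)
        self.ctx_selection = GRN(rng, H, H)
        self.ctx_state = GRN(rng, H, H)
        self.ctx_enrich = GRN(rng, H, H)
        self.temporal_embed = ContinuousEmbedding(rng, self.n_temporal, H)
        self.temporal_selection = VariableSelection(rng, self.n_temporal, H, context_dim=H)
        self.gru = GRU(rng, H, H)
        self.post_rnn = GRN(rng, H, H)
        self.norm_rnn = LayerNorm(H)
        self.enrich = GRN(rng, H, H, context_dim=H)
        self.norm_enrich = LayerNorm(H)
        self.attention = CausalSelfAttention(rng, H)
        self.post_attn = GRN(rng, H, H)
        self.norm_attn = LayerNorm(H)
        self.classifier_grn = GRN(rng, H, H)
        self.head = Dense(rng, H, len(OUTCOME_HEADS))

    # ------------------------------------------------------------ internals

    def _static_embeds(
        self,
        static_cont: np.ndarray,
        static_cat: np.ndarray,
        prev_reps: Optional[Tensor],
        prev_mask: Optional[np.ndarray],
    ) -> tuple[Tensor, np.ndarray]:
        B = static_cont.shape[0]
        H = self.config.hidden_size
        parts = []
        if self.cont_names:
            parts.append(self.static_cont_embed(static_cont))
        for j, emb in enumerate(self.static_cat_embeds):
            parts.append(emb(static_cat[:, j]).reshape(B, 1, H))
        n_real = len(self.cont_names) + len(self.cat_names)
        K = self.config.max_previous_sessions
        if K > 0:
            if prev_reps is None:
                prev_reps = Tensor(np.zeros((B, K, H)))
                prev_mask = np.zeros((B, K), dtype=bool)
            parts.append(prev_reps)
            mask = np.concatenate(
                [np.ones((B, n_real), dtype=bool), prev_mask], axis=1
            )
        else:
            mask = np.ones((B, n_real), dtype=bool)
        return Tensor.concat(parts, axis=-2), mask

    def _encode(
        self,
        static_cont: np.ndarray,
        static_cat: np.ndarray,
        temporal: np.ndarray,
        pad_mask: np.ndarray,
        prev_reps: Optional[Tensor] = None,
        prev_mask: Optional[np.ndarray] = None,
    ):
        """Shared embedding -> selection -> recurrence -> attention stack.

        Returns (per-timestep features [B,T,H], static weights, temporal
        variable weights, attention weights)."""
        B, T, _ = temporal.shape
        embeds, var_mask = self._static_embeds(
            static_cont, static_cat, prev_reps, prev_mask
        )
        static_fused, static_w = self.static_selection(embeds, var_mask=var_mask)
        c_sel = self.ctx_selection(static_fused)
        c_state = self.ctx_state(static_fused)
        c_enrich = self.ctx_enrich(static_fused)

        t_embeds = self.temporal_embed(temporal)  # [B,T,V,H]
        H = self.config.hidden_size
        fused, tv_w = self.temporal_selection(
            t_embeds, context=c_sel.reshape(B, 1, H)
        )
        seq = self.gru(fused, c_state, pad_mask)
        seq = self.norm_rnn(self.post_rnn(seq))
        enriched = self.norm_enrich(self.enrich(seq, c_enrich.reshape(B, 1, H)))
        attn_out, attn_w = self.attention(enriched, pad_mask)
        feat = self.norm_attn(enriched + self.post_attn(attn_out))
        return feat, static_w, tv_w, attn_w

    def _pool_last(self, feat: Tensor, pad_mask: np.ndarray) -> Tensor:
        idx = np.maximum(pad_mask.sum(axis=1) - 1, 0)
        return feat[np.arange(feat.shape[0]), idx]

    def encode_previous_sessions(self, batch: Batch) -> Optional[Tensor]:
        """Encode all previous-session slots through the shared stack and
        zero the representations of unavailable slots."""
        K = batch.n_prev_slots
        if K == 0:
            return None
        B = batch.temporal.shape[0]
        H = self.config.hidden_size
        flat_T = batch.prev_temporal.shape[2]
        feat, _, _, _ = self._encode(
            batch.prev_static_cont.reshape(B * K, -1),
            batch.prev_static_cat.reshape(B * K, -1),
            batch.prev_temporal.reshape(B * K, flat_T, -1),
            batch.prev_pad.reshape(B * K, flat_T),
        )
        reps = self._pool_last(feat, batch.prev_pad.reshape(B * K, flat_T))
        reps = reps.reshape(B, K, H)
        return reps * batch.prev_mask[:, :, None].astype(float)

    def forward(self, batch: Batch) -> tuple[Tensor, AttentionReport]:
        """Probabilities [B, T, 3] plus the attention report."""
        prev_reps = self.encode_previous_sessions(batch)
        feat, static_w, tv_w, attn_w = self._encode(
            batch.static_cont,
            batch.static_cat,
            batch.temporal,
            batch.pad_mask,
            prev_reps=prev_reps,
            prev_mask=batch.prev_mask if prev_reps is not None else None,
        )
        logits = self.head(self.classifier_grn(feat))
        probs = logits.sigmoid()
        report = AttentionReport(
            static_variable_weights=static_w.data.copy(),
            timevarying_variable_weights=tv_w.data.copy(),
            temporal_attention=attn_w.data.copy(),
        )
        return probs, report

    def static_variable_names(self) -> list[str]:
        prev = [
            f"previous_session_{i + 1}"
            for i in range(self.config.max_previous_sessions)
        ]
        return self.cont_names + self.cat_names + prev

    def temporal_variable_names(self) -> list[str]:
        tv = [v.name for v in self.schema.time_varying]
        return list(
            tv + list(self.schema.auxiliary_columns)
        ) + ["elapsed_session_min", "interval_prev_session_min"]


# --------------------------------------------------------------- training


def masked_bce(probs: Tensor, labels: np.ndarray, valid: np.ndarray) -> Tensor:
    """Mean binary cross-entropy over valid (timestep, head) pairs, heads
    equally weighted."""
    eps = 1e-7
    y = labels
    w = valid[..., None].astype(float) * np.ones_like(y)
    n = w.sum()
    if n == 0:
        raise ValueError("no valid labels in batch")
    ll = (
        Tensor(y) * (probs + eps).log()
        + Tensor(1.0 - y) * ((1.0 + eps) - probs).log()
    )
    return -(ll * w).sum() * (1.0 / n)


def _clip_gradients(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale


@dataclass
class TrainingLog:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf


def evaluate_loss(model, bundles: Sequence[FeatureBundle], config: ModelConfig) -> float:
    total, n = 0.0, 0
    with no_grad():
        for i in range(0, len(bundles), config.batch_size):
            batch = collate(
                bundles[i : i + config.batch_size],
                config.max_previous_sessions,
                config.max_timesteps,
            )
            probs, _ = model.forward(batch)
            w = int(batch.label_valid.sum()) * len(OUTCOME_HEADS)
            if w == 0:
                continue
            loss = masked_bce(probs, batch.labels, batch.label_valid)
            total += float(loss.data) * w
            n += w
    return total / max(n, 1)


def train_model(
    model,
    train_bundles: Sequence[FeatureBundle],
    val_bundles: Sequence[FeatureBundle],
    config: ModelConfig,
) -> TrainingLog:
    """Train any forward(batch)->(probs, report) model with Adam, early
    stopping on validation loss; deterministic under config.seed."""
    if not train_bundles:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed + 1)
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    log = TrainingLog()
    best_state = model.state_arrays()
    patience = 0
    train_bundles = list(train_bundles)
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_bundles))
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [train_bundles[j] for j in order[i : i + config.batch_size]]
            batch = collate(
                chunk, config.max_previous_sessions, config.max_timesteps
            )
            if not batch.label_valid.any():
                continue
            probs, _ = model.forward(batch)
            loss = masked_bce(probs, batch.labels, batch.label_valid)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            _clip_gradients(params, config.grad_clip)
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        val_loss = (
            evaluate_loss(model, val_bundles, config)
            if val_bundles
            else train_loss
        )
        log.epochs.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if val_loss < log.best_val_loss - 1e-6:
            log.best_val_loss = val_loss
            log.best_epoch = epoch
            best_state = model.state_arrays()
            patience = 0
        else:
            patience += 1
            if patience > config.early_stopping_patience:
                break
    model.load_state_arrays(best_state)
    return log


def predict(
    model,
    bundles: Sequence[FeatureBundle],
    config: ModelConfig,
    collect_attention: bool = False,
):
    """Per-session probability tracks (native lengths); optionally the
    attention reports."""
    probs_out: list[np.ndarray] = []
    reports: list[AttentionReport] = []
    with no_grad():
        for i in range(0, len(bundles), config.batch_size):
            chunk = bundles[i : i + config.batch_size]
            batch = collate(
                chunk, config.max_previous_sessions, config.max_timesteps
            )
            probs, report = model.forward(batch)
            for j, b in enumerate(chunk):
                t = min(b.n_timesteps, batch.temporal.shape[1])
                probs_out.append(probs.data[j, :t, :].copy())
                if collect_attention:
                    reports.append(
                        AttentionReport(
                            static_variable_weights=report.static_variable_weights[j],
                            timevarying_variable_weights=report.timevarying_variable_weights[j, :t],
                            temporal_attention=report.temporal_attention[j, :t, :t],
                        )
                    )
    return (probs_out, reports) if collect_attention else probs_out


def save_checkpoint(model: TFTClassifier, path) -> None:
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, **arrays)


def load_checkpoint(model: TFTClassifier, path) -> None:
    data = np.load(path)
    model.load_state_arrays([data[f"p{i}"] for i in range(len(data.files))])
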