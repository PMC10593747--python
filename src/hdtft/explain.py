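"""Attention-based explainability: variable-importance tables, per-session
explanations, and slim schema derivation from importance rankings."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FeatureBundle
from .model import ModelConfig, TFTClassifier, collate, predict
from .nn import no_grad
from .schema import VariableSchema


@dataclass
class ImportanceTables:
    """Mean selection weights, renormalized to sum to one per table."""

    static: pd.Series        # time-invariant originals + previous-session slots
    time_varying: pd.Series  # time-varying originals + indicators + elapsed

    def ranked_originals(self, schema: VariableSchema) -> pd.Series:
        """Pooled ranking over the schema's original variables only
        (previous-session slots, indicator and elapsed columns dropped),
        ties broken by lexicographic variable name."""
        names = {v.name for v in schema.variables}
        pooled = pd.concat([self.static, self.time_varying])
        pooled = pooled[pooled.index.isin(names)]
        order = sorted(pooled.index, key=lambda n: (-pooled[n], n))
        return pooled.loc[order]


def variable_importance(
    model: TFTClassifier,
    bundles: Sequence[FeatureBundle],
    config: ModelConfig | None = None,
) -> ImportanceTables:
    """Average selection weights over timesteps (time-varying) and then
    over examples; each table is renormalized to sum to 1."""
    if not bundles:
        raise ValueError("empty dataset")
    config = config or model.config
    static_acc = None
    tv_acc = None
    prev_avail = None
    n = 0
    with no_grad():
        for i in range(0, len(bundles), config.batch_size):
            chunk = bundles[i : i + config.batch_size]
            batch = collate(chunk, config.max_previous_sessions, config.max_timesteps)
            _, report = model.forward(batch)
            sw = report.static_variable_weights           # [B, Vs]
            tw = report.timevarying_variable_weights      # [B, T, Vt]
            pm = batch.pad_mask[:, :, None].astype(float)
            tw_mean = (tw * pm).sum(axis=1) / np.maximum(pm.sum(axis=1), 1.0)
            static_acc = sw.sum(axis=0) + (static_acc if static_acc is not None else 0)
            tv_acc = tw_mean.sum(axis=0) + (tv_acc if tv_acc is not None else 0)
            avail = batch.prev_mask.sum(axis=0)
            prev_avail = avail + (prev_avail if prev_avail is not None else 0)
            n += len(chunk)
    # real static variables: mean over all examples; previous-session
    # slots: mean over examples where the slot is available (its weight is
    # structurally zero when the session is absent, which would otherwise
    # deflate its importance)
    static_mean = static_acc / n
    k = len(prev_avail) if prev_avail is not None else 0
    if k:
        denom = np.maximum(prev_avail, 1)
        static_mean[-k:] = static_acc[-k:] / denom
    tv_mean = tv_acc / n
    static = pd.Series(static_mean, index=model.static_variable_names())
    tv = pd.Series(tv_mean, index=model.temporal_variable_names())
    return ImportanceTables(
        static=static / static.sum(), time_varying=tv / tv.sum()
    )


def session_explanation(
    model: TFTClassifier, bundle: FeatureBundle
) -> dict:
    """Per-timestep probabilities, variable weights and temporal attention
    rows (future positions exactly 0) for one session."""
    probs, reports = predict(
        model, [bundle], model.config, collect_attention=True
    )
    report = reports[0]
    return {
        "session_id": bundle.session_id,
        "times_min": bundle.times.tolist(),
        "probabilities": probs[0],
        "static_variable_weights": dict(
            zip(model.static_variable_names(),
                report.static_variable_weights.tolist())
        ),
        "timevarying_variable_weights": report.timevarying_variable_weights,
        "temporal_attention": report.temporal_attention,
    }


def select_slim_schema(
    tables: ImportanceTables, k: int, parent: VariableSchema
) -> VariableSchema:
    """Top-k original variables by mean selection weight.

    The time-varying/time-invariant split is whatever the pooled ranking
    induces; auxiliary and elapsed columns are recomputed by the schema
    itself. Ties break lexicographically, so the result is deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(parent):
        raise ValueError(f"k={k} exceeds schema size {len(parent)}")
    ranked = tables.ranked_originals(parent)
    keep = list(ranked.index[:k])
    return parent.subset(keep)


def importance_to_csv(tables: ImportanceTables, static_path, tv_path) -> None:
    tables.static.rename("weight").to_csv(static_path, index_label="variable")
    tables.time_varying.rename("weight").to_csv(tv_path, index_label="variable")
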