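"""Comparator models for ordering experiments.

* Recurrent baseline: the gated-recurrent encoder and dense head only —
  no variable selection, no attention, no previous-session context.
* Tabular baselines (logistic regression, optionally tree ensembles) on a
  flattened table built from exactly three timestamps: session start, the
  prediction timestamp, and the immediately previous recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .features import FeatureBundle
from .model import AttentionReport, Batch, ModelConfig
from .nn import Dense, GRU, Module, Tensor, no_grad


class RecurrentBaseline(Module):
    """GRU over the temporal features, state initialized from a dense
    projection of the static covariates, followed by a per-timestep dense
    head. Shares the training loop with the main model."""

    def __init__(self, config: ModelConfig, n_temporal: int, n_static: int):
        self.config = config
        H = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self.input_proj = Dense(rng, n_temporal + n_static, H)
        self.static_proj = Dense(rng, n_static, H)
        self.gru = GRU(rng, H, H)
        self.head = Dense(rng, H, 3)

    def forward(self, batch: Batch):
        B, T, _ = batch.temporal.shape
        static = np.concatenate(
            [batch.static_cont, batch.static_cat.astype(float)], axis=1
        )
        # statics are concatenated to every timestep's input (the reference
        # recurrent design consumes static and time-varying features
        # together) and also initialize the recurrent state
        tiled = np.broadcast_to(static[:, None, :], (B, T, static.shape[1]))
        x = self.input_proj(
            Tensor(np.concatenate([batch.temporal, tiled], axis=2))
        )
        h0 = self.static_proj(Tensor(static)).tanh()
        seq = self.gru(x.tanh(), h0, batch.pad_mask)
        probs = self.head(seq).sigmoid()
        B, T, _ = batch.temporal.shape
        empty = AttentionReport(
            static_variable_weights=np.zeros((B, 0)),
            timevarying_variable_weights=np.zeros((B, T, 0)),
            temporal_attention=np.zeros((B, T, T)),
        )
        return probs, empty


@dataclass
class TabularDataset:
    """Flattened three-timestamp design matrix, one row per valid
    (session, timestamp) pair."""

    X: np.ndarray
    y: np.ndarray          # [n, 3]
    times_min: np.ndarray  # prediction timestamps
    session_ids: list[str]
    column_names: list[str]


def tabular_features(bundles: Sequence[FeatureBundle]) -> TabularDataset:
    """Width = 3 * |time-varying| + |time-invariant| + 2.

    Time-varying values are taken at session start, at the prediction
    timestamp, and at the immediately previous recording (start values
    reused when no previous recording exists)."""
    if not bundles:
        raise ValueError("no bundles")
    schema = bundles[0].schema
    n_tv = len(schema.time_varying)
    tv_names = [v.name for v in schema.time_varying]
    rows, ys, times, sids = [], [], [], []
    for b in bundles:
        static = np.concatenate([b.static_cont, b.static_cat.astype(float)])
        tv = b.temporal[:, :n_tv]
        elapsed = b.temporal[:, -2:]
        for t in range(b.n_timesteps):
            if not b.label_valid[t]:
                continue
            prev_t = max(t - 1, 0)
            rows.append(
                np.concatenate([static, tv[0], tv[t], tv[prev_t], elapsed[t]])
            )
            ys.append(b.labels[t])
            times.append(b.times[t])
            sids.append(b.session_id)
    static_names = [
        v.name for v in schema.time_invariant
    ]
    cols = (
        static_names
        + [f"{n}_start" for n in tv_names]
        + [f"{n}_now" for n in tv_names]
        + [f"{n}_prev" for n in tv_names]
        + ["elapsed_session_min", "interval_prev_session_min"]
    )
    return TabularDataset(
        X=np.asarray(rows),
        y=np.asarray(ys),
        times_min=np.asarray(times),
        session_ids=sids,
        column_names=cols,
    )


def fit_logistic_regression(
    train: TabularDataset, seed: int = 0
) -> list[LogisticRegression]:
    """One binary model per outcome head."""
    models = []
    for h in range(train.y.shape[1]):
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(train.X, train.y[:, h].astype(int))
        models.append(clf)
    return models


def fit_random_forest(
    train: TabularDataset, seed: int = 0, n_estimators: int = 100
) -> list[RandomForestClassifier]:
    models = []
    for h in range(train.y.shape[1]):
        clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        clf.fit(train.X, train.y[:, h].astype(int))
        models.append(clf)
    return models


def predict_tabular(models, data: TabularDataset) -> np.ndarray:
    """[n, heads] probability matrix."""
    cols = []
    for clf in models:
        if len(clf.classes_) == 1:
            cols.append(np.full(len(data.X), float(clf.classes_[0])))
        else:
            cols.append(clf.predict_proba(data.X)[:, 1])
    return np.stack(cols, axis=1)
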