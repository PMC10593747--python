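"""End-to-end orchestration: generate -> filter/match/split -> label ->
features -> train -> evaluate, plus a manifest-driven staged runner."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .baselines import (
    RecurrentBaseline,
    fit_logistic_regression,
    predict_tabular,
    tabular_features,
)
from .cohort import (
    FilterCriteria,
    SplitAssignment,
    filter_sessions,
    match_cohort,
    split_by_patient,
)
from .data import Cohort, SessionSet
from .features import (
    FeatureBundle,
    NormalizationStats,
    assemble_bundles,
    fit_statistics,
)
from .labeling import LabelTrack, label_session
from .metrics import metric_result
from .model import (
    ModelConfig,
    OUTCOME_HEADS,
    TFTClassifier,
    predict,
    save_checkpoint,
    train_model,
)
from .schema import VariableSchema
from .synthetic import CohortTruth, SyntheticConfig, generate_cohort, write_cohort


@dataclass
class PreparedData:
    """All artifacts needed to train and evaluate on one cohort."""

    schema: VariableSchema
    stats: NormalizationStats
    split: SplitAssignment
    session_sets: dict[str, list[SessionSet]]
    bundles: dict[str, list[FeatureBundle]]
    labels: dict[str, LabelTrack]
    truth: Optional[CohortTruth] = None


def prepare_data(
    cohort: Cohort,
    seed: int,
    k: int = 5,
    window_days: float = 31.0,
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    criteria: FilterCriteria = FilterCriteria(),
    truth: Optional[CohortTruth] = None,
) -> PreparedData:
    """Filter, match, split, label and featurize a cohort."""
    kept, _ = filter_sessions(cohort.sessions, criteria)
    filtered = Cohort(schema=cohort.schema, sessions=kept)
    session_sets = match_cohort(filtered, k=k, window_days=window_days)
    split = split_by_patient(filtered.patient_ids(), fractions, seed)
    by_split: dict[str, list[SessionSet]] = {
        "train": [], "validation": [], "test": []
    }
    for ss in session_sets:
        by_split[split[ss.current.patient_id]].append(ss)
    labels = {
        ss.current.session_id: label_session(ss.current)
        for ss in session_sets
    }
    stats = fit_statistics(by_split["train"], cohort.schema)
    bundles = {
        name: assemble_bundles(sets, labels, cohort.schema, stats, n_prev_slots=k)
        for name, sets in by_split.items()
    }
    return PreparedData(
        schema=cohort.schema,
        stats=stats,
        split=split,
        session_sets=by_split,
        bundles=bundles,
        labels=labels,
        truth=truth,
    )


def flatten_predictions(
    bundles: list[FeatureBundle], prob_tracks: list[np.ndarray]
) -> dict[str, np.ndarray]:
    """Pool per-timestep predictions over sessions, keeping only valid
    labels. Returns scores [n,3], labels [n,3] and timestamps [n]."""
    scores, labels, times = [], [], []
    for b, p in zip(bundles, prob_tracks):
        t = min(b.n_timesteps, len(p))
        valid = b.label_valid[:t]
        scores.append(p[:t][valid])
        labels.append(b.labels[:t][valid])
        times.append(b.times[:t][valid])
    return {
        "scores": np.concatenate(scores),
        "labels": np.concatenate(labels),
        "times": np.concatenate(times),
    }


def evaluate_model_auroc(
    model, bundles: list[FeatureBundle], config: ModelConfig
) -> dict[str, float]:
    """Per-outcome AUROC of a trained sequence model on a bundle list."""
    from .metrics import DegenerateLabelsError

    tracks = predict(model, bundles, config)
    flat = flatten_predictions(bundles, tracks)
    out = {}
    for h, name in enumerate(OUTCOME_HEADS):
        try:
            out[name] = metric_result(
                flat["scores"][:, h], flat["labels"][:, h], n_bootstrap=0
            ).auroc
        except DegenerateLabelsError:
            out[name] = None  # single-class head at this cohort size
    return out


def train_tft(
    prepared: PreparedData, config: ModelConfig
) -> tuple[TFTClassifier, object]:
    model = TFTClassifier(config, prepared.schema, prepared.stats)
    log = train_model(
        model, prepared.bundles["train"], prepared.bundles["validation"], config
    )
    return model, log


def train_recurrent_baseline(
    prepared: PreparedData, config: ModelConfig
) -> tuple[RecurrentBaseline, object]:
    b0 = prepared.bundles["train"][0]
    n_static = len(b0.static_cont) + len(b0.static_cat)
    model = RecurrentBaseline(config, b0.temporal.shape[1], n_static)
    log = train_model(
        model, prepared.bundles["train"], prepared.bundles["validation"], config
    )
    return model, log


def logistic_auroc(prepared: PreparedData, seed: int = 0) -> dict[str, float]:
    train = tabular_features(prepared.bundles["train"])
    test = tabular_features(prepared.bundles["test"])
    models = fit_logistic_regression(train, seed=seed)
    probs = predict_tabular(models, test)
    out = {}
    for h, name in enumerate(OUTCOME_HEADS):
        out[name] = metric_result(
            probs[:, h], test.y[:, h], n_bootstrap=0
        ).auroc
    return out


# ------------------------------------------------------- staged runner


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class PipelineConfig:
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            synthetic=raw.get("synthetic", {}) or {},
            cohort=raw.get("cohort", {}) or {},
            model=raw.get("model", {}) or {},
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "synthetic": self.synthetic,
            "cohort": self.cohort,
            "model": self.model,
        }


class StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run generate -> prepare -> train -> evaluate, writing artifacts and
    a manifest. Re-running with an identical config skips completed
    stages (keyed by config hash)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = _hash_obj(config.to_dict())
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    if manifest.get("config_hash") not in (None, cfg_hash):
        raise StageError(
            f"output dir {out} was produced with a different config "
            f"({manifest.get('config_hash')} != {cfg_hash})"
        )
    manifest.setdefault("config_hash", cfg_hash)
    manifest.setdefault("stages", {})

    syn_kwargs = dict(config.synthetic)
    syn_kwargs.setdefault("seed", config.seed)
    if "sessions_per_patient" in syn_kwargs:
        syn_kwargs["sessions_per_patient"] = tuple(
            syn_kwargs["sessions_per_patient"]
        )
    if "session_duration_h" in syn_kwargs:
        syn_kwargs["session_duration_h"] = tuple(syn_kwargs["session_duration_h"])
    syn_config = SyntheticConfig(**syn_kwargs)

    if "generate" not in manifest["stages"]:
        cohort, truth = generate_cohort(syn_config)
        write_cohort(cohort, truth, out / "cohort")
        manifest["stages"]["generate"] = {
            "n_sessions": len(cohort),
            "n_patients": len(cohort.patient_ids()),
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))
    else:
        cohort = Cohort.read(out / "cohort", syn_config.schema)
        truth = None
        if not cohort.sessions:
            raise StageError(f"corrupted cohort tables under {out / 'cohort'}")

    k = int(config.cohort.get("k", 5))
    prepared = prepare_data(
        cohort,
        seed=config.seed,
        k=k,
        window_days=float(config.cohort.get("window_days", 31.0)),
        truth=truth,
    )
    manifest["stages"]["prepare"] = {
        name: len(b) for name, b in prepared.bundles.items()
    }
    schema_hash = _hash_obj([v.name for v in prepared.schema])
    manifest["schema_hash"] = schema_hash

    model_kwargs = dict(config.model)
    model_kwargs.setdefault("seed", config.seed)
    model_kwargs.setdefault("max_previous_sessions", k)
    model_config = ModelConfig(**model_kwargs)
    model, log = train_tft(prepared, model_config)
    save_checkpoint(model, out / "model.npz")
    (out / "training_log.json").write_text(
        json.dumps(log.epochs, indent=1)
    )
    manifest["stages"]["train"] = {
        "best_epoch": log.best_epoch,
        "best_val_loss": log.best_val_loss,
    }

    eval_bundles = prepared.bundles["test"] or prepared.bundles["train"]
    aurocs = evaluate_model_auroc(model, eval_bundles, model_config)
    (out / "metrics.json").write_text(json.dumps(aurocs, indent=1))
    manifest["stages"]["evaluate"] = aurocs
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
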