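"""Shared expensive fixtures: trained models on synthetic cohorts with
known generative structure.

Training experiments are the dominant cost of the suite, so each cohort
is generated once and every trained artifact is shared by all tests that
assert on it (driver recovery, model ordering, slim retention,
previous-session ablation).
"""

from __future__ import annotations

import numpy as np
import pytest

from hdtft.model import ModelConfig
from hdtft.pipeline import (
    evaluate_model_auroc,
    logistic_auroc,
    prepare_data,
    train_recurrent_baseline,
    train_tft,
)
from hdtft.synthetic import SyntheticConfig, generate_cohort

N_SEEDS = 3

#: clear-driver cohort: UFR and SBP level drive outcomes and the previous
#: session's nadir carries strong carry-over signal (driver recovery)
RECOVERY_GENERATIVE = dict(
    n_patients=560,
    sessions_per_patient=(4, 7),
    carryover_coefficient=0.5,
    vulnerability_coefficient=4.0,
    driver_coefficients={"ultrafiltration_rate": 18.0},
    noise_sd=4.0,
)

#: ordering cohort: sign-flipping static-by-driver interaction (invisible
#: to linear models), random-walk driver (history integration needed) and
#: a previous-session step signal (invisible without session context)
ORDERING_GENERATIVE = dict(
    n_patients=800,
    sessions_per_patient=(4, 7),
    carryover_coefficient=0.0,
    vulnerability_coefficient=3.5,
    driver_rho=0.995,
    driver_shift_sd=0.0,
    noise_sd=12.0,
    missing_rate_varying=0.35,
    elapsed_drift=8.0,
    driver_coefficients={"ultrafiltration_rate": 60.0},
    product_drivers=[("ultrafiltration_rate", "body_temperature", 45.0)],
    interaction_static="diabetes_mellitus",
    interaction_strength=-3.0,
)

ABLATION_GENERATIVE = {**ORDERING_GENERATIVE, "n_patients": 150}


def mean_auroc(aurocs: dict[str, float]) -> float:
    return float(np.mean(list(aurocs.values())))


@pytest.fixture(scope="session")
def recovery_experiment():
    """Criterion 8 artifacts: per seed, a model trained on >= 2,000
    sessions plus its test AUROCs and importance tables."""
    from hdtft.explain import variable_importance

    cohort, truth = generate_cohort(
        SyntheticConfig(seed=10, **RECOVERY_GENERATIVE)
    )
    runs = []
    for seed in range(N_SEEDS):
        prep = prepare_data(cohort, seed=seed, k=1)
        config = ModelConfig(
            hidden_size=16, max_previous_sessions=1, max_epochs=30,
            early_stopping_patience=6, batch_size=64, seed=seed,
            learning_rate=3e-3,
        )
        model, log = train_tft(prep, config)
        aurocs = evaluate_model_auroc(model, prep.bundles["test"], config)
        tables = variable_importance(model, prep.bundles["test"], config)
        runs.append(
            {
                "seed": seed,
                "prep": prep,
                "config": config,
                "model": model,
                "aurocs": aurocs,
                "tables": tables,
                "n_train": len(prep.bundles["train"]),
            }
        )
    return {"cohort": cohort, "truth": truth, "runs": runs}


@pytest.fixture(scope="session")
def ordering_experiment():
    """Criterion 9 artifacts: full model vs recurrent baseline vs logistic
    regression on the carryover-signal cohort, per seed."""
    cohort, _ = generate_cohort(SyntheticConfig(seed=2, **ORDERING_GENERATIVE))
    runs = []
    for seed in range(N_SEEDS):
        prep = prepare_data(cohort, seed=seed, k=1)
        full_cfg = ModelConfig(
            hidden_size=24, max_previous_sessions=1, max_epochs=40,
            early_stopping_patience=7, batch_size=64, seed=seed,
            learning_rate=2e-3,
        )
        model, _ = train_tft(prep, full_cfg)
        rec_cfg = ModelConfig(
            hidden_size=32, max_previous_sessions=1, max_epochs=100,
            early_stopping_patience=15, batch_size=64, seed=seed,
            learning_rate=5e-3,
        )
        rec, _ = train_recurrent_baseline(prep, rec_cfg)
        runs.append(
            {
                "seed": seed,
                "full": evaluate_model_auroc(model, prep.bundles["test"], full_cfg),
                "recurrent": evaluate_model_auroc(rec, prep.bundles["test"], rec_cfg),
                "logistic": logistic_auroc(prep, seed=seed),
            }
        )
    return runs


@pytest.fixture(scope="session")
def ablation_experiment():
    """Criterion 11 artifacts: AUROC as a function of the number of
    previous-session slots K, per seed (true carryover depth = 1)."""
    cohort, _ = generate_cohort(SyntheticConfig(seed=4, **ABLATION_GENERATIVE))
    sweep = {k: [] for k in (0, 1, 3, 5)}
    for seed in range(N_SEEDS):
        prep = prepare_data(cohort, seed=seed, k=5)
        for k in sweep:
            config = ModelConfig(
                hidden_size=16, max_previous_sessions=k, max_epochs=25,
                early_stopping_patience=5, batch_size=64, seed=seed,
                learning_rate=2e-3,
            )
            model, _ = train_tft(prep, config)
            sweep[k].append(
                mean_auroc(
                    evaluate_model_auroc(model, prep.bundles["test"], config)
                )
            )
    return sweep
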