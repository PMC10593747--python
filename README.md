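# hdtft

Real-time dual prediction of intradialytic hypotension (IDH-1, IDH-2) and
hypertension (IDHTN) during hemodialysis, using a modified
temporal-fusion-transformer classifier with attention-based
explainability — exercised end-to-end on synthetic hemodialysis cohorts
with known outcome drivers.

The package implements the full pipeline:

- **`hdtft.synthetic`** — seeded synthetic cohort generator: per-patient
  repeated sessions (2–6 h), ~hourly vitals with denser sampling when
  unstable, missingness in both variable classes, patient-level random
  effects, and SBP trajectories driven by a closed-form equation with
  known drivers, previous-session carry-over, and a ground-truth sidecar.
- **`hdtft.cohort`** — exclusion filters (age < 18, no initial BP,
  duration outside 2–6 h, BP gap > 1.5 h) with per-criterion tallies,
  matching of each session with up to 5 previous sessions within 31 days,
  and patient-level 70/10/20 splitting.
- **`hdtft.labeling`** — per-timestamp labels under a prospective 1-h
  horizon: IDH-1 (SBP < 90), IDH-2 (SBP drop ≥ 20 or MAP drop ≥ 10 from
  the initial reading), IDHTN (SBP rise ≥ 10), and session-level IDHTN-2
  (≥ 4 of 6 consecutive sessions).
- **`hdtft.features`** — mean/median imputation for time-invariant
  variables, forward filling for time-varying variables with a
  previous-session fallback, auxiliary imputation-indicator columns
  (0 = imputed, 1 = observed), z-score normalization fitted on the
  training split only, and two elapsed-time features. The full
  66-variable schema yields exactly 78 feature columns.
- **`hdtft.model`** — the classifier: gated residual networks, variable
  selection with simplex weights, GRU local encoding initialized from
  static context, single-headed causally masked self-attention, and three
  sigmoid heads producing one probability triple per recorded timestep.
  Previous sessions pass through the same stack and re-enter as
  time-invariant features; unavailable slots are masked with exactly zero
  weight.
- **`hdtft.nn`** — a small NumPy reverse-mode autograd engine (the
  environment has no deep-learning framework): broadcasting arithmetic,
  BLAS-backed grouped linear maps, a masked softmax with *exact* zeros at
  masked positions, GRU/attention layers and Adam.
- **`hdtft.explain`** — attention-weight importance tables (each group
  sums to 1), per-session explanations, and top-k slim schema derivation.
- **`hdtft.metrics` / `hdtft.baselines`** — AUROC with DeLong-variance
  CIs, AUPRC with seeded bootstrap CIs, the paired DeLong test,
  precision/recall/F1 at threshold 0.5, calibration curves, elapsed-time
  stratification; plus comparators (recurrent baseline without
  selection/attention/previous sessions, and tabular logistic
  regression / random forest on a three-timestamp flattened table).

## CLI

```bash
hdtft generate --out data/ --config cfg.yaml        # synthetic cohort + truth sidecar
hdtft build-cohort --in data/ --out cohort/ --seed 1
hdtft label --in data/ --out labels/
hdtft run --config cfg.yaml --out run/ --seed 1     # full pipeline incl. training
hdtft evaluate --run run/
hdtft explain --run run/
```

A pipeline config is a YAML file with `seed`, `synthetic`, `cohort` and
`model` sections; see `tests/test_cli_pipeline.py` for a minimal example.
Re-running `hdtft run` with an identical config is a no-op for completed
stages (tracked in `manifest.json`).

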