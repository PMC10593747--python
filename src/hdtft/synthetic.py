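"""Synthetic hemodialysis cohort generator with known outcome drivers.

The systolic-BP trajectory is a closed-form function of a small set of
driver variables plus patient-level random effects, a carry-over term from
the previous session's nadir SBP, and Gaussian noise:

    SBP(t) = baseline + patient_effect
             - sum_v coef_v * g_v(t)
             + carryover * (prev_nadir - nadir_ref)
             - vulnerability * (nadir_ref - prev_nadir) * [t/D >= tau]
             + noise(t)

with the step time tau drawn uniformly in [0.3, 0.9] of the session.

where ``g_v(t)`` is the running mean of the standardized driver signal
scaled by elapsed fraction ``t/D`` (fluid-removal effects accumulate over
the session). The vulnerability term makes the previous session's nadir
modulate late-session BP change without being visible in the current
session's initial BP, so previous-session context carries predictive
signal of its own.

Everything is generated from one seeded ``numpy`` generator; identical
configs produce identical cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .data import Cohort, RawSession
from .schema import (
    CATEGORICAL,
    CONTINUOUS,
    VariableSchema,
    compact_schema,
)

#: population (mean, sd) used both for sampling covariates and for
#: standardizing driver signals; variables not listed default to (0, 1).
NORMS: dict[str, tuple[float, float]] = {
    "age": (62.1, 15.2),
    "predialytic_weight": (59.5, 12.2),
    "dry_weight": (57.5, 12.0),
    "target_uf_volume": (2.2, 0.9),
    "dialysate_sodium": (138.0, 2.0),
    "dialysate_calcium": (2.75, 0.25),
    "hemoglobin": (10.4, 1.4),
    "albumin": (3.6, 0.6),
    "calcium": (8.9, 0.8),
    "phosphate": (4.4, 1.5),
    "sodium": (137.0, 3.0),
    "potassium": (4.6, 0.8),
    "creatinine": (8.5, 3.0),
    "bun": (55.0, 20.0),
    "glucose": (140.0, 60.0),
    "crp": (1.5, 3.0),
    "pth": (250.0, 200.0),
    "ferritin": (300.0, 250.0),
    "transferrin_saturation": (30.0, 12.0),
    "bicarbonate": (22.0, 3.0),
    "chloride": (100.0, 4.0),
    "magnesium": (2.4, 0.4),
    "uric_acid": (6.5, 1.8),
    "total_cholesterol": (150.0, 35.0),
    "triglyceride": (120.0, 70.0),
    "ldl_cholesterol": (80.0, 25.0),
    "hdl_cholesterol": (45.0, 15.0),
    "wbc": (6.5, 2.5),
    "platelet": (180.0, 70.0),
    "ast": (22.0, 15.0),
    "alt": (18.0, 14.0),
    "alkaline_phosphatase": (90.0, 40.0),
    "total_bilirubin": (0.6, 0.4),
    "sbp": (139.0, 20.0),
    "dbp": (73.0, 12.0),
    "heart_rate": (75.0, 12.0),
    "respiratory_rate": (18.0, 2.5),
    "body_temperature": (36.3, 0.3),
    "blood_flow_rate": (250.0, 35.0),
    "ultrafiltration_rate": (500.0, 150.0),
    "dialysate_temperature": (36.5, 0.3),
    "venous_pressure": (120.0, 30.0),
    "transmembrane_pressure": (80.0, 30.0),
}

#: reference nadir SBP used for centring the carry-over terms (mmHg)
NADIR_REF = 115.0


class ConfigurationError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Generator configuration; all randomness flows from ``seed``."""

    n_patients: int = 50
    sessions_per_patient: tuple[int, int] = (3, 6)
    session_duration_h: tuple[float, float] = (3.0, 4.5)
    base_sampling_interval_min: int = 60
    unstable_sampling_interval_min: int = 20
    unstable_sbp_threshold: float = 100.0
    driver_coefficients: dict[str, float] = field(
        default_factory=lambda: {"ultrafiltration_rate": 18.0}
    )
    # optional additional drivers acting through the square of the running
    # mean (symmetric: no marginal linear effect on the trajectory)
    quadratic_driver_coefficients: dict[str, float] = field(default_factory=dict)
    # optional pairwise products of driver running means (each factor has
    # zero marginal linear effect): list of (name_a, name_b, coefficient)
    product_drivers: list[tuple[str, str, float]] = field(default_factory=list)
    carryover_coefficient: float = 0.0
    vulnerability_coefficient: float = 0.0
    elapsed_drift: float = 8.0  # mean SBP decline over a full session (mmHg)
    driver_rho: float = 0.7     # per-minute AR(1) coefficient of driver signals
    driver_shift_sd: float = 1.0  # sd of the per-session driver level shift
    # optional static-by-driver interaction: driver effects are scaled by
    # (1 + strength * code) of this binary time-invariant variable
    interaction_static: Optional[str] = None
    interaction_strength: float = 0.0
    missing_rate_invariant: float = 0.05
    missing_rate_varying: float = 0.05
    patient_effect_sd: float = 12.0
    noise_sd: float = 4.0
    violation_rate: float = 0.0
    max_timesteps: int = 24
    seed: int = 0
    schema: VariableSchema = field(default_factory=compact_schema)

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        lo, hi = self.sessions_per_patient
        if lo <= 0 or hi < lo:
            raise ConfigurationError("bad sessions_per_patient range")
        dlo, dhi = self.session_duration_h
        if not (2.0 <= dlo <= dhi <= 6.0):
            raise ConfigurationError("session duration must lie within [2, 6] h")
        for name, r in (
            ("missing_rate_invariant", self.missing_rate_invariant),
            ("missing_rate_varying", self.missing_rate_varying),
            ("violation_rate", self.violation_rate),
        ):
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.unstable_sampling_interval_min >= self.base_sampling_interval_min:
            raise ConfigurationError(
                "unstable interval must be shorter than base interval"
            )
        product_names = [n for a, b, _ in self.product_drivers for n in (a, b)]
        for name in (
            list(self.driver_coefficients)
            + list(self.quadratic_driver_coefficients)
            + product_names
        ):
            if name not in self.schema:
                raise ConfigurationError(f"driver {name!r} not in schema")
        if self.interaction_static is not None and (
            self.interaction_static not in self.schema
        ):
            raise ConfigurationError(
                f"interaction variable {self.interaction_static!r} not in schema"
            )


@dataclass
class SessionTruth:
    """Per-session ground truth for test oracles."""

    session_id: str
    prev_nadir_sbp: Optional[float]
    nadir_sbp: float
    idh1: bool
    idh2: bool
    idhtn: bool


@dataclass
class CohortTruth:
    """Sidecar ground truth: drivers, complete data and event occurrences."""

    driver_coefficients: dict[str, float]
    carryover_coefficient: float
    vulnerability_coefficient: float
    sessions: dict[str, SessionTruth]
    complete: dict[str, dict[str, np.ndarray]]
    observed_mask: dict[str, dict[str, np.ndarray]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "driver_coefficients": self.driver_coefficients,
            "carryover_coefficient": self.carryover_coefficient,
            "vulnerability_coefficient": self.vulnerability_coefficient,
            "sessions": {
                k: {
                    "prev_nadir_sbp": v.prev_nadir_sbp,
                    "nadir_sbp": v.nadir_sbp,
                    "idh1": v.idh1,
                    "idh2": v.idh2,
                    "idhtn": v.idhtn,
                }
                for k, v in self.sessions.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _norm(name: str) -> tuple[float, float]:
    return NORMS.get(name, (0.0, 1.0))


def _sample_static(schema: VariableSchema, rng: np.random.Generator) -> dict:
    static = {}
    for v in schema.time_invariant:
        if v.dtype == CONTINUOUS:
            m, s = _norm(v.name)
            static[v.name] = float(rng.normal(m, s))
        else:
            # first level most frequent, geometric-ish decay
            p = np.array([2.0 ** -i for i in range(v.n_categories)])
            static[v.name] = int(rng.choice(v.n_categories, p=p / p.sum()))
    if "age" in static:
        static["age"] = float(np.clip(static["age"], 19.0, 95.0))
    return static


def _ar1(rng: np.random.Generator, n: int, rho: float = 0.7) -> np.ndarray:
    z = np.empty(n)
    z[0] = rng.normal()
    innov_sd = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        z[i] = rho * z[i - 1] + innov_sd * rng.normal()
    return z


def _closed_form_sbp(
    base: float,
    driver_z: dict[str, np.ndarray],
    coefs: dict[str, float],
    frac: np.ndarray,
    carryover: float,
    vulnerability: float,
    prev_nadir: Optional[float],
    noise: np.ndarray,
    elapsed_drift: float = 0.0,
    step_frac: float = 0.6,
    quad_coefs: dict[str, float] | None = None,
    product_coefs: list[tuple[str, str, float]] | None = None,
) -> np.ndarray:
    """The generative SBP equation; also used by the brute-force oracle.

    Driver effects accumulate: the drop at time t is proportional to the
    running mean of the standardized driver signal times the elapsed
    fraction (cumulative fluid-removal semantics)."""
    quad_coefs = quad_coefs or {}
    product_coefs = product_coefs or []
    sbp = np.full_like(frac, base) - elapsed_drift * frac
    for name, c in coefs.items():
        z = driver_z[name]
        running_mean = np.cumsum(z) / np.arange(1, len(z) + 1)
        sbp = sbp - c * running_mean * frac
    for name, c in quad_coefs.items():
        z = driver_z[name]
        running_mean = np.cumsum(z) / np.arange(1, len(z) + 1)
        sbp = sbp - c * (running_mean**2 - 0.5) * frac
    for name_a, name_b, c in product_coefs:
        counts = np.arange(1, len(frac) + 1)
        rm_a = np.cumsum(driver_z[name_a]) / counts
        rm_b = np.cumsum(driver_z[name_b]) / counts
        sbp = sbp - c * rm_a * rm_b * frac
    if prev_nadir is not None:
        sbp = sbp + carryover * (prev_nadir - NADIR_REF)
        # sudden BP shift at a random time, its size set by the previous
        # session's nadir: unpredictable from the current trajectory, so the
        # previous session carries signal of its own at every timestamp
        sbp = sbp - vulnerability * (NADIR_REF - prev_nadir) * (
            frac >= step_frac
        )
    return sbp + noise


def _generate_session(
    config: SyntheticConfig,
    rng: np.random.Generator,
    patient_id: str,
    session_id: str,
    start_time: pd.Timestamp,
    patient_base_sbp: float,
    prev_nadir: Optional[float],
) -> tuple[RawSession, dict[str, np.ndarray], float]:
    schema = config.schema
    duration_min = 60.0 * rng.uniform(*config.session_duration_h)
    tv_names = [v.name for v in schema.time_varying]

    # dense minute grid for trajectory evaluation; recording times chosen on it
    grid = np.arange(0.0, duration_min + 1e-9, 1.0)
    frac = grid / duration_min
    n = len(grid)

    driver_z: dict[str, np.ndarray] = {}
    tv_z: dict[str, np.ndarray] = {}
    for name in tv_names:
        if name in ("sbp", "dbp"):
            continue
        shift = config.driver_shift_sd * rng.normal()
        z = shift + 0.5 * _ar1(rng, n, rho=config.driver_rho)
        tv_z[name] = z
        if (
            name in config.driver_coefficients
            or name in config.quadratic_driver_coefficients
            or any(name in (a, b) for a, b, _ in config.product_drivers)
        ):
            driver_z[name] = z

    static = _sample_static(schema, rng)
    coefs = dict(config.driver_coefficients)
    if config.interaction_static is not None:
        scale = 1.0 + config.interaction_strength * float(
            static.get(config.interaction_static) or 0
        )
        coefs = {k: c * scale for k, c in coefs.items()}

    noise = rng.normal(0.0, config.noise_sd, size=n)
    sbp = _closed_form_sbp(
        patient_base_sbp,
        driver_z,
        coefs,
        frac,
        config.carryover_coefficient,
        config.vulnerability_coefficient,
        prev_nadir,
        noise,
        elapsed_drift=config.elapsed_drift,
        step_frac=float(rng.uniform(0.3, 0.9)),
        quad_coefs=config.quadratic_driver_coefficients,
        product_coefs=config.product_drivers,
    )
    sbp = np.clip(sbp, 55.0, 230.0)
    dbp = 0.62 * sbp + rng.normal(0.0, 2.0, size=n)
    dbp = np.clip(dbp, 30.0, sbp - 5.0)

    # adaptive recording grid: denser when SBP is below the unstable threshold
    rec = [0]
    while True:
        t = rec[-1]
        step = (
            config.unstable_sampling_interval_min
            if sbp[t] < config.unstable_sbp_threshold
            else config.base_sampling_interval_min
        )
        jitter = int(rng.integers(-3, 4))
        nxt = t + max(5, step + jitter)
        if nxt >= n or len(rec) >= config.max_timesteps:
            break
        rec.append(nxt)
    idx = np.asarray(rec)
    times = grid[idx]

    complete: dict[str, np.ndarray] = {}
    for name in tv_names:
        if name == "sbp":
            complete[name] = sbp[idx]
        elif name == "dbp":
            complete[name] = dbp[idx]
        else:
            m, s = _norm(name)
            complete[name] = m + s * tv_z[name][idx]

    session = RawSession(
        patient_id=patient_id,
        session_id=session_id,
        start_time=start_time,
        duration_min=float(duration_min),
        static=static,
        times=times,
        measurements={k: v.copy() for k, v in complete.items()},
    )
    return session, complete, float(np.min(sbp[idx]))


def _apply_violation(session: RawSession, kind: int) -> None:
    if kind == 0:  # under-age
        session.static["age"] = 15.0
    elif kind == 1:  # no initial BP
        session.measurements["sbp"][0] = np.nan
        session.measurements["dbp"][0] = np.nan
    elif kind == 2:  # too short
        keep = session.times <= 90.0
        session.duration_min = 90.0
        session.times = session.times[keep]
        session.measurements = {
            k: v[keep] for k, v in session.measurements.items()
        }
    else:  # long BP gap: blank BPs in a 2-h interior window
        lo, hi = 60.0, 60.0 + 120.0
        mask = (session.times > lo) & (session.times < hi)
        if mask.any():
            session.measurements["sbp"][mask] = np.nan
            session.measurements["dbp"][mask] = np.nan


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, CohortTruth]:
    """Generate a cohort plus its ground-truth sidecar.

    Returns the (possibly missingness-injected) model-facing cohort and a
    :class:`CohortTruth` holding the complete pre-missingness measurements,
    per-session event occurrences and the driver identities.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    schema = config.schema
    cohort = Cohort(schema=schema, sessions=[])
    truth_sessions: dict[str, SessionTruth] = {}
    complete_all: dict[str, dict[str, np.ndarray]] = {}

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        n_sessions = int(rng.integers(
            config.sessions_per_patient[0], config.sessions_per_patient[1] + 1
        ))
        base_sbp = NORMS["sbp"][0] + rng.normal(0.0, config.patient_effect_sd)
        start = pd.Timestamp("2020-01-01") + pd.Timedelta(
            days=float(rng.uniform(0, 60))
        )
        prev_nadir: Optional[float] = None
        for k in range(n_sessions):
            sid = f"{pid}-S{k:03d}"
            session, complete, nadir = _generate_session(
                config, rng, pid, sid, start, base_sbp, prev_nadir
            )
            cohort.sessions.append(session)
            complete_all[sid] = complete
            sbp0, dbp0 = complete["sbp"][0], complete["dbp"][0]
            map_series = (2.0 * complete["dbp"] + complete["sbp"]) / 3.0
            truth_sessions[sid] = SessionTruth(
                session_id=sid,
                prev_nadir_sbp=prev_nadir,
                nadir_sbp=nadir,
                idh1=bool(np.any(complete["sbp"] < 90.0)),
                idh2=bool(
                    np.any(sbp0 - complete["sbp"] >= 20.0)
                    or np.any(((2 * dbp0 + sbp0) / 3.0) - map_series >= 10.0)
                ),
                idhtn=bool(np.any(complete["sbp"] - sbp0 >= 10.0)),
            )
            prev_nadir = nadir
            # mostly short gaps, some beyond the 31-day matching window
            gap_days = (
                float(rng.uniform(35, 60))
                if rng.random() < 0.15
                else float(rng.uniform(2, 7))
            )
            start = start + pd.Timedelta(days=gap_days)

    if config.violation_rate > 0:
        for session in cohort.sessions:
            if rng.random() < config.violation_rate:
                _apply_violation(session, int(rng.integers(0, 4)))

    cohort, observed = inject_missingness(
        cohort,
        rate_invariant=config.missing_rate_invariant,
        rate_varying=config.missing_rate_varying,
        seed=int(rng.integers(0, 2**31)),
    )
    truth = CohortTruth(
        driver_coefficients=dict(config.driver_coefficients),
        carryover_coefficient=config.carryover_coefficient,
        vulnerability_coefficient=config.vulnerability_coefficient,
        sessions=truth_sessions,
        complete=complete_all,
        observed_mask=observed,
    )
    return cohort, truth


#: static variables never blanked (cohort filters depend on them)
_PROTECTED_STATIC = frozenset({"age"})


def inject_missingness(
    cohort: Cohort,
    rate_invariant: float,
    rate_varying: float,
    seed: int,
) -> tuple[Cohort, dict[str, dict[str, np.ndarray]]]:
    """Blank cells at the given rates; returns (masked cohort, truth mask).

    The truth mask maps session_id -> variable -> boolean array (True where
    the value remains observed). Initial SBP/DBP at elapsed 0 are never
    removed, and static filter variables (age) are kept complete.
    """
    for name, rate in (("rate_invariant", rate_invariant),
                       ("rate_varying", rate_varying)):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    observed: dict[str, dict[str, np.ndarray]] = {}
    for session in cohort.sessions:
        mask_map: dict[str, np.ndarray] = {}
        for v in cohort.schema.time_invariant:
            if v.name in _PROTECTED_STATIC:
                continue
            if rng.random() < rate_invariant:
                session.static[v.name] = None
        bp_drop = _bp_drop_mask(session, rate_varying, rng)
        for v in cohort.schema.time_varying:
            series = session.measurements.get(v.name)
            if series is None:
                continue
            if v.name in ("sbp", "dbp"):
                drop = bp_drop  # BP measured as a pair; gap-safe
            else:
                drop = rng.random(series.shape) < rate_varying
            series[drop] = np.nan
            mask_map[v.name] = np.isfinite(series)
        observed[session.session_id] = mask_map
    return cohort, observed


_BP_GAP_LIMIT_MIN = 90.0  # keep generated sessions inside the gap filter


def _bp_drop_mask(
    session, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Joint SBP/DBP missingness that never opens a BP gap wide enough to
    trip the cohort gap filter; the initial reading is always kept."""
    times = session.times
    T = len(times)
    drop = rng.random(T) < rate
    if T == 0:
        return drop
    drop[0] = False
    last_kept = times[0]
    for i in range(1, T):
        if drop[i]:
            nxt = times[i + 1] if i + 1 < T else None
            if nxt is not None and nxt - last_kept > _BP_GAP_LIMIT_MIN:
                drop[i] = False
        if not drop[i]:
            last_kept = times[i]
    return drop


def write_cohort(
    cohort: Cohort,
    truth: Optional[CohortTruth],
    out_dir: str | Path,
    fmt: str = "csv",
) -> None:
    out = Path(out_dir)
    cohort.write(out, fmt=fmt)
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
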