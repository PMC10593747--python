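"""Variable schemas for hemodialysis session data.

A schema enumerates the model-facing variables: time-invariant covariates
(demographics, comorbidities, labs, medications, prescription) and
time-varying measurements (vitals and dialysis settings). Every
time-varying variable receives one auxiliary imputation-indicator column,
and two elapsed-time features are always appended, so the feature width of
a schema is ``n_original + n_time_varying + 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

TIME_INVARIANT = "time_invariant"
TIME_VARYING = "time_varying"
CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: Names of the two elapsed-time features appended to every bundle.
ELAPSED_COLUMNS = ("elapsed_session_min", "interval_prev_session_min")


@dataclass(frozen=True)
class Variable:
    """One model variable.

    Parameters
    ----------
    name : str
        Unique variable name.
    kind : str
        ``"time_invariant"`` or ``"time_varying"``.
    dtype : str
        ``"continuous"`` or ``"categorical"``.
    normal_flag : bool or None
        For continuous variables: whether the variable is treated as
        normally distributed (mean imputation) rather than skewed (median
        imputation). ``None`` means "decide from training data".
    n_categories : int
        Number of category levels (categorical variables only).
    """

    name: str
    kind: str
    dtype: str
    normal_flag: Optional[bool] = None
    n_categories: int = 0

    def __post_init__(self) -> None:
        if self.kind not in (TIME_INVARIANT, TIME_VARYING):
            raise ValueError(f"bad kind {self.kind!r} for {self.name}")
        if self.dtype not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"bad dtype {self.dtype!r} for {self.name}")
        if self.dtype == CATEGORICAL and self.n_categories < 2:
            raise ValueError(f"categorical {self.name} needs >=2 categories")


@dataclass(frozen=True)
class VariableSchema:
    """Ordered collection of variables; order fixes column layout."""

    variables: tuple[Variable, ...]

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self):
        return iter(self.variables)

    def __getitem__(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def time_varying(self) -> tuple[Variable, ...]:
        return tuple(v for v in self.variables if v.kind == TIME_VARYING)

    @property
    def time_invariant(self) -> tuple[Variable, ...]:
        return tuple(v for v in self.variables if v.kind == TIME_INVARIANT)

    @property
    def auxiliary_columns(self) -> tuple[str, ...]:
        """One imputation indicator per time-varying variable."""
        return tuple(f"{v.name}__observed" for v in self.time_varying)

    def feature_columns(self) -> tuple[str, ...]:
        """Full ordered feature layout: originals + indicators + elapsed."""
        return (
            tuple(v.name for v in self.variables)
            + self.auxiliary_columns
            + ELAPSED_COLUMNS
        )

    @property
    def n_feature_columns(self) -> int:
        return len(self.variables) + len(self.time_varying) + 2

    def subset(self, names: Iterable[str]) -> "VariableSchema":
        """Schema restricted to ``names``, preserving this schema's order."""
        keep = set(names)
        missing = keep - {v.name for v in self.variables}
        if missing:
            raise KeyError(f"unknown variables: {sorted(missing)}")
        return VariableSchema(tuple(v for v in self.variables if v.name in keep))

    def with_normal_flags(self, flags: dict[str, bool]) -> "VariableSchema":
        """Return a copy with resolved mean/median imputation flags."""
        out = []
        for v in self.variables:
            if v.name in flags and v.dtype == CONTINUOUS:
                out.append(replace(v, normal_flag=bool(flags[v.name])))
            else:
                out.append(v)
        return VariableSchema(tuple(out))


def _cont(name: str, kind: str, normal: Optional[bool] = None) -> Variable:
    return Variable(name, kind, CONTINUOUS, normal_flag=normal)


def _cat(name: str, n: int) -> Variable:
    return Variable(name, TIME_INVARIANT, CATEGORICAL, n_categories=n)


# The 10 time-varying variables of the full schema (vitals + settings).
_TIME_VARYING_FULL = (
    "sbp",
    "dbp",
    "heart_rate",
    "respiratory_rate",
    "body_temperature",
    "blood_flow_rate",
    "ultrafiltration_rate",
    "dialysate_temperature",
    "venous_pressure",
    "transmembrane_pressure",
)

_CONTINUOUS_INVARIANT_FULL = (
    ("age", True),
    ("predialytic_weight", True),
    ("dry_weight", True),
    ("target_uf_volume", False),
    ("dialysate_sodium", True),
    ("dialysate_calcium", True),
    ("hemoglobin", True),
    ("albumin", False),
    ("calcium", True),
    ("phosphate", False),
    ("sodium", True),
    ("potassium", True),
    ("creatinine", False),
    ("bun", False),
    ("glucose", False),
    ("crp", False),
    ("pth", False),
    ("ferritin", False),
    ("transferrin_saturation", False),
    ("bicarbonate", True),
    ("chloride", True),
    ("magnesium", True),
    ("uric_acid", True),
    ("total_cholesterol", True),
    ("triglyceride", False),
    ("ldl_cholesterol", True),
    ("hdl_cholesterol", False),
    ("wbc", False),
    ("platelet", True),
    ("ast", False),
    ("alt", False),
    ("alkaline_phosphatase", False),
    ("total_bilirubin", False),
)

_CATEGORICAL_INVARIANT_FULL = (
    ("sex", 2),
    ("hemodialysis_type", 4),
    ("vascular_access", 4),
    ("dialyzer_type", 4),
    ("anticoagulant_type", 3),
    ("diabetes_mellitus", 2),
    ("hypertension_dx", 2),
    ("coronary_artery_disease", 2),
    ("heart_failure", 2),
    ("atrial_fibrillation", 2),
    ("cerebrovascular_disease", 2),
    ("peripheral_artery_disease", 2),
    ("copd", 2),
    ("chronic_liver_disease", 2),
    ("malignancy", 2),
    ("antihypertensive_drug", 2),
    ("oral_hypoglycemic_agent", 2),
    ("subcutaneous_insulin", 2),
    ("statin", 2),
    ("erythropoietin", 2),
    ("iron_supplement", 2),
    ("phosphate_binder", 2),
    ("vitamin_d_analog", 2),
)


def full_schema() -> VariableSchema:
    """The full 66-variable schema: 56 time-invariant + 10 time-varying."""
    variables = (
        tuple(_cont(n, TIME_INVARIANT, f) for n, f in _CONTINUOUS_INVARIANT_FULL)
        + tuple(_cat(n, k) for n, k in _CATEGORICAL_INVARIANT_FULL)
        + tuple(_cont(n, TIME_VARYING) for n in _TIME_VARYING_FULL)
    )
    return VariableSchema(variables)


def compact_schema() -> VariableSchema:
    """A reduced schema (12 time-invariant + 6 time-varying) for fast
    experiments and tests; layout rules are identical to the full schema."""
    variables = (
        _cont("age", TIME_INVARIANT, True),
        _cont("predialytic_weight", TIME_INVARIANT, True),
        _cont("dry_weight", TIME_INVARIANT, True),
        _cont("hemoglobin", TIME_INVARIANT, True),
        _cont("albumin", TIME_INVARIANT, False),
        _cont("calcium", TIME_INVARIANT, True),
        _cont("potassium", TIME_INVARIANT, True),
        _cat("sex", 2),
        _cat("vascular_access", 4),
        _cat("diabetes_mellitus", 2),
        _cat("hypertension_dx", 2),
        _cat("antihypertensive_drug", 2),
        _cont("sbp", TIME_VARYING),
        _cont("dbp", TIME_VARYING),
        _cont("heart_rate", TIME_VARYING),
        _cont("body_temperature", TIME_VARYING),
        _cont("blood_flow_rate", TIME_VARYING),
        _cont("ultrafiltration_rate", TIME_VARYING),
    )
    return VariableSchema(variables)
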