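"""Feature pipeline: imputation, indicator columns, normalization and
previous-session stacking into model-ready bundles.

Imputation rules
----------------
* time-invariant continuous, normally distributed -> training mean
* time-invariant continuous, skewed, and categorical -> training median
  (categorical median = median of frequency-ordered integer codes)
* time-varying -> forward fill; leading nulls fall back to the most recent
  value from the matched previous session, then to the training median

One auxiliary indicator column per time-varying variable records the
imputation status of each cell: 0 = imputed, 1 = originally observed.
Continuous variables (including the two elapsed-time features) are
z-scored with statistics fitted on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .data import RawSession, SessionSet
from .labeling import LabelTrack
from .schema import (
    CATEGORICAL,
    CONTINUOUS,
    ELAPSED_COLUMNS,
    VariableSchema,
)


class SchemaError(KeyError):
    pass


class AssemblyError(ValueError):
    pass


@dataclass
class ContinuousStats:
    mean: float
    sd: float
    median: float
    normal_flag: bool

    @property
    def fill_value(self) -> float:
        return self.mean if self.normal_flag else self.median


@dataclass
class CategoricalStats:
    code_map: dict
    median_code: int
    n_levels: int


@dataclass
class NormalizationStats:
    """Training-split statistics for every schema variable plus the two
    elapsed-time features. Fitted once on training data, applied to all
    splits (no leakage)."""

    continuous: dict[str, ContinuousStats] = field(default_factory=dict)
    categorical: dict[str, CategoricalStats] = field(default_factory=dict)

    def encode_category(self, name: str, value) -> int:
        cs = self.categorical[name]
        return cs.code_map.get(value, cs.median_code)


_SKEW_NORMAL_LIMIT = 1.0  # |skewness| below this => mean imputation


def fit_statistics(
    session_sets: Sequence[SessionSet], schema: VariableSchema
) -> NormalizationStats:
    """Fit imputation/normalization statistics on training session sets."""
    if not session_sets:
        raise ValueError("cannot fit statistics on an empty training split")
    stats = NormalizationStats()
    sessions = [ss.current for ss in session_sets]

    def _fit_cont(name: str, values: np.ndarray, declared: Optional[bool]):
        values = values[np.isfinite(values)]
        if values.size == 0:
            raise AssemblyError(f"variable {name!r} has no observed values")
        sd = float(np.std(values))
        if sd <= 0:
            raise AssemblyError(f"variable {name!r} is constant in training data")
        normal = (
            declared
            if declared is not None
            else bool(abs(sps.skew(values)) < _SKEW_NORMAL_LIMIT)
        )
        stats.continuous[name] = ContinuousStats(
            mean=float(np.mean(values)),
            sd=sd,
            median=float(np.median(values)),
            normal_flag=normal,
        )

    for v in schema.time_invariant:
        raw = [s.static.get(v.name) for s in sessions]
        if v.dtype == CONTINUOUS:
            arr = np.array(
                [np.nan if x is None else float(x) for x in raw], dtype=float
            )
            _fit_cont(v.name, arr, v.normal_flag)
        else:
            observed = [x for x in raw if x is not None]
            if not observed:
                raise AssemblyError(f"categorical {v.name!r} fully missing")
            levels, counts = np.unique(observed, return_counts=True)
            order = sorted(
                range(len(levels)), key=lambda i: (-counts[i], levels[i])
            )
            code_map = {levels[i]: rank for rank, i in enumerate(order)}
            codes = np.array([code_map[x] for x in observed])
            stats.categorical[v.name] = CategoricalStats(
                code_map=code_map,
                median_code=int(np.median(codes)),
                n_levels=max(len(levels), v.n_categories),
            )

    for v in schema.time_varying:
        vals = np.concatenate(
            [s.measurements.get(v.name, np.empty(0)) for s in sessions]
        )
        _fit_cont(v.name, vals, v.normal_flag)

    # elapsed-time features, z-scored like other continuous variables
    all_times = np.concatenate([s.times for s in sessions])
    _fit_cont(ELAPSED_COLUMNS[0], all_times, None)
    intervals = np.array(
        [
            ss.interval_from_previous_min()
            for ss in session_sets
            if ss.interval_from_previous_min() is not None
        ],
        dtype=float,
    )
    if intervals.size == 0:
        intervals = np.array([7.0 * 24 * 60, 2.0 * 24 * 60, 3.0 * 24 * 60])
    _fit_cont(ELAPSED_COLUMNS[1], intervals, None)
    return stats


def impute_time_invariant(
    values: dict, schema: VariableSchema, stats: NormalizationStats
) -> dict:
    """Complete a static covariate map. Continuous values stay in value
    space; categorical values become frequency-ordered integer codes."""
    out: dict[str, float | int] = {}
    for v in schema.time_invariant:
        if v.dtype == CONTINUOUS and v.name not in stats.continuous:
            raise SchemaError(v.name)
        if v.dtype == CATEGORICAL and v.name not in stats.categorical:
            raise SchemaError(v.name)
        raw = values.get(v.name)
        if v.dtype == CONTINUOUS:
            if raw is None or not np.isfinite(float(raw)):
                out[v.name] = stats.continuous[v.name].fill_value
            else:
                out[v.name] = float(raw)
        else:
            cs = stats.categorical[v.name]
            out[v.name] = (
                cs.median_code if raw is None else stats.encode_category(v.name, raw)
            )
    return out


def forward_fill_time_varying(
    series: np.ndarray,
    prev_session_value: Optional[float] = None,
    fallback: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-fill one time-ordered series.

    Returns (filled series, observed mask) where mask is True for cells
    holding an originally observed value. Leading nulls take
    ``prev_session_value`` when given, else ``fallback``.
    """
    series = np.asarray(series, dtype=float)
    observed = np.isfinite(series)
    filled = series.copy()
    last: Optional[float] = None
    for i in range(len(filled)):
        if observed[i]:
            last = filled[i]
        elif last is not None:
            filled[i] = last
        elif prev_session_value is not None:
            filled[i] = prev_session_value
        elif fallback is not None:
            filled[i] = fallback
        else:
            raise AssemblyError("leading null with no fallback value")
    return filled, observed


def build_auxiliary_indicators(observed_mask: np.ndarray) -> np.ndarray:
    """Indicator matrix from an observed-cell mask: 1 = observed,
    0 = imputed (the source convention is preserved)."""
    mask = np.asarray(observed_mask)
    return mask.astype(float)


def normalize_continuous(
    values: np.ndarray, cs: ContinuousStats
) -> np.ndarray:
    if cs.sd <= 0:
        raise AssemblyError("zero standard deviation")
    return (np.asarray(values, dtype=float) - cs.mean) / cs.sd


def denormalize_continuous(
    zscores: np.ndarray, cs: ContinuousStats
) -> np.ndarray:
    return np.asarray(zscores, dtype=float) * cs.sd + cs.mean


@dataclass
class FeatureBundle:
    """Model-ready representation of one session (and, recursively one
    level deep, its matched previous sessions).

    ``temporal`` columns are ordered: time-varying variables (schema
    order, z-scored), auxiliary indicators (same order), then the two
    elapsed-time features.
    """

    session_id: str
    times: np.ndarray                      # [T] native minutes
    static_cont: np.ndarray                # [n_static_cont] z-scores
    static_cat: np.ndarray                 # [n_static_cat] int codes
    temporal: np.ndarray                   # [T, 2*n_tv + 2]
    labels: np.ndarray                     # [T, 3]
    label_valid: np.ndarray                # [T] bool
    schema: VariableSchema
    previous: tuple[Optional["FeatureBundle"], ...] = ()
    previous_mask: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_timesteps(self) -> int:
        return len(self.times)

    @property
    def n_feature_columns(self) -> int:
        """Total model-facing columns: originals + indicators + elapsed."""
        n_static = len(self.static_cont) + len(self.static_cat)
        return n_static + self.temporal.shape[1]

    def feature_column_names(self) -> tuple[str, ...]:
        sc = [v.name for v in self.schema.time_invariant if v.dtype == CONTINUOUS]
        cc = [v.name for v in self.schema.time_invariant if v.dtype == CATEGORICAL]
        tv = [v.name for v in self.schema.time_varying]
        aux = list(self.schema.auxiliary_columns)
        return tuple(sc + cc + tv + aux + list(ELAPSED_COLUMNS))


def _last_observed(session: Optional[RawSession], name: str) -> Optional[float]:
    if session is None:
        return None
    vals = session.measurements.get(name)
    if vals is None:
        return None
    obs = np.isfinite(vals)
    if not obs.any():
        return None
    return float(vals[obs][-1])


def _assemble_single(
    session: RawSession,
    schema: VariableSchema,
    stats: NormalizationStats,
    labels: Optional[LabelTrack],
    prev_for_fill: Optional[RawSession],
    interval_prev_min: Optional[float],
) -> FeatureBundle:
    static = impute_time_invariant(session.static, schema, stats)
    sc_names = [v.name for v in schema.time_invariant if v.dtype == CONTINUOUS]
    cat_names = [v.name for v in schema.time_invariant if v.dtype == CATEGORICAL]
    static_cont = np.array(
        [
            normalize_continuous(static[n], stats.continuous[n])
            for n in sc_names
        ],
        dtype=float,
    )
    static_cat = np.array([static[n] for n in cat_names], dtype=int)

    T = session.n_timesteps
    tv_names = [v.name for v in schema.time_varying]
    tv_cols, aux_cols = [], []
    for name in tv_names:
        series = session.measurements.get(name, np.full(T, np.nan))
        filled, observed = forward_fill_time_varying(
            series,
            prev_session_value=_last_observed(prev_for_fill, name),
            fallback=stats.continuous[name].median,
        )
        tv_cols.append(normalize_continuous(filled, stats.continuous[name]))
        aux_cols.append(build_auxiliary_indicators(observed))

    elapsed = normalize_continuous(
        session.times, stats.continuous[ELAPSED_COLUMNS[0]]
    )
    iv_stats = stats.continuous[ELAPSED_COLUMNS[1]]
    iv = iv_stats.median if interval_prev_min is None else interval_prev_min
    interval = np.full(T, normalize_continuous(np.array([iv]), iv_stats)[0])

    temporal = np.column_stack(tv_cols + aux_cols + [elapsed, interval])
    if not np.all(np.isfinite(temporal)) or not np.all(np.isfinite(static_cont)):
        raise AssemblyError(f"{session.session_id}: nulls remain after assembly")

    if labels is not None:
        lab, valid = labels.stacked(), labels.valid.copy()
    else:
        lab, valid = np.zeros((T, 3)), np.zeros(T, dtype=bool)
    return FeatureBundle(
        session_id=session.session_id,
        times=session.times.copy(),
        static_cont=static_cont,
        static_cat=static_cat,
        temporal=temporal,
        labels=lab,
        label_valid=valid,
        schema=schema,
    )


def assemble_feature_bundle(
    session_set: SessionSet,
    labels: Optional[LabelTrack],
    schema: VariableSchema,
    stats: NormalizationStats,
    n_prev_slots: Optional[int] = None,
) -> FeatureBundle:
    """Build the FeatureBundle for a matched session set.

    Previous sessions run through the same single-session pipeline (one
    recursion level); unavailable slots stay ``None`` with mask False and
    are zero-filled at batch time.
    """
    k = session_set.k if n_prev_slots is None else n_prev_slots
    prev_sessions = list(session_set.previous[:k])
    bundle = _assemble_single(
        session_set.current,
        schema,
        stats,
        labels,
        prev_for_fill=prev_sessions[0] if prev_sessions else None,
        interval_prev_min=session_set.interval_from_previous_min(),
    )
    prev_bundles: list[Optional[FeatureBundle]] = []
    mask = np.zeros(k, dtype=bool)
    for i in range(k):
        if i < len(prev_sessions):
            p = prev_sessions[i]
            deeper = prev_sessions[i + 1] if i + 1 < len(prev_sessions) else None
            prev_bundles.append(
                _assemble_single(
                    p, schema, stats, None, prev_for_fill=deeper,
                    interval_prev_min=None,
                )
            )
            mask[i] = True
        else:
            prev_bundles.append(None)
    bundle.previous = tuple(prev_bundles)
    bundle.previous_mask = mask
    return bundle


def assemble_bundles(
    session_sets: Iterable[SessionSet],
    label_map: dict[str, LabelTrack],
    schema: VariableSchema,
    stats: NormalizationStats,
    n_prev_slots: int = 5,
) -> list[FeatureBundle]:
    return [
        assemble_feature_bundle(
            ss,
            label_map.get(ss.current.session_id),
            schema,
            stats,
            n_prev_slots=n_prev_slots,
        )
        for ss in session_sets
    ]
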