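"""Cohort construction: exclusion filters, previous-session matching and
patient-level train/validation/test splitting.

Filters are applied sequentially in a fixed order (age, initial BP,
duration, BP gap); a session is tallied once, at the first criterion it
fails, so kept + excluded counts always reconstruct the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import Cohort, MalformedRecordError, RawSession, SessionSet

#: fixed exclusion order; tallies are well defined for multi-criterion failures
EXCLUSION_ORDER = ("age", "initial_bp", "duration", "bp_gap")


@dataclass(frozen=True)
class FilterCriteria:
    min_age_years: float = 18.0
    require_initial_bp: bool = True
    min_duration_h: float = 2.0
    max_duration_h: float = 6.0
    max_bp_gap_h: float = 1.5

    def __post_init__(self) -> None:
        if self.min_duration_h >= self.max_duration_h:
            raise ValueError("min_duration_h must be < max_duration_h")
        if min(self.min_age_years, self.min_duration_h, self.max_bp_gap_h) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass
class ExclusionTally:
    """Per-criterion exclusion counts plus the kept count."""

    total: int = 0
    excluded: dict[str, int] = field(
        default_factory=lambda: {k: 0 for k in EXCLUSION_ORDER}
    )
    kept: int = 0

    def remaining(self) -> int:
        return self.total - sum(self.excluded.values())

    @classmethod
    def from_counts(cls, total: int, excluded: dict[str, int]) -> "ExclusionTally":
        """Build a tally from externally reported per-criterion counts."""
        unknown = set(excluded) - set(EXCLUSION_ORDER)
        if unknown:
            raise ValueError(f"unknown criteria: {sorted(unknown)}")
        full = {k: int(excluded.get(k, 0)) for k in EXCLUSION_ORDER}
        tally = cls(total=int(total), excluded=full)
        tally.kept = tally.remaining()
        return tally


def _failed_criterion(session: RawSession, c: FilterCriteria) -> str | None:
    """First criterion (in EXCLUSION_ORDER) the session fails, or None."""
    if session.duration_min is None or not np.isfinite(session.duration_min):
        raise MalformedRecordError(f"{session.session_id}: missing duration")
    age = session.age
    if age is not None and age < c.min_age_years:
        return "age"
    if c.require_initial_bp and not session.has_initial_bp():
        return "initial_bp"
    hours = session.duration_min / 60.0
    if hours < c.min_duration_h or hours > c.max_duration_h:
        return "duration"
    bp_t = session.bp_times()
    if bp_t.size >= 2 and np.max(np.diff(bp_t)) > c.max_bp_gap_h * 60.0:
        return "bp_gap"
    # a lone initial BP followed by nothing for >1.5h of session
    if bp_t.size == 1 and session.duration_min - bp_t[0] > c.max_bp_gap_h * 60.0:
        return "bp_gap"
    return None


def filter_sessions(
    sessions: Iterable[RawSession],
    criteria: FilterCriteria = FilterCriteria(),
) -> tuple[list[RawSession], ExclusionTally]:
    """Apply the exclusion filters; returns (kept sessions, tally)."""
    tally = ExclusionTally()
    kept: list[RawSession] = []
    for s in sessions:
        tally.total += 1
        fail = _failed_criterion(s, criteria)
        if fail is None:
            kept.append(s)
            tally.kept += 1
        else:
            tally.excluded[fail] += 1
    return kept, tally


def match_previous_sessions(
    sessions: Sequence[RawSession],
    k: int = 5,
    window_days: float = 31.0,
) -> list[SessionSet]:
    """Match each session with its <=k most recent prior sessions within the
    window. Sessions must belong to one patient; output preserves input
    chronological order. Mask slots without a match are False."""
    ordered = sorted(sessions, key=lambda s: s.start_time)
    window = pd.Timedelta(days=window_days)
    out = []
    for i, cur in enumerate(ordered):
        candidates = [
            p
            for p in ordered[:i]
            if p.start_time < cur.start_time
            and cur.start_time - p.start_time <= window
        ]
        candidates.sort(key=lambda s: s.start_time, reverse=True)
        prev = tuple(candidates[:k])
        mask = tuple([True] * len(prev) + [False] * (k - len(prev)))
        out.append(SessionSet(current=cur, previous=prev, availability_mask=mask))
    return out


def match_cohort(
    cohort: Cohort, k: int = 5, window_days: float = 31.0
) -> list[SessionSet]:
    """Previous-session matching across a whole cohort, per patient."""
    out: list[SessionSet] = []
    for _, sess in sorted(cohort.by_patient().items()):
        out.extend(match_previous_sessions(sess, k=k, window_days=window_days))
    return out


@dataclass(frozen=True)
class SplitAssignment:
    assignment: dict[str, str]
    seed: int

    def patients(self, split: str) -> list[str]:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def __getitem__(self, patient_id: str) -> str:
        return self.assignment[patient_id]


def split_by_patient(
    patient_ids: Iterable[str],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition patients into train/validation/test.

    Split is by patient, so session-level leakage is impossible by
    construction. Sizes are floor(frac*n) with the remainder assigned to
    the splits with the largest fractional parts.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    ids = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    names = ("train", "validation", "test")
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    for j in sorted(range(3), key=lambda j: raw[j] - counts[j], reverse=True)[:rem]:
        counts[j] += 1
    assignment: dict[str, str] = {}
    pos = 0
    for name, cnt in zip(names, counts):
        for pid in order[pos : pos + cnt]:
            assignment[pid] = name
        pos += cnt
    return SplitAssignment(assignment=assignment, seed=seed)
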