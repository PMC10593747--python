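"""Per-timestamp outcome labels under a prospective 1-hour horizon.

Three binary outcomes are labeled at every recorded timestamp t using the
BP recordings in the half-open window (t, t+horizon]:

* ``idh1``  — any future SBP < 90 mmHg
* ``idh2``  — any future SBP drop >= 20 mmHg, or MAP drop >= 10 mmHg, from
  the session's initial reading
* ``idhtn`` — any future SBP rise >= 10 mmHg from the initial SBP

A timestamp with no BP recording inside the window has no defined label and
is excluded from training and evaluation. Timestamps after an event are
still labeled (real-time prediction continues over the whole session).

Session-level ``idhtn2`` flags IDHTN in >= 4 of 6 consecutive sessions
(the index session plus the 5 preceding ones); it is undefined for
sessions with fewer than 5 predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import RawSession

HORIZON_MIN = 60.0
OUTCOME_NAMES = ("idh1", "idh2", "idhtn")


class InvalidReadingError(ValueError):
    pass


def compute_map(sbp: float, dbp: float) -> float:
    """Mean arterial pressure: (2*DBP + SBP) / 3."""
    if not (sbp > dbp > 0):
        raise InvalidReadingError(f"require SBP > DBP > 0, got ({sbp}, {dbp})")
    return (2.0 * dbp + sbp) / 3.0


def _window(times: np.ndarray, t: float, horizon: float) -> np.ndarray:
    return (times > t) & (times <= t + horizon)


def label_idh1(
    times: np.ndarray, sbp: np.ndarray, t: float, horizon: float = HORIZON_MIN
) -> Optional[bool]:
    """True iff any SBP recording in (t, t+horizon] is < 90 mmHg;
    None when no recording falls inside the window."""
    w = _window(times, t, horizon) & np.isfinite(sbp)
    if not w.any():
        return None
    return bool(np.any(sbp[w] < 90.0))


def label_idh2(
    times: np.ndarray,
    sbp: np.ndarray,
    dbp: np.ndarray,
    initial_sbp: float,
    initial_dbp: float,
    t: float,
    horizon: float = HORIZON_MIN,
) -> Optional[bool]:
    """True iff any recording in the window shows an SBP drop >= 20 or a
    MAP drop >= 10 from the initial reading."""
    initial_map = compute_map(initial_sbp, initial_dbp)
    w = _window(times, t, horizon)
    w_sbp = w & np.isfinite(sbp)
    if np.any(initial_sbp - sbp[w_sbp] >= 20.0):
        return True
    w_map = w & np.isfinite(sbp) & np.isfinite(dbp)
    if w_map.any():
        maps = (2.0 * dbp[w_map] + sbp[w_map]) / 3.0
        if np.any(initial_map - maps >= 10.0):
            return True
    if not (w_sbp.any() or w_map.any()):
        return None
    return False


def label_idhtn(
    times: np.ndarray,
    sbp: np.ndarray,
    initial_sbp: float,
    t: float,
    horizon: float = HORIZON_MIN,
) -> Optional[bool]:
    """True iff any SBP in the window rose >= 10 mmHg above the initial SBP."""
    w = _window(times, t, horizon) & np.isfinite(sbp)
    if not w.any():
        return None
    return bool(np.any(sbp[w] - initial_sbp >= 10.0))


@dataclass
class LabelTrack:
    """Labels for every recorded timestamp of one session.

    ``valid[i]`` is False where the label is undefined (no future BP in the
    horizon); label values at invalid positions are False placeholders.
    """

    session_id: str
    times: np.ndarray
    idh1: np.ndarray
    idh2: np.ndarray
    idhtn: np.ndarray
    valid: np.ndarray
    horizon_min: float = HORIZON_MIN

    def stacked(self) -> np.ndarray:
        """[T, 3] float array in OUTCOME_NAMES order."""
        return np.stack([self.idh1, self.idh2, self.idhtn], axis=1).astype(float)


def label_session(session: RawSession, horizon: float = HORIZON_MIN) -> LabelTrack:
    """Label all recorded timestamps of a session.

    Requires an initial BP reading at elapsed 0 (cohort filters guarantee
    this for analysis sessions).
    """
    times = session.times
    sbp = session.measurements.get("sbp", np.full(len(times), np.nan))
    dbp = session.measurements.get("dbp", np.full(len(times), np.nan))
    if len(times) == 0 or times[0] != 0.0 or not (
        np.isfinite(sbp[0]) and np.isfinite(dbp[0])
    ):
        raise InvalidReadingError(
            f"{session.session_id}: no initial BP reading at elapsed 0"
        )
    init_sbp, init_dbp = float(sbp[0]), float(dbp[0])
    T = len(times)
    idh1 = np.zeros(T, dtype=bool)
    idh2 = np.zeros(T, dtype=bool)
    idhtn = np.zeros(T, dtype=bool)
    valid = np.zeros(T, dtype=bool)
    for i, t in enumerate(times):
        l1 = label_idh1(times, sbp, t, horizon)
        l2 = label_idh2(times, sbp, dbp, init_sbp, init_dbp, t, horizon)
        l3 = label_idhtn(times, sbp, init_sbp, t, horizon)
        if l1 is None and l2 is None and l3 is None:
            continue
        valid[i] = True
        idh1[i] = bool(l1)
        idh2[i] = bool(l2)
        idhtn[i] = bool(l3)
    return LabelTrack(
        session_id=session.session_id,
        times=times.copy(),
        idh1=idh1,
        idh2=idh2,
        idhtn=idhtn,
        valid=valid,
        horizon_min=horizon,
    )


def session_idhtn_occurrence(session: RawSession) -> bool:
    """Whether IDHTN occurred anywhere in the session (SBP rise >= 10 from
    the initial SBP), used as input to the IDHTN-2 definition."""
    sbp = session.measurements.get("sbp")
    if sbp is None or not len(sbp) or not np.isfinite(sbp[0]):
        return False
    obs = np.isfinite(sbp)
    return bool(np.any(sbp[obs] - sbp[0] >= 10.0))


def label_idhtn2(
    idhtn_flags: Sequence[bool], window: int = 6, min_count: int = 4
) -> list[Optional[bool]]:
    """Session-level IDHTN-2 per index session of an ordered sequence.

    Entry i is True iff >= ``min_count`` of the ``window`` consecutive
    sessions ending at i (inclusive) had IDHTN; None while fewer than
    ``window`` sessions exist.
    """
    flags = [bool(f) for f in idhtn_flags]
    out: list[Optional[bool]] = []
    for i in range(len(flags)):
        if i + 1 < window:
            out.append(None)
        else:
            out.append(sum(flags[i - window + 1 : i + 1]) >= min_count)
    return out
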