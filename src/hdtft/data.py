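"""Core session containers shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .schema import VariableSchema

MAX_SESSION_MIN = 360.0


class MalformedRecordError(ValueError):
    """A session record violates a structural invariant."""


@dataclass
class RawSession:
    """One hemodialysis session.

    ``static`` maps time-invariant variable names to values (``None`` for
    missing). ``times`` holds minutes elapsed from session start, strictly
    increasing; ``measurements`` maps each time-varying variable name to an
    array aligned with ``times`` (``NaN`` for missing).
    """

    patient_id: str
    session_id: str
    start_time: pd.Timestamp
    duration_min: float
    static: dict[str, object]
    times: np.ndarray
    measurements: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.measurements = {
            k: np.asarray(v, dtype=float) for k, v in self.measurements.items()
        }

    @property
    def age(self) -> Optional[float]:
        v = self.static.get("age")
        return None if v is None else float(v)

    @property
    def n_timesteps(self) -> int:
        return len(self.times)

    def bp_times(self) -> np.ndarray:
        """Timestamps where both SBP and DBP are observed."""
        sbp = self.measurements.get("sbp")
        dbp = self.measurements.get("dbp")
        if sbp is None or dbp is None:
            return np.empty(0)
        ok = np.isfinite(sbp) & np.isfinite(dbp)
        return self.times[ok]

    def has_initial_bp(self) -> bool:
        t = self.bp_times()
        return t.size > 0 and t[0] == 0.0

    def validate(self) -> None:
        if self.duration_min is None or not np.isfinite(self.duration_min):
            raise MalformedRecordError(f"{self.session_id}: missing duration")
        if not (0 < self.duration_min <= MAX_SESSION_MIN):
            raise MalformedRecordError(
                f"{self.session_id}: duration {self.duration_min} outside (0, 360]"
            )
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise MalformedRecordError(f"{self.session_id}: times not increasing")
        sbp = self.measurements.get("sbp")
        dbp = self.measurements.get("dbp")
        if sbp is not None and dbp is not None:
            both = np.isfinite(sbp) & np.isfinite(dbp)
            if np.any(sbp[both] <= dbp[both]):
                raise MalformedRecordError(f"{self.session_id}: SBP <= DBP")


@dataclass
class SessionSet:
    """A current session matched with up to k previous sessions.

    ``previous`` is ordered most-recent-first; ``availability_mask[i]`` is
    True exactly when slot i holds a matched session.
    """

    current: RawSession
    previous: tuple[RawSession, ...]
    availability_mask: tuple[bool, ...]

    def __post_init__(self) -> None:
        if sum(self.availability_mask) != len(self.previous):
            raise ValueError("availability mask inconsistent with previous list")
        for p in self.previous:
            if p.patient_id != self.current.patient_id:
                raise ValueError("previous session from a different patient")
            if p.start_time >= self.current.start_time:
                raise ValueError("previous session does not precede current")

    @property
    def k(self) -> int:
        return len(self.availability_mask)

    def interval_from_previous_min(self) -> Optional[float]:
        """Minutes between the most recent previous session start and the
        current session start; ``None`` when no previous session matched."""
        if not self.previous:
            return None
        delta = self.current.start_time - self.previous[0].start_time
        return delta.total_seconds() / 60.0


@dataclass
class Cohort:
    """A set of sessions plus the schema that describes their variables."""

    schema: VariableSchema
    sessions: list[RawSession] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sessions)

    def patient_ids(self) -> list[str]:
        return sorted({s.patient_id for s in self.sessions})

    def by_patient(self) -> dict[str, list[RawSession]]:
        out: dict[str, list[RawSession]] = {}
        for s in self.sessions:
            out.setdefault(s.patient_id, []).append(s)
        for v in out.values():
            v.sort(key=lambda s: s.start_time)
        return out

    # ------------------------------------------------------------------ IO

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(sessions table, long-format measurements table)."""
        static_rows = []
        meas_rows: dict[str, list] = {
            "patient_id": [],
            "session_id": [],
            "elapsed_min": [],
            "variable": [],
            "value": [],
        }
        tv_names = [v.name for v in self.schema.time_varying]
        for s in self.sessions:
            row = {
                "patient_id": s.patient_id,
                "session_id": s.session_id,
                "start_time": s.start_time,
                "duration_min": s.duration_min,
            }
            row.update({k: s.static.get(k) for k in
                        (v.name for v in self.schema.time_invariant)})
            static_rows.append(row)
            for name in tv_names:
                vals = s.measurements.get(name)
                if vals is None:
                    continue
                obs = np.isfinite(vals)
                n = int(obs.sum())
                meas_rows["patient_id"].extend([s.patient_id] * n)
                meas_rows["session_id"].extend([s.session_id] * n)
                meas_rows["elapsed_min"].extend(s.times[obs].tolist())
                meas_rows["variable"].extend([name] * n)
                meas_rows["value"].extend(vals[obs].tolist())
        return pd.DataFrame(static_rows), pd.DataFrame(meas_rows)

    @classmethod
    def from_frames(
        cls,
        schema: VariableSchema,
        sessions_df: pd.DataFrame,
        measurements_df: pd.DataFrame,
    ) -> "Cohort":
        tv_names = [v.name for v in schema.time_varying]
        ti_names = [v.name for v in schema.time_invariant]
        grouped = (
            measurements_df.groupby("session_id")
            if len(measurements_df)
            else None
        )
        sessions = []
        for _, row in sessions_df.iterrows():
            sid = row["session_id"]
            static = {}
            for k in ti_names:
                v = row.get(k)
                static[k] = None if pd.isna(v) else v
            if grouped is not None and sid in grouped.groups:
                g = grouped.get_group(sid)
                times = np.sort(np.unique(g["elapsed_min"].to_numpy(float)))
            else:
                g = None
                times = np.empty(0)
            meas = {n: np.full(len(times), np.nan) for n in tv_names}
            if g is not None:
                idx = {t: i for i, t in enumerate(times)}
                for t, var, val in zip(
                    g["elapsed_min"], g["variable"], g["value"]
                ):
                    if var in meas:
                        meas[var][idx[float(t)]] = val
            sessions.append(
                RawSession(
                    patient_id=str(row["patient_id"]),
                    session_id=str(sid),
                    start_time=pd.Timestamp(row["start_time"]),
                    duration_min=float(row["duration_min"]),
                    static=static,
                    times=times,
                    measurements=meas,
                )
            )
        return cls(schema=schema, sessions=sessions)

    def write(self, out_dir: str | Path, fmt: str = "csv") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sessions_df, meas_df = self.to_frames()
        if fmt == "csv":
            sessions_df.to_csv(out / "sessions.csv", index=False)
            meas_df.to_csv(out / "measurements.csv", index=False)
        elif fmt == "parquet":
            sessions_df.to_parquet(out / "sessions.parquet", index=False)
            meas_df.to_parquet(out / "measurements.parquet", index=False)
        else:
            raise ValueError(f"unknown format {fmt!r}")

    @classmethod
    def read(cls, in_dir: str | Path, schema: VariableSchema) -> "Cohort":
        p = Path(in_dir)
        if (p / "sessions.csv").exists():
            sdf = pd.read_csv(p / "sessions.csv", parse_dates=["start_time"])
            mdf = pd.read_csv(p / "measurements.csv")
        elif (p / "sessions.parquet").exists():
            sdf = pd.read_parquet(p / "sessions.parquet")
            mdf = pd.read_parquet(p / "measurements.parquet")
        else:
            raise FileNotFoundError(f"no cohort tables under {p}")
        return cls.from_frames(schema, sdf, mdf)
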