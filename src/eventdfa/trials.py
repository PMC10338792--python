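"""Domain types and operations for reaction-time trial series.

A :class:`TrialSeries` holds the ordered trials of one subject in one
session and time-stress condition: the latency sequence Y(n) in
operational (trial-number) time.  Operations here implement the standard
preprocessing of a Go/NoGo latency table: pruning of extreme latencies,
concatenation of sessions into one long series, and the commission-error
rate (responses to friendly/NoGo targets).

The CSV schema (one row per trial) is::

    subject,session,condition,trial,rt_ms,target_type,responded

with ``condition`` in {low, high}, ``target_type`` in {enemy, friendly},
``responded`` in {0, 1} and a missing ``rt_ms`` encoded as an empty field.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateRateError,
    InvalidInputError,
    ParameterError,
)

__all__ = [
    "Trial",
    "TrialSeries",
    "EventSeries",
    "TRIAL_COLUMNS",
    "prune_reaction_times",
    "concatenate_sessions",
    "commission_rate",
    "read_trial_table",
    "write_trial_table",
    "series_from_table",
]

TRIAL_COLUMNS = [
    "subject",
    "session",
    "condition",
    "trial",
    "rt_ms",
    "target_type",
    "responded",
]

_CONDITIONS = ("low", "high")
_TARGETS = ("enemy", "friendly")


@dataclass(frozen=True)
class Trial:
    """One Go/NoGo trial: Y(n) at operational time n (1-based)."""

    trial_index: int
    reaction_time_ms: float | None
    target_type: str
    responded: bool

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise InvalidInputError("trial_index must be a positive integer")
        if self.target_type not in _TARGETS:
            raise InvalidInputError(f"unknown target_type {self.target_type!r}")
        if self.responded:
            if self.reaction_time_ms is None or not self.reaction_time_ms > 0:
                raise InvalidInputError("responded trials need a positive latency")
        elif self.reaction_time_ms is not None:
            raise InvalidInputError("non-response trials carry no latency")


@dataclass
class TrialSeries:
    """Ordered trials of one subject under one condition.

    ``session`` is the 1-based session number, or the label ``"appended"``
    for six sessions concatenated.  The backing frame has columns
    ``trial, rt_ms, target_type, responded`` (plus ``session`` for
    appended series, recording each trial's source session).
    """

    subject_id: str
    session: Union[int, str]
    condition: str
    frame: pd.DataFrame
    n_pruned: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITIONS:
            raise InvalidInputError(f"condition must be one of {_CONDITIONS}")
        df = self.frame
        if "session" not in df.columns:
            df = df.assign(session=self.session)
            self.frame = df
        for sess, grp in df.groupby("session", sort=False):
            if np.any(np.diff(grp["trial"].to_numpy()) <= 0):
                raise InvalidInputError(
                    f"trial indices must be strictly increasing (session {sess})"
                )
        resp = df["responded"].to_numpy(dtype=bool)
        rts = df["rt_ms"].to_numpy(dtype=float)
        if np.any(resp & ~(rts > 0)):
            raise InvalidInputError("responded trials must have rt_ms > 0")
        if np.any(~resp & ~np.isnan(rts)):
            raise InvalidInputError("non-response trials must have missing rt_ms")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def trials(self) -> List[Trial]:
        out = []
        for row in self.frame.itertuples(index=False):
            rt = None if (not row.responded or pd.isna(row.rt_ms)) else float(row.rt_ms)
            out.append(
                Trial(int(row.trial), rt, str(row.target_type), bool(row.responded))
            )
        return out

    def reaction_times(self) -> np.ndarray:
        """Latencies of responded trials, in trial order: the Y(n) signal."""
        df = self.frame
        return df.loc[df["responded"].astype(bool), "rt_ms"].to_numpy(dtype=float)


@dataclass(frozen=True)
class EventSeries:
    """A +/-1-valued signal on the uniform 1-ms event-time grid.

    Stored compactly as (durations, signs): interval i holds the constant
    sign ``signs[i]`` for ``durations[i]`` consecutive samples.  The dense
    sample vector and the cumulative interval boundaries are derived.
    """

    durations: np.ndarray
    signs: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=np.int64)
        s = np.asarray(self.signs, dtype=np.int8)
        if d.ndim != 1 or d.size == 0:
            raise InvalidInputError("durations must be a non-empty 1-d sequence")
        if d.shape != s.shape:
            raise InvalidInputError("durations and signs must have equal length")
        if np.any(d < 1):
            raise InvalidInputError("durations must be >= 1 ms")
        if not np.all(np.abs(s) == 1):
            raise InvalidInputError("signs must be +1 or -1")
        object.__setattr__(self, "durations", d)
        object.__setattr__(self, "signs", s)

    def __len__(self) -> int:
        return int(self.durations.sum())

    @property
    def n_intervals(self) -> int:
        return self.durations.size

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative interval end times (ms); the last equals len(self)."""
        return np.cumsum(self.durations)

    @property
    def samples(self) -> np.ndarray:
        """Dense +/-1 sample vector X(t) on the 1-ms grid."""
        return np.repeat(self.signs, self.durations)

    def to_csv(self, path) -> None:
        """Write the dense signal to a two-column (t_ms, value) CSV."""
        pd.DataFrame(
            {"t_ms": np.arange(1, len(self) + 1), "value": self.samples}
        ).to_csv(path, index=False)


def prune_reaction_times(
    series: TrialSeries, lo: float = 100.0, hi: float = 1500.0
) -> Tuple[TrialSeries, int]:
    """Keep responded trials with lo < rt_ms < hi (strict bounds).

    Non-response trials (omissions, correct rejections) carry no latency
    and are removed along with extreme latencies; original trial indices
    are preserved.  Returns the pruned series and the number of removed
    trials.  Pruning is idempotent.
    """
    if not lo < hi:
        raise ParameterError(f"need lo < hi, got ({lo}, {hi})")
    df = series.frame
    keep = (
        df["responded"].astype(bool)
        & (df["rt_ms"] > lo)
        & (df["rt_ms"] < hi)
    )
    n_removed = int((~keep).sum())
    pruned = replace(
        series, frame=df.loc[keep].reset_index(drop=True), n_pruned=n_removed
    )
    return pruned, n_removed


def concatenate_sessions(series_list: Sequence[TrialSeries]) -> TrialSeries:
    """Concatenate one subject's sessions into a single "appended" series.

    Trial order is session order then within-session order; no gap padding
    is inserted between sessions (the event-time transform is insensitive
    to inter-trial spacing).  All inputs must share subject and condition
    and arrive in ascending session order.
    """
    if not series_list:
        raise InvalidInputError("need at least one series")
    first = series_list[0]
    if len(series_list) == 1:
        return first
    sessions = []
    for s in series_list:
        if s.subject_id != first.subject_id:
            raise InvalidInputError("cannot concatenate across subjects")
        if s.condition != first.condition:
            raise InvalidInputError("cannot concatenate across conditions")
        if not isinstance(s.session, (int, np.integer)):
            raise InvalidInputError("can only concatenate single-session series")
        sessions.append(int(s.session))
    if np.any(np.diff(sessions) <= 0):
        raise InvalidInputError("sessions must be in ascending order")
    frame = pd.concat([s.frame for s in series_list], ignore_index=True)
    return TrialSeries(
        subject_id=first.subject_id,
        session="appended",
        condition=first.condition,
        frame=frame,
    )


def commission_rate(series: TrialSeries) -> float:
    """Fraction of friendly-target (NoGo) trials that drew a response."""
    df = series.frame
    friendly = df["target_type"] == "friendly"
    n_friendly = int(friendly.sum())
    if n_friendly == 0:
        raise DegenerateRateError("commission rate undefined: no friendly trials")
    fired = int(df.loc[friendly, "responded"].astype(bool).sum())
    return fired / n_friendly


# ---------------------------------------------------------------------------
# CSV table I/O


def read_trial_table(path_or_buf) -> pd.DataFrame:
    """Read and validate a trial table CSV (see module docstring schema)."""
    df = pd.read_csv(
        path_or_buf, dtype={"subject": str}, float_precision="round_trip"
    )
    if list(df.columns) != TRIAL_COLUMNS:
        raise InvalidInputError(
            f"trial table must have columns {TRIAL_COLUMNS}, got {list(df.columns)}"
        )
    df["session"] = df["session"].astype(np.int64)
    df["trial"] = df["trial"].astype(np.int64)
    df["rt_ms"] = df["rt_ms"].astype(float)
    df["responded"] = df["responded"].astype(np.int64)
    bad_cond = set(df["condition"].unique()) - set(_CONDITIONS)
    if bad_cond:
        raise InvalidInputError(f"unknown condition values {sorted(bad_cond)}")
    bad_tt = set(df["target_type"].unique()) - set(_TARGETS)
    if bad_tt:
        raise InvalidInputError(f"unknown target_type values {sorted(bad_tt)}")
    if not df["responded"].isin([0, 1]).all():
        raise InvalidInputError("responded must be 0 or 1")
    return df


def write_trial_table(table: pd.DataFrame, path) -> None:
    """Write a trial table CSV; round-trips losslessly through read."""
    df = table.loc[:, TRIAL_COLUMNS].copy()
    df["responded"] = df["responded"].astype(np.int64)
    df.to_csv(path, index=False, na_rep="", lineterminator="\n")


def series_from_table(
    table: pd.DataFrame,
) -> Iterable[Tuple[str, str, int, TrialSeries]]:
    """Yield (subject, condition, session, TrialSeries) per table group."""
    cols = ["trial", "rt_ms", "target_type", "responded", "session"]
    for (subj, cond, sess), grp in table.groupby(
        ["subject", "condition", "session"], sort=True
    ):
        frame = grp.sort_values("trial")[cols].reset_index(drop=True)
        yield str(subj), str(cond), int(sess), TrialSeries(
            subject_id=str(subj),
            session=int(sess),
            condition=str(cond),
            frame=frame,
        )
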