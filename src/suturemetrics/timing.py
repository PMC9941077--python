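"""Session timing: total, per-stitch and intermediate times with penalties.

A session's raw total runs from the first needle entry to the last thread
cut.  Every required stitch left uncompleted adds a fixed penalty
(300 s by convention) so that a premature termination is never mistaken for
a fast finish.  Per-stitch time is needle entry to thread cut of that
stitch; intermediate time is the mean gap between the thread cut of one
completed stitch and the needle entry of the next completed stitch.
Seconds are used internally; reports convert to minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StitchEvents",
    "EventLog",
    "TimeSummary",
    "per_stitch_time",
    "intermediate_time",
    "total_time",
    "PENALTY_S",
]

PENALTY_S = 300.0


@dataclass(frozen=True)
class StitchEvents:
    """Needle-entry and thread-cut timestamps of one stitch attempt."""

    index: int
    needle_entry: float
    thread_cut: float | None = None  # None when the stitch was not completed

    def __post_init__(self) -> None:
        if not math.isfinite(self.needle_entry):
            raise ValueError("needle_entry must be finite")
        if self.thread_cut is not None:
            if not math.isfinite(self.thread_cut):
                raise ValueError("thread_cut must be finite")
            if self.thread_cut <= self.needle_entry:
                raise ValueError(
                    f"stitch {self.index}: thread_cut must follow needle_entry"
                )

    @property
    def completed(self) -> bool:
        return self.thread_cut is not None

    @property
    def end(self) -> float:
        return self.thread_cut if self.thread_cut is not None else self.needle_entry


@dataclass(frozen=True)
class EventLog:
    """Ordered stitch events of one session plus the required stitch count."""

    stitches: tuple[StitchEvents, ...]
    required_stitches: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "stitches", tuple(self.stitches))
        if not self.stitches:
            raise ValueError("event log must contain at least one needle entry")
        if self.required_stitches < 1:
            raise ValueError("required_stitches must be >= 1")
        idx = [s.index for s in self.stitches]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError("stitch indices must be unique and ascending")
        for prev, cur in zip(self.stitches, self.stitches[1:]):
            if cur.needle_entry < prev.end:
                raise ValueError(
                    "stitch events must be non-overlapping and ordered in time"
                )

    @property
    def completed(self) -> tuple[StitchEvents, ...]:
        return tuple(s for s in self.stitches if s.completed)

    @property
    def n_completed(self) -> int:
        return len(self.completed)

    def get(self, index: int) -> StitchEvents | None:
        for s in self.stitches:
            if s.index == index:
                return s
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stitch_index": [s.index for s in self.stitches],
                "needle_entry_s": [s.needle_entry for s in self.stitches],
                "thread_cut_s": [
                    s.thread_cut if s.thread_cut is not None else np.nan
                    for s in self.stitches
                ],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, required_stitches: int = 3) -> "EventLog":
        stitches = []
        for row in df.itertuples(index=False):
            cut = getattr(row, "thread_cut_s")
            stitches.append(
                StitchEvents(
                    index=int(getattr(row, "stitch_index")),
                    needle_entry=float(getattr(row, "needle_entry_s")),
                    thread_cut=None if pd.isna(cut) else float(cut),
                )
            )
        return cls(stitches=tuple(stitches), required_stitches=required_stitches)


@dataclass
class TimeSummary:
    """Timing outputs of one session, in seconds."""

    total_raw_s: float
    total_penalized_s: float
    per_stitch_s: dict[int, float]
    intermediate_s: float  # NaN when fewer than 2 completed stitches
    n_completed: int
    n_uncompleted: int
    penalty_s: float
    raw_flagged: bool  # True when no thread cut exists and raw span falls
    # back to the last recorded event

    def to_dict(self) -> dict:
        return {
            "total_raw_s": self.total_raw_s,
            "total_penalized_s": self.total_penalized_s,
            "total_raw_min": self.total_raw_s / 60.0,
            "total_penalized_min": self.total_penalized_s / 60.0,
            "per_stitch_s": {str(k): v for k, v in self.per_stitch_s.items()},
            "intermediate_s": self.intermediate_s,
            "n_completed": self.n_completed,
            "n_uncompleted": self.n_uncompleted,
            "penalty_s": self.penalty_s,
            "raw_flagged": self.raw_flagged,
        }


def per_stitch_time(log: EventLog, k: int) -> float:
    """Needle-entry-to-thread-cut duration of completed stitch ``k``."""
    s = log.get(k)
    if s is None or not s.completed:
        raise ValueError(f"stitch {k} is uncompleted; its time is undefined")
    return float(s.thread_cut - s.needle_entry)


def intermediate_time(log: EventLog) -> float:
    """Mean gap between consecutive completed stitches.

    The gap of the pair (k, k+1) is needle_entry_{k+1} - thread_cut_k;
    pairs involving an uncompleted stitch are excluded.  Requires at least
    one such pair.
    """
    by_index = {s.index: s for s in log.completed}
    gaps = [
        by_index[k + 1].needle_entry - by_index[k].thread_cut
        for k in sorted(by_index)
        if k + 1 in by_index
    ]
    if not gaps:
        raise ValueError("intermediate time requires >= 2 consecutive completed stitches")
    return float(np.mean(gaps))


def total_time(log: EventLog, penalty_s: float = PENALTY_S) -> TimeSummary:
    """Raw and penalized session totals plus per-stitch and intermediate times.

    Raw total is last thread cut minus first needle entry.  When no stitch
    was completed the raw total falls back to the span from first needle
    entry to the last recorded event and the summary is flagged.  The
    penalized total adds ``penalty_s`` per required stitch not completed.
    """
    if penalty_s < 0:
        raise ValueError("penalty_s must be >= 0")
    first_entry = log.stitches[0].needle_entry
    cuts = [s.thread_cut for s in log.completed]
    if cuts:
        total_raw = max(cuts) - first_entry
        flagged = False
    else:
        total_raw = log.stitches[-1].end - first_entry
        flagged = True
    n_completed = log.n_completed
    n_uncompleted = max(log.required_stitches - n_completed, 0)
    per_stitch = {s.index: float(s.thread_cut - s.needle_entry) for s in log.completed}
    try:
        inter = intermediate_time(log)
    except ValueError:
        inter = float("nan")
    return TimeSummary(
        total_raw_s=float(total_raw),
        total_penalized_s=float(total_raw + penalty_s * n_uncompleted),
        per_stitch_s=per_stitch,
        intermediate_s=inter,
        n_completed=n_completed,
        n_uncompleted=n_uncompleted,
        penalty_s=float(penalty_s),
        raw_flagged=flagged,
    )
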