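"""Per-session record and metric extraction.

A :class:`SessionRecord` bundles everything one participant-session
produced: the instrument trace, the end-of-session stitch endpoints, the
surgical event log, the rater score sheets, ergonomic posture
observations, and metadata (group label, participant, session index).
:func:`compute_session_metrics` evaluates every analysis stage on one
record and returns the flat per-session values that feed group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometrySummary, StitchSet, summarize_geometry
from .scoring import RULAPosture, ZhangSheet, aggregate_raters, rula_grand
from .timing import EventLog, TimeSummary, total_time
from .zones import ToolTrace, ZoneConfig, ZoneSummary, summarize_zones, zone_timeline

__all__ = ["SessionRecord", "SessionMetrics", "compute_session_metrics"]

GROUPS = ("senior", "junior", "novice")


@dataclass
class SessionRecord:
    """One participant-session: data streams plus identifying metadata."""

    participant: str
    group: str
    session_index: int
    trace: ToolTrace | None = None
    stitches: StitchSet | None = None
    events: EventLog | None = None
    zhang_sheets: tuple[ZhangSheet, ...] = ()
    rula_postures: tuple[RULAPosture, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session_index < 1:
            raise ValueError("session_index must be >= 1")

    @property
    def n_completed(self) -> int:
        if self.events is not None:
            return self.events.n_completed
        if self.stitches is not None:
            return len(self.stitches.completed)
        return 0


@dataclass
class SessionMetrics:
    """Flat per-session metric values (NaN where undefined/absent)."""

    zhang: float
    rula: float
    time: TimeSummary | None
    zone: ZoneSummary | None
    geometry: GeometrySummary | None
    n_completed: int

    def scalar(self, key: str) -> float:
        """Per-session scalar for a report row key; NaN when unavailable."""
        t, z = self.time, self.zone
        if key == "zhang_total":
            return self.zhang
        if key == "rula_grand":
            return self.rula
        if key == "total_time_penalized_min":
            return t.total_penalized_s / 60.0 if t else math.nan
        if key == "total_time_raw_min":
            return t.total_raw_s / 60.0 if t else math.nan
        if key.startswith("stitch_") and key.endswith("_time_min"):
            k = int(key.split("_")[1])
            if t and k in t.per_stitch_s:
                return t.per_stitch_s[k] / 60.0
            return math.nan
        if key == "intermediate_time_min":
            return t.intermediate_s / 60.0 if t else math.nan
        if key.startswith("zone_") and key.endswith("_pct"):
            k = int(key.split("_")[1])
            return 100.0 * float(z.fraction_zone[k - 1]) if z else math.nan
        raise KeyError(key)

    def pooled(self, key: str) -> list[float]:
        """Pooled per-measurement values for a geometry report row key."""
        g = self.geometry
        if g is None:
            return []
        if key == "stitch_length_mm":
            return list(g.lengths_mm.values())
        if key == "length_ratio":
            return list(g.length_ratios.values())
        if key == "inter_stitch_distance_mm":
            return list(g.distances_mm.values())
        if key == "inter_stitch_angle_deg":
            return list(g.angles_deg.values())
        raise KeyError(key)


def compute_session_metrics(
    record: SessionRecord,
    zones: ZoneConfig | None = None,
    sampling_hz: float = 1.0,
    penalty_s: float = 300.0,
) -> SessionMetrics:
    """Run every analysis stage available for one session.

    Streams absent from the record yield NaN/None entries rather than
    errors, so partially recorded sessions still contribute the metrics
    they support.
    """
    zhang = (
        aggregate_raters(list(record.zhang_sheets))
        if record.zhang_sheets
        else math.nan
    )
    if record.rula_postures:
        grands = [rula_grand(p).grand for p in record.rula_postures]
        rula = float(np.median(grands))
    else:
        rula = math.nan
    time_summary = total_time(record.events, penalty_s) if record.events else None
    zone_summary = None
    if record.trace is not None:
        cfg = zones if zones is not None else ZoneConfig()
        zone_summary = summarize_zones(zone_timeline(record.trace, cfg, sampling_hz))
    geom = summarize_geometry(record.stitches) if record.stitches else None
    return SessionMetrics(
        zhang=zhang,
        rula=rula,
        time=time_summary,
        zone=zone_summary,
        geometry=geom,
        n_completed=record.n_completed,
    )
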