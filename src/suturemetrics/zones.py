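"""Instrument-zone attribution and occupancy summaries.

The microscope field of view is partitioned into three concentric regions by
two circles: zone 1 is the corneal surface (inner circle), zone 2 the
mounting base excluding the cornea (annulus between the circles) and zone 3
everything outside the base.  A time-stamped instrument trace is resampled
at a fixed rate (1 Hz by convention), each retained sample is attributed a
zone, and the resulting timeline is summarised as occupancy fractions,
a transition-count table and a back-and-forth count between zones 1 and 2.

Conventions
-----------
* Coordinates follow the image convention: x to the right, y down.
* Distances exactly equal to a circle radius belong to the inner zone
  (closed inner regions).
* A sample in which no instrument is visible is attributed zone 3.
* Resampling picks the nearest-in-time input sample per tick, ties broken
  toward the earlier sample; tick times become the output time stamps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZoneConfig",
    "ToolTrace",
    "ZoneTimeline",
    "ZoneSummary",
    "attribute_zone",
    "attribute_zones",
    "sample_trace",
    "zone_timeline",
    "summarize_zones",
    "detect_instrument",
]


@dataclass(frozen=True)
class ZoneConfig:
    """Two-circle partition of the microscope field.

    Parameters
    ----------
    center : (float, float)
        Common center of the cornea and mounting-base circles.
    r_cornea : float
        Radius of the cornea circle (zone 1 boundary).
    r_base : float
        Radius of the mounting-base circle (zone 2 outer boundary).
    units : str
        Coordinate units tag, ``"mm"`` or ``"px"``.
    """

    center: tuple[float, float] = (0.0, 0.0)
    r_cornea: float = 5.75
    r_base: float = 15.0
    units: str = "mm"

    def __post_init__(self) -> None:
        cx, cy = float(self.center[0]), float(self.center[1])
        if not (np.isfinite(cx) and np.isfinite(cy)):
            raise ValueError("zone center must be finite")
        if not (0.0 < self.r_cornea < self.r_base):
            raise ValueError(
                f"need 0 < r_cornea < r_base, got {self.r_cornea} and {self.r_base}"
            )

    def scaled(self, factor: float) -> "ZoneConfig":
        """Return the configuration with coordinates scaled by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return ZoneConfig(
            center=(self.center[0] * factor, self.center[1] * factor),
            r_cornea=self.r_cornea * factor,
            r_base=self.r_base * factor,
            units=self.units,
        )


@dataclass
class ToolTrace:
    """Time-stamped 2-D instrument positions with a visibility flag.

    ``x``/``y`` may be NaN where ``visible`` is False; they must be finite
    where it is True.  Time stamps must be strictly increasing.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    visible: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.visible.size == n):
            raise ValueError("trace columns must have equal length")
        if n == 0:
            raise ValueError("trace must contain at least one sample")
        if not np.all(np.isfinite(self.t)):
            raise ValueError("trace times must be finite")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("trace times must be strictly increasing")
        vis = self.visible
        if not np.all(np.isfinite(self.x[vis]) & np.isfinite(self.y[vis])):
            raise ValueError("visible samples must have finite coordinates")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "visible": self.visible.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ToolTrace":
        return cls(
            t=df["t_s"].to_numpy(float),
            x=df["x_mm"].to_numpy(float),
            y=df["y_mm"].to_numpy(float),
            visible=df["visible"].to_numpy().astype(bool),
        )


@dataclass
class ZoneTimeline:
    """Zone label per retained (resampled) trace sample."""

    t: np.ndarray
    zone: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.zone = np.asarray(self.zone, dtype=int)
        if self.t.size != self.zone.size:
            raise ValueError("timeline columns must have equal length")
        if self.t.size == 0:
            raise ValueError("timeline must be non-empty")
        if not np.all(np.isin(self.zone, (1, 2, 3))):
            raise ValueError("zones must be in {1, 2, 3}")

    def __len__(self) -> int:
        return int(self.t.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "zone": self.zone})


@dataclass
class ZoneSummary:
    """Occupancy fractions and transition structure of a zone timeline."""

    fraction_zone: np.ndarray  # shape (3,), zones 1..3
    transitions: np.ndarray  # shape (3, 3), [from-1, to-1] consecutive pairs
    n_samples: int
    back_and_forth_12: int
    duration_s: float

    @property
    def transitions_12(self) -> int:
        """Raw count of 1->2 plus 2->1 moves."""
        return int(self.transitions[0, 1] + self.transitions[1, 0])

    @property
    def back_and_forth_per_min(self) -> float:
        if self.duration_s <= 0:
            return float("nan")
        return 60.0 * self.back_and_forth_12 / self.duration_s

    def to_dict(self) -> dict:
        return {
            "fraction_zone": self.fraction_zone.tolist(),
            "pct_zone": (100.0 * self.fraction_zone).tolist(),
            "transitions": self.transitions.tolist(),
            "n_samples": int(self.n_samples),
            "transitions_12": self.transitions_12,
            "back_and_forth_12": int(self.back_and_forth_12),
            "back_and_forth_per_min": float(self.back_and_forth_per_min),
            "duration_s": float(self.duration_s),
        }


def attribute_zone(point, zones: ZoneConfig, visible: bool = True) -> int:
    """Attribute one sample to a zone.

    ``point`` is an ``(x, y)`` pair, or ``None`` for an invisible sample.
    Invisible samples are attributed zone 3.  Boundary points (distance
    exactly equal to a radius) belong to the inner zone.
    """
    if point is None or not visible:
        return 3
    x, y = float(point[0]), float(point[1])
    if not (np.isfinite(x) and np.isfinite(y)):
        raise ValueError("visible sample has non-finite coordinates")
    d = float(np.hypot(x - zones.center[0], y - zones.center[1]))
    if d <= zones.r_cornea:
        return 1
    if d <= zones.r_base:
        return 2
    return 3


def attribute_zones(trace: ToolTrace, zones: ZoneConfig) -> np.ndarray:
    """Vectorised zone attribution over a whole trace."""
    d = np.hypot(trace.x - zones.center[0], trace.y - zones.center[1])
    out = np.full(len(trace), 3, dtype=int)
    vis = trace.visible
    out[vis & (d <= zones.r_base)] = 2
    out[vis & (d <= zones.r_cornea)] = 1
    return out


def sample_trace(trace: ToolTrace, rate_hz: float) -> ToolTrace:
    """Resample a trace at ``rate_hz`` by nearest-in-time selection.

    Ticks run from the first trace time to the last, inclusive of both
    endpoints; the output carries the tick times.  Ties between two equally
    near input samples resolve toward the earlier sample.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    t0, t1 = trace.t[0], trace.t[-1]
    n_ticks = int(np.floor((t1 - t0) * rate_hz + 1e-9)) + 1
    ticks = t0 + np.arange(n_ticks) / rate_hz
    idx = _nearest_indices(trace.t, ticks)
    return ToolTrace(
        t=ticks,
        x=trace.x[idx],
        y=trace.y[idx],
        visible=trace.visible[idx],
    )


def _nearest_indices(times: np.ndarray, ticks: np.ndarray) -> np.ndarray:
    """Index of the nearest time per tick, ties toward the earlier sample."""
    right = np.searchsorted(times, ticks, side="left")
    right = np.clip(right, 0, times.size - 1)
    left = np.clip(right - 1, 0, times.size - 1)
    d_left = np.abs(ticks - times[left])
    d_right = np.abs(times[right] - ticks)
    return np.where(d_left <= d_right, left, right)


def zone_timeline(trace: ToolTrace, zones: ZoneConfig, rate_hz: float = 1.0) -> ZoneTimeline:
    """Resample the trace and attribute a zone per retained sample."""
    sampled = sample_trace(trace, rate_hz)
    return ZoneTimeline(t=sampled.t, zone=attribute_zones(sampled, zones))


def summarize_zones(timeline: ZoneTimeline) -> ZoneSummary:
    """Occupancy fractions, transition table and 1<->2 back-and-forth count.

    ``back_and_forth_12`` counts direction reversals in the timeline
    restricted to zones 1 and 2 (consecutive duplicates collapsed): the
    alternating subsequence 1,2,1,2,1 contains four moves and three
    reversals.
    """
    z = timeline.zone
    n = z.size
    fractions = np.array([np.mean(z == k) for k in (1, 2, 3)])
    trans = np.zeros((3, 3), dtype=int)
    if n > 1:
        np.add.at(trans, (z[:-1] - 1, z[1:] - 1), 1)
    sub = z[z != 3]
    collapsed = sub[np.concatenate(([True], np.diff(sub) != 0))] if sub.size else sub
    back_and_forth = max(int(collapsed.size) - 2, 0)
    duration = float(timeline.t[-1] - timeline.t[0])
    return ZoneSummary(
        fraction_zone=fractions,
        transitions=trans,
        n_samples=int(n),
        back_and_forth_12=back_and_forth,
        duration_s=duration,
    )


def detect_instrument(
    frame: np.ndarray,
    threshold: float | None = None,
    min_blob_fraction: float = 0.4,
):
    """Locate the instrument blob in a grayscale frame.

    Returns the intensity-weighted centroid ``(x, y)`` in pixel coordinates
    of the largest connected component above threshold, or ``None`` when no
    pixel clears it (the instrument is out of the field of view).

    The default threshold is Otsu's, floored at ``min_blob_fraction`` of the
    dtype's full scale so that the faint zone-circle annotations drawn into
    synthetic frames are never mistaken for an instrument.
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D image")
    full_scale = 255.0 if np.issubdtype(frame.dtype, np.integer) else 1.0
    img = frame.astype(float)
    if threshold is None:
        thr = min_blob_fraction * full_scale
        if np.unique(frame).size > 1:
            thr = max(float(threshold_otsu(img)), thr)
    else:
        thr = float(threshold)
    mask = img >= thr
    if not mask.any():
        return None
    labels = label(mask)
    best = max(regionprops(labels, intensity_image=img), key=lambda r: r.area)
    cy, cx = best.centroid_weighted
    return (float(cx), float(cy))
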