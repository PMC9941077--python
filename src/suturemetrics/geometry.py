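"""Stitch-geometry criteria from end-of-session endpoint coordinates.

Four criteria characterise the final suture pattern of a session: the
length of each completed stitch, each stitch's length ratio relative to the
first stitch, the distance between successive stitches (midpoint to
midpoint) and the acute angle between successive stitches.  Only completed
stitches enter the geometry — an unfinished stitch has no final endpoints
in the end-of-session photograph.

A well-formed corneal stitch is conventionally 2 mm long with ~1 mm
spacing between neighbours; :func:`quality_deviation` measures departures
from those references.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Stitch",
    "StitchSet",
    "GeometrySummary",
    "calibrate",
    "stitch_length",
    "length_ratios",
    "inter_stitch_distance",
    "inter_stitch_angle",
    "quality_deviation",
    "summarize_geometry",
]

REF_LENGTH_MM = 2.0
REF_SPACING_MM = 1.0


@dataclass(frozen=True)
class Stitch:
    """One interrupted suture: entry and exit points plus completion flag."""

    index: int
    entry: tuple[float, float]
    exit: tuple[float, float]
    completed: bool = True

    def __post_init__(self) -> None:
        e = np.asarray(self.entry, dtype=float)
        x = np.asarray(self.exit, dtype=float)
        if e.shape != (2,) or x.shape != (2,):
            raise ValueError("stitch endpoints must be 2-D points")
        if self.completed:
            if not (np.all(np.isfinite(e)) and np.all(np.isfinite(x))):
                raise ValueError("completed stitch must have finite endpoints")
            if np.all(e == x):
                raise ValueError("completed stitch must have distinct endpoints")

    @property
    def midpoint(self) -> np.ndarray:
        return (np.asarray(self.entry, float) + np.asarray(self.exit, float)) / 2.0

    @property
    def direction(self) -> np.ndarray:
        """Unit direction vector entry -> exit."""
        v = np.asarray(self.exit, float) - np.asarray(self.entry, float)
        norm = float(np.linalg.norm(v))
        if norm == 0:
            raise ValueError("degenerate (zero-length) stitch has no direction")
        return v / norm


@dataclass(frozen=True)
class StitchSet:
    """Ordered stitches with a units tag and optional pixel calibration."""

    stitches: tuple[Stitch, ...]
    units: str = "mm"
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stitches", tuple(self.stitches))
        idx = [s.index for s in self.stitches]
        if len(set(idx)) != len(idx) or idx != sorted(idx):
            raise ValueError("stitch indices must be unique and ascending")
        if self.units not in ("mm", "px"):
            raise ValueError("units must be 'mm' or 'px'")

    @property
    def completed(self) -> tuple[Stitch, ...]:
        return tuple(s for s in self.stitches if s.completed)

    def get(self, index: int) -> Stitch | None:
        for s in self.stitches:
            if s.index == index:
                return s
        return None


@dataclass
class GeometrySummary:
    """Aggregated geometry criteria over the completed stitches of a set.

    ``lengths_mm`` maps stitch index to length; ``length_ratios`` maps each
    completed index k >= 2 to length_k / length_1 (empty, with
    ``ratio_defined`` False, when stitch 1 is missing or uncompleted);
    ``distances_mm`` and ``angles_deg`` map successive completed index pairs
    (k, k+1) to midpoint distance and acute inter-stitch angle.
    """

    lengths_mm: dict[int, float]
    length_ratios: dict[int, float]
    distances_mm: dict[tuple[int, int], float]
    angles_deg: dict[tuple[int, int], float]
    n_completed: int
    ratio_defined: bool

    def to_dict(self) -> dict:
        return {
            "lengths_mm": {str(k): v for k, v in self.lengths_mm.items()},
            "length_ratios": {str(k): v for k, v in self.length_ratios.items()},
            "distances_mm": {f"{a}-{b}": v for (a, b), v in self.distances_mm.items()},
            "angles_deg": {f"{a}-{b}": v for (a, b), v in self.angles_deg.items()},
            "n_completed": self.n_completed,
            "ratio_defined": self.ratio_defined,
        }


def calibrate(stitches: StitchSet) -> StitchSet:
    """Convert a stitch set to millimetres; identity on mm input."""
    if stitches.units == "mm":
        return stitches
    if stitches.mm_per_px is None or stitches.mm_per_px <= 0:
        raise ValueError("pixel input requires mm_per_px > 0")
    s = stitches.mm_per_px
    scaled = tuple(
        replace(
            st,
            entry=(st.entry[0] * s, st.entry[1] * s),
            exit=(st.exit[0] * s, st.exit[1] * s),
        )
        for st in stitches.stitches
    )
    return StitchSet(stitches=scaled, units="mm", mm_per_px=stitches.mm_per_px)


def stitch_length(s: Stitch) -> float:
    """Euclidean entry-exit distance of a completed stitch."""
    if not s.completed:
        raise ValueError(f"stitch {s.index} is uncompleted and has no geometry")
    return float(
        np.linalg.norm(np.asarray(s.exit, float) - np.asarray(s.entry, float))
    )


def length_ratios(stitches: StitchSet) -> dict[int, float]:
    """Length of each completed stitch k >= 2 relative to stitch 1."""
    first = stitches.get(1)
    if first is None or not first.completed:
        raise ValueError("length ratios undefined: stitch 1 missing or uncompleted")
    l1 = stitch_length(first)
    return {
        s.index: stitch_length(s) / l1
        for s in stitches.completed
        if s.index >= 2
    }


def inter_stitch_distance(a: Stitch, b: Stitch) -> float:
    """Euclidean distance between the midpoints of two successive stitches."""
    if not (a.completed and b.completed):
        raise ValueError("inter-stitch distance requires completed stitches")
    if abs(a.index - b.index) != 1:
        raise ValueError("inter-stitch distance is defined for consecutive indices")
    return float(np.linalg.norm(a.midpoint - b.midpoint))


def inter_stitch_angle(a: Stitch, b: Stitch) -> float:
    """Acute angle in degrees between the undirected stitch directions."""
    if not (a.completed and b.completed):
        raise ValueError("inter-stitch angle requires completed stitches")
    if abs(a.index - b.index) != 1:
        raise ValueError("inter-stitch angle is defined for consecutive indices")
    cos = abs(float(np.dot(a.direction, b.direction)))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def quality_deviation(
    stitches: StitchSet,
    ref_length_mm: float = REF_LENGTH_MM,
    ref_spacing_mm: float = REF_SPACING_MM,
) -> dict:
    """Absolute deviations from the reference stitch length and spacing."""
    summary = summarize_geometry(stitches)
    if summary.n_completed == 0:
        raise ValueError("quality deviation requires at least one completed stitch")
    length_dev = {
        k: abs(v - ref_length_mm) for k, v in summary.lengths_mm.items()
    }
    spacing_dev = {
        pair: abs(v - ref_spacing_mm) for pair, v in summary.distances_mm.items()
    }
    return {
        "length_deviation_mm": length_dev,
        "spacing_deviation_mm": spacing_dev,
        "mean_length_deviation_mm": float(np.mean(list(length_dev.values()))),
        "mean_spacing_deviation_mm": (
            float(np.mean(list(spacing_dev.values()))) if spacing_dev else float("nan")
        ),
    }


def summarize_geometry(stitches: StitchSet) -> GeometrySummary:
    """All four geometry criteria over the completed stitches of a set."""
    stitches = calibrate(stitches)
    completed = stitches.completed
    lengths = {s.index: stitch_length(s) for s in completed}
    first = stitches.get(1)
    ratio_defined = first is not None and first.completed
    ratios = length_ratios(stitches) if ratio_defined else {}
    by_index = {s.index: s for s in completed}
    distances: dict[tuple[int, int], float] = {}
    angles: dict[tuple[int, int], float] = {}
    for k in sorted(by_index):
        if k + 1 in by_index:
            a, b = by_index[k], by_index[k + 1]
            distances[(k, k + 1)] = inter_stitch_distance(a, b)
            angles[(k, k + 1)] = inter_stitch_angle(a, b)
    return GeometrySummary(
        lengths_mm=lengths,
        length_ratios=ratios,
        distances_mm=distances,
        angles_deg=angles,
        n_completed=len(completed),
        ratio_defined=bool(ratio_defined),
    )
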