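"""Rubric and ergonomic scoring.

Two observer-based instruments are aggregated here:

* a 12-item suturing-quality rubric (a modification of the 15-item Zhang
  corneal wound-closure scale), each item rated 1-5, giving a 12-60 total;
  per-session scores average the totals of the available raters;
* the RULA (Rapid Upper Limb Assessment) ergonomic instrument, which maps
  a seated posture observation through three published lookup tables to a
  grand score of 1-7 (higher = greater musculoskeletal load).

The rubric item list and the RULA tables ship as editable data files; the
RULA fixture carries a checksum so silent edits are surfaced as a warning.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Rubric",
    "ZhangSheet",
    "RULAPosture",
    "RULAResult",
    "RULATables",
    "load_rubric",
    "load_rula_tables",
    "zhang_total",
    "aggregate_raters",
    "rula_grand",
]

_RULA_SHA256 = "33ce35ee66bd9fb7bf919d80257b095156bb85a49d437470a1180bfe5bacabc6"

# Published field ranges of a RULA posture observation.
_POSTURE_RANGES = {
    "upper_arm": (1, 6),
    "lower_arm": (1, 3),
    "wrist": (1, 4),
    "wrist_twist": (1, 2),
    "neck": (1, 6),
    "trunk": (1, 6),
    "legs": (1, 2),
    "muscle_use_a": (0, 1),
    "muscle_use_b": (0, 1),
    "force_a": (0, 3),
    "force_b": (0, 3),
}


@dataclass(frozen=True)
class Rubric:
    """A labelled rating scale: item names plus score bounds per item."""

    name: str
    items: tuple[str, ...]
    scale_min: int = 1
    scale_max: int = 5

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("rubric must define at least one item")
        if self.scale_min >= self.scale_max:
            raise ValueError("rubric scale must satisfy min < max")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def max_total(self) -> int:
        return self.n_items * self.scale_max

    @property
    def min_total(self) -> int:
        return self.n_items * self.scale_min


_rubric_cache: "Rubric | None" = None


def load_rubric(path: str | Path | None = None) -> Rubric:
    """Load a rubric definition; defaults to the shipped 12-item scale."""
    global _rubric_cache
    if path is None:
        if _rubric_cache is not None:
            return _rubric_cache
        text = resources.files("suturemetrics.data").joinpath("rubric.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rubric = Rubric(
        name=str(raw["name"]),
        items=tuple(str(i) for i in raw["items"]),
        scale_min=int(raw["scale"]["min"]),
        scale_max=int(raw["scale"]["max"]),
    )
    if path is None:
        _rubric_cache = rubric
    return rubric


@dataclass(frozen=True)
class ZhangSheet:
    """One rater's item scores on a rubric."""

    rater: str
    item_scores: tuple[int, ...]
    rubric: Rubric | None = None  # defaults to the shipped 12-item rubric

    def __post_init__(self) -> None:
        rubric = self.rubric if self.rubric is not None else load_rubric()
        object.__setattr__(self, "rubric", rubric)
        scores = tuple(int(s) for s in self.item_scores)
        object.__setattr__(self, "item_scores", scores)
        if len(scores) != rubric.n_items:
            raise ValueError(
                f"expected {rubric.n_items} item scores, got {len(scores)}"
            )
        for i, s in enumerate(scores, start=1):
            if not (rubric.scale_min <= s <= rubric.scale_max):
                raise ValueError(
                    f"item {i} score {s} outside "
                    f"[{rubric.scale_min}, {rubric.scale_max}]"
                )


def zhang_total(sheet: ZhangSheet) -> int:
    """Sum of the sheet's item scores (12-60 on the default rubric)."""
    return int(sum(sheet.item_scores))


def aggregate_raters(sheets: list[ZhangSheet]) -> float:
    """Unrounded arithmetic mean of per-rater totals."""
    if not sheets:
        raise ValueError("need at least one rater sheet")
    return float(np.mean([zhang_total(s) for s in sheets]))


@dataclass(frozen=True)
class RULAPosture:
    """One RULA posture observation (arm/wrist group A, neck/trunk group B)."""

    upper_arm: int
    lower_arm: int
    wrist: int
    wrist_twist: int
    neck: int
    trunk: int
    legs: int
    muscle_use_a: int = 0
    force_a: int = 0
    muscle_use_b: int = 0
    force_b: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _POSTURE_RANGES.items():
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or not (lo <= v <= hi):
                raise ValueError(f"RULA field {name}={v!r} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class RULAResult:
    score_a: int
    score_b: int
    score_c: int
    score_d: int
    grand: int


class RULATables:
    """The three published RULA lookup tables as numpy arrays."""

    def __init__(self, table_a, table_b, table_c):
        self.a = np.asarray(table_a, dtype=int)  # (6, 3, 4, 2)
        self.b = np.asarray(table_b, dtype=int)  # (6, 6, 2)
        self.c = np.asarray(table_c, dtype=int)  # (8, 7)
        if self.a.shape != (6, 3, 4, 2) or self.b.shape != (6, 6, 2) or self.c.shape != (8, 7):
            raise ValueError("RULA tables have unexpected shapes")


_tables_cache: RULATables | None = None


def load_rula_tables(path: str | Path | None = None) -> RULATables:
    """Load the RULA tables fixture, verifying its checksum when default."""
    global _tables_cache
    if path is None and _tables_cache is not None:
        return _tables_cache
    if path is None:
        text = (
            resources.files("suturemetrics.data")
            .joinpath("rula_tables.json")
            .read_text()
        )
        digest = hashlib.sha256(text.encode()).hexdigest()
        if digest != _RULA_SHA256:
            warnings.warn(
                "rula_tables.json does not match its recorded checksum; "
                "the fixture appears to have been edited",
                stacklevel=2,
            )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    tables = RULATables(raw["table_a"], raw["table_b"], raw["table_c"])
    if path is None:
        _tables_cache = tables
    return tables


def rula_grand(p: RULAPosture, tables: RULATables | None = None) -> RULAResult:
    """Grand RULA score of one posture observation.

    Score A comes from Table A (upper arm, lower arm, wrist, wrist twist);
    score B from Table B (neck, trunk, legs).  Muscle-use and force
    adjustments give scores C and D, which index Table C — saturated at its
    bounds — for the grand score in 1-7.
    """
    if tables is None:
        tables = load_rula_tables()
    score_a = int(
        tables.a[p.upper_arm - 1, p.lower_arm - 1, p.wrist - 1, p.wrist_twist - 1]
    )
    score_b = int(tables.b[p.neck - 1, p.trunk - 1, p.legs - 1])
    score_c = score_a + p.muscle_use_a + p.force_a
    score_d = score_b + p.muscle_use_b + p.force_b
    grand = int(tables.c[min(score_c, 8) - 1, min(score_d, 7) - 1])
    return RULAResult(
        score_a=score_a,
        score_b=score_b,
        score_c=int(score_c),
        score_d=int(score_d),
        grand=grand,
    )
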