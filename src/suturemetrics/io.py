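"""Session directory formats, pipeline orchestration and plot export.

A session directory holds plain-text streams:

* ``trace.csv`` — ``t_s,x_mm,y_mm,visible`` (coordinates empty when the
  instrument is invisible);
* ``stitches.csv`` — ``stitch_index,entry_x_mm,entry_y_mm,exit_x_mm,
  exit_y_mm,completed``;
* ``events.csv`` — ``stitch_index,needle_entry_s,thread_cut_s`` (thread
  cut empty for uncompleted stitches);
* ``zhang.csv`` — ``rater,item_1..item_12``;
* ``rula.csv`` — one posture observation per row;
* ``meta.yaml`` — group, participant, session index, scenario, schema
  version.

``meta.yaml`` is required; every data stream is optional and flagged when
absent.  Writers are deterministic (sorted keys, locale-independent
decimal points), so write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .geometry import Stitch, StitchSet
from .scoring import RULAPosture, ZhangSheet, load_rubric
from .session import SessionRecord, compute_session_metrics
from .stats import ComparisonReport, build_report
from .timing import EventLog
from .zones import ToolTrace, ZoneConfig, ZoneTimeline

__all__ = [
    "SCHEMA_VERSION",
    "PipelineConfig",
    "write_session",
    "read_session",
    "write_manifest",
    "read_manifest",
    "run_pipeline",
    "export_timeline_plot",
]

SCHEMA_VERSION = 1

_POSTURE_COLUMNS = (
    "upper_arm",
    "lower_arm",
    "wrist",
    "wrist_twist",
    "neck",
    "trunk",
    "legs",
    "muscle_use_a",
    "force_a",
    "muscle_use_b",
    "force_b",
)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the study's constants
    (1 Hz sampling, 300 s penalty, 3 required stitches, 12-item rubric)."""

    zone_config: ZoneConfig = field(default_factory=ZoneConfig)
    mm_per_px: float | None = None
    sampling_hz: float = 1.0
    penalty_s: float = 300.0
    required_stitches: int = 3
    rubric_path: str | None = None
    rula_tables_path: str | None = None
    policy: str = "paper"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")
        if self.penalty_s < 0:
            raise ValueError("penalty_s must be >= 0")
        if self.required_stitches < 1:
            raise ValueError("required_stitches must be >= 1")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def write_session(record: SessionRecord, directory: str | Path) -> Path:
    """Serialize a session record into a directory of plain-text files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if record.trace is not None:
        _write_csv(record.trace.to_dataframe(), directory / "trace.csv")
    if record.stitches is not None:
        rows = [
            {
                "stitch_index": s.index,
                "entry_x_mm": s.entry[0],
                "entry_y_mm": s.entry[1],
                "exit_x_mm": s.exit[0],
                "exit_y_mm": s.exit[1],
                "completed": int(s.completed),
            }
            for s in record.stitches.stitches
        ]
        _write_csv(pd.DataFrame(rows), directory / "stitches.csv")
    if record.events is not None:
        _write_csv(record.events.to_dataframe(), directory / "events.csv")
    if record.zhang_sheets:
        rows = []
        for sheet in record.zhang_sheets:
            row = {"rater": sheet.rater}
            row.update(
                {f"item_{i + 1}": s for i, s in enumerate(sheet.item_scores)}
            )
            rows.append(row)
        _write_csv(pd.DataFrame(rows), directory / "zhang.csv")
    if record.rula_postures:
        rows = [
            {c: getattr(p, c) for c in _POSTURE_COLUMNS}
            for p in record.rula_postures
        ]
        _write_csv(pd.DataFrame(rows), directory / "rula.csv")
    meta = dict(record.meta)
    meta.pop("missing_streams", None)  # read-time flag, not persisted
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta["group"] = record.group
    meta["participant"] = record.participant
    meta["session"] = int(record.session_index)
    (directory / "meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True, default_flow_style=False)
    )
    return directory


def read_session(directory: str | Path) -> SessionRecord:
    """Load a session directory; missing optional streams are flagged in
    ``record.meta['missing_streams']`` rather than fatal."""
    directory = Path(directory)
    meta_path = directory / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"{meta_path}: session metadata is required")
    try:
        meta = yaml.safe_load(meta_path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{meta_path}: malformed YAML ({exc})") from exc
    if not isinstance(meta, dict):
        raise ValueError(f"{meta_path}: expected a mapping")
    for key in ("group", "participant", "session"):
        if key not in meta:
            raise ValueError(f"{meta_path}: missing required field {key!r}")

    missing: list[str] = []
    trace = stitches = events = None
    zhang_sheets: tuple[ZhangSheet, ...] = ()
    rula_postures: tuple[RULAPosture, ...] = ()

    path = directory / "trace.csv"
    if path.exists():
        trace = ToolTrace.from_dataframe(_read_csv(path))
    else:
        missing.append("trace")

    path = directory / "stitches.csv"
    if path.exists():
        df = _read_csv(path)
        stitch_objs = tuple(
            Stitch(
                index=int(r.stitch_index),
                entry=(float(r.entry_x_mm), float(r.entry_y_mm)),
                exit=(float(r.exit_x_mm), float(r.exit_y_mm)),
                completed=bool(int(r.completed)),
            )
            for r in df.itertuples(index=False)
        )
        stitches = StitchSet(stitches=stitch_objs, units="mm")
    else:
        missing.append("stitches")

    path = directory / "events.csv"
    if path.exists():
        required = int(
            meta.get("scenario", {}).get("n_stitches_required", 3)
            if isinstance(meta.get("scenario"), dict)
            else 3
        )
        events = EventLog.from_dataframe(_read_csv(path), required_stitches=required)
    else:
        missing.append("events")

    path = directory / "zhang.csv"
    if path.exists():
        df = _read_csv(path)
        rubric = load_rubric()
        item_cols = [c for c in df.columns if c.startswith("item_")]
        zhang_sheets = tuple(
            ZhangSheet(
                rater=str(row["rater"]),
                item_scores=tuple(int(row[c]) for c in item_cols),
                rubric=rubric,
            )
            for _, row in df.iterrows()
        )
    else:
        missing.append("zhang")

    path = directory / "rula.csv"
    if path.exists():
        df = _read_csv(path)
        rula_postures = tuple(
            RULAPosture(**{c: int(row[c]) for c in _POSTURE_COLUMNS})
            for _, row in df.iterrows()
        )
    else:
        missing.append("rula")

    if not (trace or stitches or events or zhang_sheets or rula_postures):
        raise ValueError(f"{directory}: no data stream present")

    meta = dict(meta)
    meta["missing_streams"] = missing
    return SessionRecord(
        participant=str(meta["participant"]),
        group=str(meta["group"]),
        session_index=int(meta["session"]),
        trace=trace,
        stitches=stitches,
        events=events,
        zhang_sheets=zhang_sheets,
        rula_postures=rula_postures,
        meta=meta,
    )


def _read_csv(path: Path) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write -> read -> write byte-identical
        return pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc


def write_manifest(session_dirs: list[str | Path], path: str | Path) -> Path:
    """Write a cohort manifest: a YAML list of session directory entries."""
    path = Path(path)
    entries = [{"dir": str(Path(d))} for d in session_dirs]
    path.write_text(
        yaml.safe_dump({"schema_version": SCHEMA_VERSION, "sessions": entries},
                       sort_keys=True)
    )
    return path


def read_manifest(path: str | Path) -> list[Path]:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "sessions" not in raw:
        raise ValueError(f"{path}: manifest must contain a 'sessions' list")
    base = path.parent
    dirs = []
    for entry in raw["sessions"]:
        d = Path(entry["dir"]) if isinstance(entry, dict) else Path(entry)
        dirs.append(d if d.is_absolute() else base / d)
    return dirs


def run_pipeline(
    manifest: str | Path | list[SessionRecord],
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ComparisonReport, dict[str, str]]:
    """Run every analysis stage over a cohort and write all artifacts.

    ``manifest`` may be a manifest path or an in-memory list of records.
    Per-session failures are collected in the returned error mapping and
    the pipeline continues with the remaining sessions.
    """
    if config is None:
        config = PipelineConfig()
    errors: dict[str, str] = {}
    records: list[SessionRecord] = []
    if isinstance(manifest, (str, Path)):
        for d in read_manifest(manifest):
            try:
                records.append(read_session(d))
            except Exception as exc:  # noqa: BLE001 - per-session error ledger
                errors[str(d)] = f"{type(exc).__name__}: {exc}"
    else:
        records = list(manifest)

    kept: list[SessionRecord] = []
    for rec in records:
        session_id = f"{rec.group}/{rec.participant}/s{rec.session_index}"
        try:
            m = compute_session_metrics(
                rec,
                zones=config.zone_config,
                sampling_hz=config.sampling_hz,
                penalty_s=config.penalty_s,
            )
            kept.append(rec)
            if out_dir is not None:
                session_out = Path(out_dir) / rec.group / rec.participant / (
                    f"session_{rec.session_index}"
                )
                session_out.mkdir(parents=True, exist_ok=True)
                if m.zone is not None:
                    _write_json(m.zone.to_dict(), session_out / "zone_summary.json")
                if rec.trace is not None:
                    from .zones import zone_timeline as _ztl

                    tl = _ztl(rec.trace, config.zone_config, config.sampling_hz)
                    _write_csv(tl.to_dataframe(), session_out / "timeline.csv")
                if m.geometry is not None:
                    _write_json(m.geometry.to_dict(), session_out / "geometry.json")
                if m.time is not None:
                    _write_json(m.time.to_dict(), session_out / "time_summary.json")
                scores = {
                    "zhang": None if math.isnan(m.zhang) else m.zhang,
                    "rula": None if math.isnan(m.rula) else m.rula,
                }
                _write_json(scores, session_out / "scores.json")
        except Exception as exc:  # noqa: BLE001
            errors[session_id] = f"{type(exc).__name__}: {exc}"

    report = build_report(
        kept,
        policy=config.policy,
        zones=config.zone_config,
        sampling_hz=config.sampling_hz,
        penalty_s=config.penalty_s,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_dataframe().to_csv(out / "report.csv", index=False,
                                     lineterminator="\n")
        (out / "report.md").write_text(report.to_markdown())
        _write_json(report.to_dict(), out / "report.json")
        if errors:
            _write_json(errors, out / "errors.json")
    return report, errors


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def export_timeline_plot(timeline: ZoneTimeline, out: str | Path) -> Path:
    """Step plot of zone versus time, with the underlying CSV alongside."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 2.4))
    ax.step(timeline.t, timeline.zone, where="post", lw=1.0)
    ax.set_yticks([1, 2, 3])
    ax.set_ylim(0.5, 3.5)
    ax.invert_yaxis()  # zone 1 (cornea) on top, as read in practice
    ax.set_xlabel("time (s)")
    ax.set_ylabel("zone")
    fig.tight_layout()
    fig.savefig(out, dpi=100)
    plt.close(fig)
    _write_csv(timeline.to_dataframe(), out.with_suffix(".csv"))
    return out
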