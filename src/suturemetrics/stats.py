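"""Cohort-level nonparametric comparison of session metrics.

Sessions are first filtered by a selection policy (the study design pools
all three sessions for novices, who gained no outside practice, but keeps
only the first session for juniors and seniors, who sutured between
sessions), then every metric row is compared across the three groups with
a Kruskal-Wallis test; pairwise Mann-Whitney tests are available for
two-group follow-ups.  Rows report per-group median and IQR in the units
the study tabulates (minutes, percent, mm, degrees, points).

Conventions: quartiles use linear interpolation; no multiple-testing
correction is applied across rows; significance is flagged at p < 0.05.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import GROUPS, SessionRecord, compute_session_metrics
from .zones import ZoneConfig

__all__ = [
    "select_sessions",
    "median_iqr",
    "kruskal_wallis",
    "mann_whitney",
    "count_achievement",
    "build_report",
    "ComparisonReport",
    "ReportRow",
    "METRIC_ROWS",
]

ALPHA = 0.05

# (key, label, unit, pooling) — pooling "session" takes one scalar per
# session, "measurement" pools individual stitch/pair measurements across
# sessions.  Order matches the study's results table.
METRIC_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("zhang_total", "Zhang score (/60)", "points", "session"),
    ("rula_grand", "RULA score", "score", "session"),
    ("total_time_penalized_min", "Total time with penalties", "min", "session"),
    ("total_time_raw_min", "Total time without penalties", "min", "session"),
    ("stitch_1_time_min", "Stitch 1", "min", "session"),
    ("stitch_2_time_min", "Stitch 2", "min", "session"),
    ("stitch_3_time_min", "Stitch 3", "min", "session"),
    ("intermediate_time_min", "Intermediate time", "min", "session"),
    ("zone_1_pct", "Zone 1", "% time", "session"),
    ("zone_2_pct", "Zone 2", "% time", "session"),
    ("zone_3_pct", "Zone 3", "% time", "session"),
    ("stitch_length_mm", "Length of each stitch", "mm", "measurement"),
    ("length_ratio", "Length ratio with respect to stitch 1", "-", "measurement"),
    ("inter_stitch_distance_mm", "Distance between successive stitches", "mm", "measurement"),
    ("inter_stitch_angle_deg", "Angle between successive stitches", "deg", "measurement"),
)


def select_sessions(
    cohort: list[SessionRecord], policy: str = "paper"
) -> list[SessionRecord]:
    """Apply a session-selection policy to a labeled cohort.

    ``"paper"``: all sessions for the novice group, session 1 only for
    junior and senior.  ``"first"``: session 1 only for everyone.
    ``"all"``: identity.
    """
    if policy == "all":
        return list(cohort)
    if policy == "first":
        return [r for r in cohort if r.session_index == 1]
    if policy == "paper":
        return [
            r
            for r in cohort
            if r.group == "novice" or r.session_index == 1
        ]
    raise ValueError(f"unknown session policy {policy!r}")


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) by the linear-interpolation quartile convention."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def _kw_h_from_ranks(rank_sums: np.ndarray, sizes: np.ndarray, n: int) -> float:
    return 12.0 / (n * (n + 1)) * float(np.sum(rank_sums**2 / sizes)) - 3.0 * (n + 1)


def _kw_exact(groups: list[np.ndarray]) -> tuple[float, float]:
    """Exact permutation null of the Kruskal-Wallis statistic.

    Valid only for all-distinct pooled values; enumerates every assignment
    of the pooled ranks to groups of the observed sizes.
    """
    pooled = np.concatenate(groups)
    n = pooled.size
    sizes = np.array([g.size for g in groups])
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)
    rank_sums = np.array(
        [ranks[s - g: s].sum() for g, s in zip(sizes, bounds)]
    )
    h_obs = _kw_h_from_ranks(rank_sums, sizes, n)

    all_ranks = np.arange(1, n + 1)

    # Enumerate every assignment of ranks to groups of the observed sizes.
    count = 0
    ge = 0
    stack_sizes = tuple(int(s) for s in sizes)

    def recurse(remaining: tuple, sizes_left: tuple, sums: tuple):
        nonlocal count, ge
        if len(sizes_left) == 1:
            all_sums = sums + (sum(remaining),)
            h = _kw_h_from_ranks(np.array(all_sums, dtype=float), sizes, n)
            count += 1
            if h >= h_obs - 1e-12:
                ge += 1
            return
        first = sizes_left[0]
        for combo in itertools.combinations(remaining, first):
            rest = tuple(r for r in remaining if r not in combo)
            recurse(rest, sizes_left[1:], sums + (sum(combo),))

    recurse(tuple(all_ranks), stack_sizes, ())
    return float(h_obs), ge / count


def kruskal_wallis(
    groups: list, method: str = "auto"
) -> tuple[float, float]:
    """Kruskal-Wallis H and p across two or more groups.

    ``method="asymptotic"`` uses the tie-corrected chi-square approximation
    (k-1 degrees of freedom).  ``"exact"`` enumerates the permutation null
    (all-distinct values only).  ``"auto"`` picks exact for total n <= 10
    without ties, asymptotic otherwise.  All values identical across all
    groups returns (0, 1) by convention.
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    n = pooled.size
    distinct = np.unique(pooled).size == n
    if method == "auto":
        method = "exact" if (n <= 10 and distinct) else "asymptotic"
    if method == "exact":
        if not distinct:
            raise ValueError("exact Kruskal-Wallis requires all-distinct values")
        return _kw_exact(arrays)
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (of the first sample) and p.

    Exact null when both samples are small (max n <= 20) and tie-free;
    normal approximation with tie and continuity correction otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 20) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def count_achievement(
    cohort: list[SessionRecord], required: int = 3
) -> dict[str, dict[int, int]]:
    """Per-group counts of sessions with 0..required completed stitches."""
    counts: dict[str, dict[int, int]] = {}
    for r in cohort:
        g = counts.setdefault(r.group, {k: 0 for k in range(required + 1)})
        g[min(r.n_completed, required)] += 1
    return counts


@dataclass
class ReportRow:
    """One metric row of the comparison report."""

    key: str
    label: str
    unit: str
    unit_of_analysis: str  # "session" or "measurement"
    per_group: dict[str, dict]  # group -> {n, median, q1, q3}
    h: float
    p: float
    significant: bool
    flag: str = ""


@dataclass
class ComparisonReport:
    """Table-style comparison of group performance, one row per metric."""

    rows: list[ReportRow]
    achievement: dict[str, dict[int, int]]
    n_sessions: dict[str, int]
    policy: str
    alpha: float = ALPHA

    def row(self, key: str) -> ReportRow:
        for r in self.rows:
            if r.key == key:
                return r
        raise KeyError(key)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            rec = {
                "metric": r.label,
                "key": r.key,
                "unit": r.unit,
                "unit_of_analysis": r.unit_of_analysis,
                "H": r.h,
                "p": r.p,
                "significant": r.significant,
                "flag": r.flag,
            }
            for g in GROUPS:
                pg = r.per_group.get(g)
                if pg is None:
                    rec[f"{g}_n"] = 0
                    rec[f"{g}_median"] = np.nan
                    rec[f"{g}_q1"] = np.nan
                    rec[f"{g}_q3"] = np.nan
                else:
                    rec[f"{g}_n"] = pg["n"]
                    rec[f"{g}_median"] = pg["median"]
                    rec[f"{g}_q1"] = pg["q1"]
                    rec[f"{g}_q3"] = pg["q3"]
            recs.append(rec)
        return pd.DataFrame(recs)

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "alpha": self.alpha,
            "n_sessions": self.n_sessions,
            "achievement": {
                g: {str(k): v for k, v in c.items()}
                for g, c in self.achievement.items()
            },
            "rows": [
                {
                    "key": r.key,
                    "label": r.label,
                    "unit": r.unit,
                    "unit_of_analysis": r.unit_of_analysis,
                    "per_group": r.per_group,
                    "H": r.h,
                    "p": r.p,
                    "significant": r.significant,
                    "flag": r.flag,
                }
                for r in self.rows
            ],
        }

    def to_markdown(self) -> str:
        lines = [
            f"# Group comparison (policy: {self.policy})",
            "",
            "| Metric | "
            + " | ".join(f"{g} median (IQR)" for g in GROUPS)
            + " | p |",
            "|---" * 5 + "|",
        ]
        for r in self.rows:
            cells = []
            for g in GROUPS:
                pg = r.per_group.get(g)
                if pg is None or not np.isfinite(pg["median"]):
                    cells.append("-")
                else:
                    cells.append(
                        f"{pg['median']:.3g} ({pg['q1']:.3g}-{pg['q3']:.3g})"
                    )
            p_txt = "-" if math.isnan(r.p) else f"{r.p:.3g}"
            if r.significant:
                p_txt = f"**{p_txt}**"
            lines.append(f"| {r.label} | " + " | ".join(cells) + f" | {p_txt} |")
        lines.append("")
        lines.append("Achieved stitches per group (sessions): ")
        for g in GROUPS:
            if g in self.achievement:
                c = self.achievement[g]
                lines.append(
                    f"- {g}: "
                    + ", ".join(f"{k}: {v}" for k, v in sorted(c.items()))
                )
        return "\n".join(lines) + "\n"


def build_report(
    cohort: list[SessionRecord],
    policy: str = "paper",
    zones: ZoneConfig | None = None,
    sampling_hz: float = 1.0,
    penalty_s: float = 300.0,
    alpha: float = ALPHA,
) -> ComparisonReport:
    """Build the full metric-by-metric group comparison.

    The report carries one row per metric plus an achievement row; rows
    for which fewer than two groups have data are flagged rather than
    dropped.  The output is invariant to the ordering of the input
    sessions.
    """
    selected = select_sessions(cohort, policy)
    selected = sorted(
        selected, key=lambda r: (r.group, r.participant, r.session_index)
    )
    metrics = [
        compute_session_metrics(r, zones=zones, sampling_hz=sampling_hz,
                                penalty_s=penalty_s)
        for r in selected
    ]
    groups_present = [g for g in GROUPS if any(r.group == g for r in selected)]
    n_sessions = {
        g: sum(1 for r in selected if r.group == g) for g in groups_present
    }

    rows: list[ReportRow] = []
    for key, label, unit, pooling in METRIC_ROWS:
        values: dict[str, list[float]] = {g: [] for g in groups_present}
        for rec, m in zip(selected, metrics):
            if pooling == "session":
                v = m.scalar(key)
                if math.isfinite(v):
                    values[rec.group].append(float(v))
            else:
                values[rec.group].extend(
                    float(v) for v in m.pooled(key) if math.isfinite(v)
                )
        per_group = {}
        for g in groups_present:
            if values[g]:
                med, q1, q3 = median_iqr(values[g])
                per_group[g] = {
                    "n": len(values[g]),
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
        nonempty = [values[g] for g in groups_present if values[g]]
        if len(nonempty) >= 2:
            h, p = kruskal_wallis(nonempty, method="asymptotic")
            flag = "" if len(nonempty) == len(groups_present) else "missing-group"
        else:
            h, p, flag = float("nan"), float("nan"), "insufficient-data"
        rows.append(
            ReportRow(
                key=key,
                label=label,
                unit=unit,
                unit_of_analysis=pooling,
                per_group=per_group,
                h=h,
                p=p,
                significant=bool(p < alpha) if math.isfinite(p) else False,
                flag=flag,
            )
        )

    achievement = count_achievement(selected)
    rows.append(
        ReportRow(
            key="achievement",
            label="Achieved stitches (sessions)",
            unit="count",
            unit_of_analysis="session",
            per_group={
                g: {"n": n_sessions[g], "median": float("nan"),
                    "q1": float("nan"), "q3": float("nan")}
                for g in groups_present
            },
            h=float("nan"),
            p=float("nan"),
            significant=False,
            flag="counts",
        )
    )
    return ComparisonReport(
        rows=rows,
        achievement=achievement,
        n_sessions=n_sessions,
        policy=policy,
        alpha=alpha,
    )
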