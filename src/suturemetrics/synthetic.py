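"""Synthetic corneal-suturing sessions and cohorts.

The study this package analyses recorded real microscope video; its
recordings are not redistributable, so this module generates sessions with
the same observable structure so every downstream stage is testable:

* per-stitch completion is Bernoulli with a group-dependent probability;
* per-stitch durations and inter-stitch gaps are log-normal (positive and
  right-skewed, matching minute-scale medians with wide spread);
* the instrument trace is a continuous-time Markov process over the three
  zones, sampled at the scenario rate; positions are drawn uniformly inside
  the corresponding region (cornea disc or base annulus) and flagged
  invisible in zone 3 — the observable used downstream is exactly the zone
  label per sample, which a 3-state process reproduces directly;
* stitch endpoints follow an ideal template (evenly spaced midpoints on the
  wound line, stitches perpendicular to the wound) perturbed by the
  profile's length drift, length noise, spacing noise and angle jitter;
* rubric item scores are integer-rounded truncated-normal draws in [1, 5]
  for each of two raters; a RULA posture consistent with the profile's
  target grand score is drawn from the posture grid.

Default group profiles (senior / junior / novice) are calibrated once so
the group medians land near the published anchors: monotone decreasing
stitch quality and monotone increasing times from senior to novice, length
drift above 1 for seniors and below 1 for novices, and zone-1 dwell
fractions of roughly 0.69 / 0.55 / 0.61 with increasingly frequent zone
switching in less experienced groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Stitch, StitchSet
from .scoring import RULAPosture, ZhangSheet, load_rubric, load_rula_tables
from .session import SessionRecord
from .timing import EventLog, StitchEvents
from .zones import ToolTrace, ZoneConfig

__all__ = [
    "GroupProfile",
    "ScenarioConfig",
    "default_profiles",
    "simulate_session",
    "simulate_cohort",
    "render_frames",
    "px_zone_config",
    "mm_to_px",
    "px_to_mm",
]


@dataclass(frozen=True)
class GroupProfile:
    """Statistical profile of one experience group.

    ``zone_rates`` is a 3x3 table of transition rates (events/s) for the
    continuous-time 3-state zone process; the diagonal is ignored.
    ``length_drift`` multiplies the mean stitch length per successive
    stitch (> 1: stitches grow over the session; < 1: they shrink).
    """

    group_label: str
    stitch_time_median: float  # seconds per stitch
    stitch_time_log_sd: float
    completion_prob: float
    zone_rates: tuple  # 3x3, events/s
    stitch_length_mm: float  # mean length of stitch 1
    stitch_length_sd_mm: float
    length_drift: float
    angle_jitter_deg_sd: float
    spacing_mm: float
    spacing_sd_mm: float
    zhang_item_mean: float
    zhang_item_sd: float
    rula_grand_mode: int
    gap_median_s: float = 60.0  # inter-stitch gap (thread cut -> next entry)
    gap_log_sd: float = 0.4

    def __post_init__(self) -> None:
        rates = np.asarray(self.zone_rates, dtype=float)
        if rates.shape != (3, 3):
            raise ValueError("zone_rates must be a 3x3 table")
        object.__setattr__(self, "zone_rates", tuple(map(tuple, rates)))
        scalars = {
            "stitch_time_median": self.stitch_time_median,
            "stitch_time_log_sd": self.stitch_time_log_sd,
            "completion_prob": self.completion_prob,
            "stitch_length_mm": self.stitch_length_mm,
            "stitch_length_sd_mm": self.stitch_length_sd_mm,
            "length_drift": self.length_drift,
            "angle_jitter_deg_sd": self.angle_jitter_deg_sd,
            "spacing_mm": self.spacing_mm,
            "spacing_sd_mm": self.spacing_sd_mm,
            "zhang_item_mean": self.zhang_item_mean,
            "zhang_item_sd": self.zhang_item_sd,
            "gap_median_s": self.gap_median_s,
            "gap_log_sd": self.gap_log_sd,
        }
        for name, v in scalars.items():
            if not math.isfinite(float(v)):
                raise ValueError(f"profile field {name} must be finite, got {v!r}")
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise ValueError("zone_rates must be finite and >= 0")
        if not (0.0 <= self.completion_prob <= 1.0):
            raise ValueError("completion_prob must lie in [0, 1]")
        for name in (
            "stitch_time_log_sd",
            "stitch_length_sd_mm",
            "angle_jitter_deg_sd",
            "spacing_sd_mm",
            "zhang_item_sd",
            "gap_log_sd",
        ):
            if float(scalars[name]) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (1.0 <= self.zhang_item_mean <= 5.0):
            raise ValueError("zhang_item_mean must lie in [1, 5]")
        if not (1 <= int(self.rula_grand_mode) <= 7):
            raise ValueError("rula_grand_mode must lie in 1..7")

    @property
    def rate_matrix(self) -> np.ndarray:
        return np.asarray(self.zone_rates, dtype=float)


@dataclass(frozen=True)
class ScenarioConfig:
    """The suturing exercise: a 4 mm linear penetrating wound, three
    stitches (three loops each), traced at 1 Hz."""

    wound_length_mm: float = 4.0
    wound_center: tuple[float, float] = (2.0, 0.0)
    wound_orientation_deg: float = 90.0
    n_stitches_required: int = 3
    loops_per_stitch: int = 3  # metadata only
    zone_config: ZoneConfig = field(default_factory=ZoneConfig)
    sampling_hz: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.wound_length_mm > 0:
            raise ValueError("wound_length_mm must be > 0")
        if self.n_stitches_required < 1:
            raise ValueError("n_stitches_required must be >= 1")
        if self.sampling_hz <= 0:
            raise ValueError("sampling_hz must be > 0")

    @property
    def wound_endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        theta = math.radians(self.wound_orientation_deg)
        u = np.array([math.cos(theta), math.sin(theta)])
        c = np.asarray(self.wound_center, dtype=float)
        half = 0.5 * self.wound_length_mm
        return c - half * u, c + half * u


def _rates_from_stationary(pi, switch_rate: float) -> tuple:
    """Rate table q_ij = switch_rate * pi_j (i != j); stationary law = pi."""
    pi = np.asarray(pi, dtype=float)
    q = switch_rate * np.tile(pi, (3, 1))
    np.fill_diagonal(q, 0.0)
    return tuple(map(tuple, q))


def default_profiles() -> dict[str, GroupProfile]:
    """The three default experience-group profiles (study conditions)."""
    return {
        "senior": GroupProfile(
            group_label="senior",
            stitch_time_median=93.0,
            stitch_time_log_sd=0.25,
            completion_prob=1.0,
            zone_rates=_rates_from_stationary((0.69, 0.19, 0.12), 0.08),
            stitch_length_mm=1.0,
            stitch_length_sd_mm=0.15,
            length_drift=1.16,
            angle_jitter_deg_sd=2.9,
            spacing_mm=0.94,
            spacing_sd_mm=0.12,
            zhang_item_mean=4.83,
            zhang_item_sd=0.35,
            rula_grand_mode=3,
            gap_median_s=67.0,
            gap_log_sd=0.30,
        ),
        "junior": GroupProfile(
            group_label="junior",
            stitch_time_median=121.0,
            stitch_time_log_sd=0.30,
            completion_prob=1.0,
            zone_rates=_rates_from_stationary((0.547, 0.28, 0.173), 0.14),
            stitch_length_mm=0.85,
            stitch_length_sd_mm=0.20,
            length_drift=1.05,
            angle_jitter_deg_sd=6.0,
            spacing_mm=0.78,
            spacing_sd_mm=0.15,
            zhang_item_mean=4.21,
            zhang_item_sd=0.60,
            rula_grand_mode=3,
            gap_median_s=57.0,
            gap_log_sd=0.40,
        ),
        "novice": GroupProfile(
            group_label="novice",
            stitch_time_median=192.0,
            stitch_time_log_sd=0.45,
            completion_prob=0.9,
            zone_rates=_rates_from_stationary((0.61, 0.22, 0.17), 0.20),
            stitch_length_mm=1.35,
            stitch_length_sd_mm=0.30,
            length_drift=0.83,
            angle_jitter_deg_sd=7.2,
            spacing_mm=0.88,
            spacing_sd_mm=0.20,
            zhang_item_mean=3.0,
            zhang_item_sd=1.0,
            rula_grand_mode=3,
            gap_median_s=78.0,
            gap_log_sd=0.50,
        ),
    }


def _simulate_ctmc(rng, rates: np.ndarray, t_end: float, initial_state: int = 0):
    """Jump times and states of the 3-state zone process on [0, t_end].

    States are 0-based internally.  A state with zero exit rate is
    absorbing.  Returns (jump_times, states) with jump_times[0] == 0.
    """
    exit_rates = rates.sum(axis=1)
    times = [0.0]
    states = [initial_state]
    t, s = 0.0, initial_state
    while True:
        r = exit_rates[s]
        if r <= 0:
            break
        t = t + rng.exponential(1.0 / r)
        if t >= t_end:
            break
        p = rates[s] / r
        s = int(rng.choice(3, p=p))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states, dtype=int)


def _positions_in_zone(rng, zone: np.ndarray, cfg: ZoneConfig):
    """Uniform positions inside the region of each sample's zone.

    Zone 3 samples get NaN coordinates and visible=False (an instrument
    outside the base is treated as out of the field of view).
    """
    n = zone.size
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    visible = zone != 3
    u = rng.random(n)
    theta = rng.random(n) * 2 * np.pi
    rc2, rb2 = cfg.r_cornea**2, cfg.r_base**2
    r = np.zeros(n)
    in1 = zone == 1
    in2 = zone == 2
    r[in1] = np.sqrt(u[in1] * rc2)
    r[in2] = np.sqrt(rc2 + u[in2] * (rb2 - rc2))
    x[visible] = cfg.center[0] + r[visible] * np.cos(theta[visible])
    y[visible] = cfg.center[1] + r[visible] * np.sin(theta[visible])
    return x, y, visible


_posture_pool_cache: dict[int, np.ndarray] = {}


def _posture_pool(grand: int) -> np.ndarray:
    """All no-muscle/no-force posture grid cells whose grand score equals
    ``grand`` (rows of the 7 posture fields)."""
    if grand in _posture_pool_cache:
        return _posture_pool_cache[grand]
    tables = load_rula_tables()
    ua, la, w, wt, nk, tr, lg = np.meshgrid(
        np.arange(1, 7),
        np.arange(1, 4),
        np.arange(1, 5),
        np.arange(1, 3),
        np.arange(1, 7),
        np.arange(1, 7),
        np.arange(1, 3),
        indexing="ij",
    )
    score_a = tables.a[ua - 1, la - 1, w - 1, wt - 1]
    score_b = tables.b[nk - 1, tr - 1, lg - 1]
    g = tables.c[np.minimum(score_a, 8) - 1, np.minimum(score_b, 7) - 1]
    mask = g == grand
    pool = np.stack(
        [ua[mask], la[mask], w[mask], wt[mask], nk[mask], tr[mask], lg[mask]],
        axis=1,
    )
    if pool.size == 0:
        raise ValueError(f"no posture reaches grand score {grand} without force")
    _posture_pool_cache[grand] = pool
    return pool


def _draw_posture(rng, grand_mode: int) -> RULAPosture:
    pool = _posture_pool(int(grand_mode))
    row = pool[int(rng.integers(pool.shape[0]))]
    return RULAPosture(
        upper_arm=int(row[0]),
        lower_arm=int(row[1]),
        wrist=int(row[2]),
        wrist_twist=int(row[3]),
        neck=int(row[4]),
        trunk=int(row[5]),
        legs=int(row[6]),
    )


def _draw_zhang_sheet(rng, rater: str, profile: GroupProfile, rubric) -> ZhangSheet:
    raw = rng.normal(profile.zhang_item_mean, profile.zhang_item_sd, rubric.n_items)
    items = np.rint(np.clip(raw, rubric.scale_min, rubric.scale_max)).astype(int)
    return ZhangSheet(rater=rater, item_scores=tuple(items), rubric=rubric)


def _generate_stitches(
    rng, profile: GroupProfile, scenario: ScenarioConfig, completed: np.ndarray
) -> StitchSet:
    n = scenario.n_stitches_required
    start, _ = scenario.wound_endpoints
    theta = math.radians(scenario.wound_orientation_deg)
    u = np.array([math.cos(theta), math.sin(theta)])  # along wound
    v = np.array([-math.sin(theta), math.cos(theta)])  # perpendicular
    center = np.asarray(scenario.wound_center, dtype=float)
    stitches = []
    for k in range(1, n + 1):
        offset = (k - (n + 1) / 2.0) * profile.spacing_mm
        offset += rng.normal(0.0, profile.spacing_sd_mm) if profile.spacing_sd_mm else 0.0
        mid = center + offset * u
        length = profile.stitch_length_mm * profile.length_drift ** (k - 1)
        if profile.stitch_length_sd_mm:
            length += rng.normal(0.0, profile.stitch_length_sd_mm)
        length = max(length, 0.05)
        jitter = (
            rng.normal(0.0, profile.angle_jitter_deg_sd)
            if profile.angle_jitter_deg_sd
            else 0.0
        )
        a = math.radians(jitter)
        direction = math.cos(a) * v + math.sin(a) * u
        entry = mid - 0.5 * length * direction
        exit_ = mid + 0.5 * length * direction
        stitches.append(
            Stitch(
                index=k,
                entry=(float(entry[0]), float(entry[1])),
                exit=(float(exit_[0]), float(exit_[1])),
                completed=bool(completed[k - 1]),
            )
        )
    return StitchSet(stitches=tuple(stitches), units="mm")


def simulate_session(
    profile: GroupProfile,
    scenario: ScenarioConfig | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant: str = "P01",
    session_index: int = 1,
) -> SessionRecord:
    """Generate one complete synthetic session.

    The same (profile, scenario, seed) triple always yields an identical
    session.  Draw order is fixed: completions, stitch durations, gaps,
    zone process, positions, stitch endpoints, rubric sheets, posture.
    """
    if scenario is None:
        scenario = ScenarioConfig()
    rng = np.random.default_rng(seed)
    n = scenario.n_stitches_required

    completed = rng.random(n) < profile.completion_prob
    mu = math.log(profile.stitch_time_median)
    durations = np.exp(rng.normal(mu, profile.stitch_time_log_sd, n))
    gap_mu = math.log(profile.gap_median_s)
    gaps = np.exp(rng.normal(gap_mu, profile.gap_log_sd, max(n - 1, 0)))

    # Event log: an uncompleted attempt consumes its drawn duration but
    # records no thread cut.
    t = 5.0
    events = []
    for k in range(1, n + 1):
        entry = t
        cut = entry + durations[k - 1] if completed[k - 1] else None
        events.append(StitchEvents(index=k, needle_entry=entry, thread_cut=cut))
        t = entry + durations[k - 1]
        if k < n:
            t += gaps[k - 1]
    log = EventLog(stitches=tuple(events), required_stitches=n)
    t_end = t + 5.0

    rates = profile.rate_matrix
    jump_t, jump_s = _simulate_ctmc(rng, rates, t_end, initial_state=0)
    ticks = np.arange(0.0, t_end + 1e-9, 1.0 / scenario.sampling_hz)
    state_idx = np.searchsorted(jump_t, ticks, side="right") - 1
    zone = jump_s[state_idx] + 1
    x, y, visible = _positions_in_zone(rng, zone, scenario.zone_config)
    trace = ToolTrace(t=ticks, x=x, y=y, visible=visible)

    stitches = _generate_stitches(rng, profile, scenario, completed)
    rubric = load_rubric()
    sheets = tuple(
        _draw_zhang_sheet(rng, rater, profile, rubric)
        for rater in ("rater_1", "rater_2")
    )
    posture = _draw_posture(rng, profile.rula_grand_mode)

    w_start, w_end = scenario.wound_endpoints
    meta = {
        "schema_version": 1,
        "group": profile.group_label,
        "participant": participant,
        "session": int(session_index),
        "scenario": {
            "wound_length_mm": float(scenario.wound_length_mm),
            "wound_center": [float(c) for c in scenario.wound_center],
            "wound_orientation_deg": float(scenario.wound_orientation_deg),
            "n_stitches_required": int(scenario.n_stitches_required),
            "loops_per_stitch": int(scenario.loops_per_stitch),
            "sampling_hz": float(scenario.sampling_hz),
        },
        "wound": {
            "start": [float(w_start[0]), float(w_start[1])],
            "end": [float(w_end[0]), float(w_end[1])],
        },
        "zone_config": {
            "center": [float(c) for c in scenario.zone_config.center],
            "r_cornea": float(scenario.zone_config.r_cornea),
            "r_base": float(scenario.zone_config.r_base),
            "units": scenario.zone_config.units,
        },
    }
    return SessionRecord(
        participant=participant,
        group=profile.group_label,
        session_index=session_index,
        trace=trace,
        stitches=stitches,
        events=log,
        zhang_sheets=sheets,
        rula_postures=(posture,),
        meta=meta,
    )


def simulate_cohort(
    profiles: list[GroupProfile] | None = None,
    n_per_group: int | tuple[int, ...] = (5, 8, 11),
    sessions_per_participant: int = 3,
    seed: int = 0,
    scenario: ScenarioConfig | None = None,
) -> list[SessionRecord]:
    """Generate a cohort of sessions over one or more group profiles.

    ``n_per_group`` may be a single count or one count per profile; the
    default mirrors a 5 senior / 8 junior / 11 novice cohort with three
    sessions each.  Per-session seeds derive from the master seed by the
    counter scheme SeedSequence([seed, group_index, participant_index,
    session_index]), so any session can be regenerated in isolation.
    """
    if profiles is None:
        profiles = list(default_profiles().values())
    if not profiles:
        raise ValueError("need at least one group profile")
    if isinstance(n_per_group, (int, np.integer)):
        counts = [int(n_per_group)] * len(profiles)
    else:
        counts = [int(c) for c in n_per_group]
        if len(counts) != len(profiles):
            raise ValueError("n_per_group must match the number of profiles")
    if any(c < 1 for c in counts):
        raise ValueError("n_per_group must be >= 1")
    if sessions_per_participant < 1:
        raise ValueError("sessions_per_participant must be >= 1")
    records = []
    for gi, (profile, count) in enumerate(zip(profiles, counts)):
        for pi in range(count):
            participant = f"{profile.group_label}_{pi + 1:02d}"
            for si in range(1, sessions_per_participant + 1):
                ss = np.random.SeedSequence([int(seed), gi, pi, si])
                records.append(
                    simulate_session(
                        profile,
                        scenario=scenario,
                        seed=ss,
                        participant=participant,
                        session_index=si,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Frame rendering (the image-based path of zone analysis)
# ---------------------------------------------------------------------------

_CIRCLE_INTENSITY = 50
_BLOB_SIGMA_PX = 1.5


def px_zone_config(
    zones: ZoneConfig, image_size_px: tuple[int, int], mm_per_px: float
) -> ZoneConfig:
    """The zone partition expressed in pixel coordinates of a rendered
    frame (zone center at the image center)."""
    h, w = image_size_px
    return ZoneConfig(
        center=((w - 1) / 2.0, (h - 1) / 2.0),
        r_cornea=zones.r_cornea / mm_per_px,
        r_base=zones.r_base / mm_per_px,
        units="px",
    )


def mm_to_px(point_mm, zones: ZoneConfig, image_size_px, mm_per_px: float):
    h, w = image_size_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return (
        cx + (point_mm[0] - zones.center[0]) / mm_per_px,
        cy + (point_mm[1] - zones.center[1]) / mm_per_px,
    )


def px_to_mm(point_px, zones: ZoneConfig, image_size_px, mm_per_px: float):
    h, w = image_size_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return (
        zones.center[0] + (point_px[0] - cx) * mm_per_px,
        zones.center[1] + (point_px[1] - cy) * mm_per_px,
    )


def render_frames(
    trace: ToolTrace,
    zones: ZoneConfig,
    image_size_px: tuple[int, int] = (256, 256),
    mm_per_px: float = 0.15,
) -> list[np.ndarray]:
    """Render one grayscale frame per trace sample.

    Visible samples produce a bright Gaussian instrument blob at the
    sample position; every frame carries the two zone circles drawn
    faintly.  The base circle must fit inside the image.
    """
    from skimage.draw import circle_perimeter

    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be > 0")
    h, w = int(image_size_px[0]), int(image_size_px[1])
    r_base_px = zones.r_base / mm_per_px
    if r_base_px > min(h, w) / 2.0 - 1:
        raise ValueError("image too small to contain the base circle")
    background = np.zeros((h, w), dtype=np.uint8)
    cy, cx = (h - 1) // 2, (w - 1) // 2
    for r in (zones.r_cornea, zones.r_base):
        rr, cc = circle_perimeter(cy, cx, int(round(r / mm_per_px)), shape=(h, w))
        background[rr, cc] = _CIRCLE_INTENSITY
    frames = []
    for i in range(len(trace)):
        frame = background.copy()
        if trace.visible[i]:
            bx, by = mm_to_px(
                (trace.x[i], trace.y[i]), zones, (h, w), mm_per_px
            )
            _draw_blob(frame, bx, by)
        frames.append(frame)
    return frames


def _draw_blob(frame: np.ndarray, bx: float, by: float) -> None:
    """Additive Gaussian blob centred at the (possibly fractional) pixel
    position (bx, by)."""
    h, w = frame.shape
    rad = int(math.ceil(4 * _BLOB_SIGMA_PX))
    x0 = max(int(math.floor(bx)) - rad, 0)
    x1 = min(int(math.ceil(bx)) + rad + 1, w)
    y0 = max(int(math.floor(by)) - rad, 0)
    y1 = min(int(math.ceil(by)) + rad + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - bx) ** 2 + (yy - by) ** 2
    blob = 255.0 * np.exp(-d2 / (2.0 * _BLOB_SIGMA_PX**2))
    patch = np.clip(frame[y0:y1, x0:x1].astype(float) + blob, 0, 255)
    frame[y0:y1, x0:x1] = patch.astype(np.uint8)
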