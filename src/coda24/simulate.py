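"""Synthetic cohorts, bout schedules and tri-axial wrist signals.

Every downstream stage of the package is exercised against data with known
ground truth, generated here:

* :func:`generate_cohort` draws a two-group cohort (typically developing vs
  suspected DCD) whose daily 4-part compositions are log-ratio Gaussian
  around the group compositional means, together with covariates, a DCDQ
  screening score consistent with the group label, and a motor-competence
  outcome generated from a linear model on the ilr coordinates.
* :func:`generate_day_schedule` tiles a 1440-min day with behaviour bouts
  whose totals match a participant's true minutes (one contiguous nocturnal
  sleep bout with a few posture shifts, short waking bouts, optional
  off-body gaps of at least an hour).
* :func:`render_triaxial` turns a schedule into raw x/y/z samples in g: per
  bout, a gravity vector at the bout's posture angle plus a circular
  "dynamic" acceleration orthogonal to gravity whose amplitude is set so the
  epoch-mean ENMO equals the bout's target, a slow random walk of the
  posture angle (fast during waking, nearly frozen during sleep, absent
  off-body), and optional white measurement noise.

The circular orthogonal motion keeps the vector norm at sqrt(1 + A^2)
exactly, so the rendered ENMO hits its target deterministically and the
round trip through the processing chain is limited only by epoch rounding
and detected sleep-window edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from . import reference as ref
from .accel import TriaxialRecording
from .coda import DEFAULT_PARTS, IlrBasis, ilr, ilr_inv, pivot_basis

__all__ = [
    "CohortSpec",
    "CohortTruth",
    "ScheduleParams",
    "generate_cohort",
    "generate_day_schedule",
    "render_triaxial",
    "render_week",
    "schedule_labels",
    "make_stationary_recording",
    "distort_recording",
]

BEHAVIOURS = DEFAULT_PARTS + ("nonwear",)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class CohortSpec:
    """Conditions a synthetic cohort is drawn under.

    Defaults reproduce the motivating cohort: 69 children, 30 with suspected
    DCD, group compositional means as reported, log-ratio dispersion 0.25
    (typical of weekly-averaged child time-use data and consistent with the
    reported outcome-model precision), and an outcome model calibrated so
    association strengths match the reported ones.
    """

    n_participants: int = ref.N_TD + ref.N_SDCD
    prop_sdcd: float = ref.N_SDCD / (ref.N_TD + ref.N_SDCD)
    group_mean_minutes: dict = field(
        default_factory=lambda: {
            g: tuple(v) for g, v in ref.GROUP_MEAN_MINUTES["total"].items()
        }
    )
    logratio_sd: float = 0.25
    age_mean: float = ref.AGE_MEAN
    age_sd: float = ref.AGE_SD
    age_range: tuple = ref.AGE_RANGE
    prop_boys: float = ref.PROP_BOYS
    deprivation_probs: tuple = tuple(
        np.asarray(ref.DEPRIVATION_COUNTS) / sum(ref.DEPRIVATION_COUNTS)
    )
    outcome_coefficients: dict = field(
        default_factory=lambda: dict(ref.DEFAULT_OUTCOME_COEFFICIENTS)
    )
    outcome_noise_sd: float = ref.DEFAULT_OUTCOME_NOISE_SD
    seed: int = 0

    def validate(self) -> None:
        for g, mean in self.group_mean_minutes.items():
            if abs(sum(mean) - 1440.0) > 1e-6:
                raise ValueError(f"group mean for {g!r} sums to {sum(mean)}, not 1440")
            if any(m <= 0 for m in mean):
                raise ValueError(f"group mean for {g!r} has non-positive parts")
        for p in (self.prop_sdcd, self.prop_boys, *self.deprivation_probs):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.deprivation_probs) - 1.0) > 1e-9:
            raise ValueError("deprivation quartile probabilities must sum to 1")
        n_sdcd = round(self.n_participants * self.prop_sdcd)
        if min(n_sdcd, self.n_participants - n_sdcd) < 2:
            raise ValueError("need at least 2 participants per group")
        if self.logratio_sd < 0 or self.outcome_noise_sd < 0:
            raise ValueError("dispersions must be non-negative")


@dataclass
class CohortTruth:
    """Ground truth for one generated cohort.

    ``table`` has one row per participant: id, group, true daily minutes per
    behaviour, true ilr coordinates (z1..z3 in the sleep-pivot basis),
    covariates, DCDQ and motor-competence (SFDC) scores.
    """

    table: pd.DataFrame
    basis: IlrBasis
    spec: CohortSpec

    def minutes(self, group: str | None = None) -> np.ndarray:
        t = self.table if group is None else self.table[self.table["group"] == group]
        return t[list(DEFAULT_PARTS)].to_numpy()


def generate_cohort(spec: CohortSpec | None = None, seed: int | None = None) -> CohortTruth:
    """Draw a cohort according to ``spec`` (see :class:`CohortSpec`)."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_participants
    n_sdcd = round(n * spec.prop_sdcd)
    groups = np.array(["sdcd"] * n_sdcd + ["td"] * (n - n_sdcd))
    rng.shuffle(groups)

    basis = pivot_basis(DEFAULT_PARTS, "sleep")
    mu = {g: ilr(np.asarray(m, float), basis) for g, m in spec.group_mean_minutes.items()}
    z = np.vstack([mu[g] for g in groups])
    z = z + rng.normal(0.0, spec.logratio_sd, z.shape)
    minutes = ilr_inv(z, basis, 1440.0)

    lo, hi = spec.age_range
    if spec.age_sd > 0:
        a, b = (lo - spec.age_mean) / spec.age_sd, (hi - spec.age_mean) / spec.age_sd
        ages = truncnorm.rvs(a, b, loc=spec.age_mean, scale=spec.age_sd, size=n, random_state=rng)
    else:
        ages = np.full(n, spec.age_mean)
    sex_male = (rng.random(n) < spec.prop_boys).astype(int)
    deprivation = rng.choice(np.arange(1, 5), size=n, p=np.asarray(spec.deprivation_probs))

    thresholds = np.array([ref.dcdq_threshold(a) for a in ages])
    dcdq = np.where(
        groups == "sdcd",
        rng.integers(np.maximum(thresholds - 25, 10), thresholds),
        rng.integers(thresholds, ref.DCDQ_MAX + 1),
    )

    c = spec.outcome_coefficients
    beta = np.array([c["z1"], c["z2"], c["z3"]])
    lin = (
        c["intercept"]
        + z @ beta
        + c["age"] * ages
        + c["sex_male"] * sex_male
        + c["deprivation"] * deprivation
    )
    sfdc = lin + rng.normal(0.0, spec.outcome_noise_sd, n) if spec.outcome_noise_sd > 0 else lin
    sfdc = np.clip(sfdc, 0.0, ref.SFDC_MAX)

    lifestyle = {}
    for item, t in ref.LIFESTYLE_TABLES.items():
        levels = list(t["levels"])
        answers = np.empty(n, dtype=object)
        for g in ("td", "sdcd"):
            m = groups == g
            probs = np.asarray(t[g], dtype=float)
            probs = probs / probs.sum()
            answers[m] = rng.choice(levels, size=m.sum(), p=probs)
        lifestyle[f"lifestyle_{item}"] = answers

    table = pd.DataFrame(
        {
            "id": [f"P{i + 1:03d}" for i in range(n)],
            "group": groups,
            **{p: minutes[:, j] for j, p in enumerate(DEFAULT_PARTS)},
            **{f"z{k + 1}": z[:, k] for k in range(3)},
            "age": ages,
            "sex_male": sex_male,
            "deprivation": deprivation,
            "dcdq": dcdq,
            "sfdc": sfdc,
            **lifestyle,
        }
    )
    return CohortTruth(table=table, basis=basis, spec=spec)


# ---------------------------------------------------------------------------
# bout schedules


@dataclass
class ScheduleParams:
    """Bout-structure and rendering conditions for one simulated day.

    ENMO target bands sit safely inside the intensity cut-point bands
    (SB <= 50 < LPA < 200 <= MVPA, in mg); posture-wander rates control how
    much the z-angle drifts per 5-s epoch (fast while awake, nearly frozen
    in sleep, zero off-body), which is what the sleep heuristic keys on.
    """

    enmo_bands_mg: dict = field(
        default_factory=lambda: {
            "sleep": (5.0, 20.0),
            "sb": (10.0, 45.0),
            "lpa": (60.0, 190.0),
            "mvpa": (210.0, 350.0),
            "nonwear": (0.0, 0.0),
        }
    )
    bout_minutes: dict = field(
        default_factory=lambda: {"sb": (3, 20), "lpa": (3, 15), "mvpa": (2, 8)}
    )
    sleep_segments: tuple = (3, 5)  # 2-4 posture shifts per night
    sleep_shift_deg: tuple = (8.0, 25.0)
    sleep_base_angle_deg: tuple = (30.0, 70.0)
    wake_angle_deg: tuple = (-45.0, 45.0)
    wander_deg_per_epoch: dict = field(
        default_factory=lambda: {
            "sleep": 0.03,
            "sb": 3.0,
            "lpa": 3.5,
            "mvpa": 4.5,
            "nonwear": 0.0,
        }
    )
    motion_freq_hz: float = 1.0
    epoch_s: int = 5


def _round_preserving_total(values: np.ndarray, total: int) -> np.ndarray:
    """Round to whole minutes, largest-remainder, preserving the total."""
    floors = np.floor(values).astype(int)
    rem = total - floors.sum()
    order = np.argsort(-(values - floors))
    out = floors.copy()
    out[order[:rem]] += 1
    return out


def generate_day_schedule(
    minutes,
    rng: np.random.Generator,
    nonwear_minutes: int = 0,
    params: ScheduleParams | None = None,
) -> pd.DataFrame:
    """Tile one 1440-min day with behaviour bouts.

    ``minutes`` maps sleep/sb/lpa/mvpa to true daily minutes (summing to
    1440).  The day starts with a single nocturnal sleep bout (several
    posture segments) and partitions waking time into short bouts whose
    totals match the true minutes after whole-minute rounding.  A non-wear
    gap of at least 60 min can replace scheduled waking behaviour; its start
    snaps to the quarter-hour (devices come off at round times, and this
    keeps the off-body span commensurate with the sliding detection grid).

    Returns a DataFrame with ``start_min, duration_min, behaviour,
    target_enmo_mg, z_angle_deg, azimuth_deg`` tiling [0, 1440) exactly.
    """
    params = params or ScheduleParams()
    if not 0 <= nonwear_minutes < 1440:
        raise ValueError("nonwear_minutes must be in [0, 1440)")
    if nonwear_minutes and nonwear_minutes < 60:
        raise ValueError("non-wear gaps shorter than 60 min are not generated")
    vals = np.array([float(minutes[p]) for p in DEFAULT_PARTS])
    if abs(vals.sum() - 1440.0) > 1e-6:
        raise ValueError(f"daily minutes sum to {vals.sum()}, not 1440")
    totals = dict(zip(DEFAULT_PARTS, _round_preserving_total(vals, 1440)))

    rows = []
    # --- nocturnal sleep: one contiguous bout, 2-4 posture shifts
    s_total = totals["sleep"]
    n_seg = int(rng.integers(params.sleep_segments[0], params.sleep_segments[1] + 1))
    n_seg = max(2, min(n_seg, s_total // 20))
    base = s_total - 20 * n_seg
    extra = rng.multinomial(base, np.ones(n_seg) / n_seg)
    seg_dur = 20 + extra
    angle = rng.uniform(*params.sleep_base_angle_deg)
    t = 0
    for d in seg_dur:
        rows.append(("sleep", t, int(d), angle, rng.uniform(0, 360)))
        t += int(d)
        angle = np.clip(
            angle + rng.choice([-1, 1]) * rng.uniform(*params.sleep_shift_deg), -80, 85
        )
    # --- waking bouts
    remaining = {b: totals[b] for b in ("sb", "lpa", "mvpa")}
    while any(v > 0 for v in remaining.values()):
        avail = [b for b, v in remaining.items() if v > 0]
        weights = np.array([remaining[b] for b in avail], dtype=float)
        b = rng.choice(avail, p=weights / weights.sum())
        lo, hi = params.bout_minutes[b]
        dur = int(min(rng.integers(lo, hi + 1), remaining[b]))
        if remaining[b] - dur < lo:
            dur = remaining[b]
        rows.append((b, t, dur, rng.uniform(*params.wake_angle_deg), rng.uniform(0, 360)))
        remaining[b] -= dur
        t += dur
    assert t == 1440

    df = pd.DataFrame(rows, columns=["behaviour", "start_min", "duration_min", "z_angle_deg", "azimuth_deg"])
    df = df[["start_min", "duration_min", "behaviour", "z_angle_deg", "azimuth_deg"]]

    if nonwear_minutes:
        wake_start = int(np.ceil(s_total / 15.0) * 15)
        latest = 1440 - nonwear_minutes
        if latest < wake_start:
            raise ValueError("non-wear gap does not fit into waking time")
        starts = np.arange(wake_start, latest + 1, 15)
        g0 = int(rng.choice(starts))
        df = _carve(df, g0, g0 + nonwear_minutes, rng)

    bands = params.enmo_bands_mg
    df["target_enmo_mg"] = [
        rng.uniform(*bands[b]) if bands[b][1] > bands[b][0] else bands[b][0]
        for b in df["behaviour"]
    ]
    df = df[["start_min", "duration_min", "behaviour", "target_enmo_mg", "z_angle_deg", "azimuth_deg"]]
    _check_schedule(df)
    return df.reset_index(drop=True)


def _carve(df: pd.DataFrame, t0: int, t1: int, rng: np.random.Generator) -> pd.DataFrame:
    """Replace [t0, t1) of a day schedule with an off-body gap."""
    rows = []
    for r in df.itertuples(index=False):
        a, b = r.start_min, r.start_min + r.duration_min
        if b <= t0 or a >= t1:
            rows.append(tuple(r))
            continue
        if a < t0:
            rows.append((a, t0 - a, r.behaviour, r.z_angle_deg, r.azimuth_deg))
        if b > t1:
            rows.append((t1, b - t1, r.behaviour, r.z_angle_deg, r.azimuth_deg))
    rows.append((t0, t1 - t0, "nonwear", rng.uniform(-30, 85), rng.uniform(0, 360)))
    out = pd.DataFrame(
        rows, columns=["start_min", "duration_min", "behaviour", "z_angle_deg", "azimuth_deg"]
    ).sort_values("start_min")
    return out


def _check_schedule(df: pd.DataFrame) -> None:
    starts = df["start_min"].to_numpy()
    durs = df["duration_min"].to_numpy()
    if starts[0] != 0 or durs.sum() != 1440:
        raise ValueError("schedule does not tile the 1440-min day")
    if not np.array_equal(starts[1:], (starts + durs)[:-1]):
        raise ValueError("schedule has gaps or overlaps")
    if (durs <= 0).any():
        raise ValueError("schedule has non-positive bout durations")


def schedule_labels(schedule: pd.DataFrame, epoch_s: int = 5) -> np.ndarray:
    """Per-epoch behaviour labels implied by a day schedule (oracle)."""
    epm = 60 // epoch_s
    labels = np.empty(1440 * epm, dtype=object)
    for r in schedule.itertuples(index=False):
        a = int(r.start_min * epm)
        labels[a : a + int(r.duration_min * epm)] = r.behaviour
    return labels


# ---------------------------------------------------------------------------
# signal rendering


def _reflect(x: np.ndarray, lo: float = -85.0, hi: float = 85.0) -> np.ndarray:
    """Fold a random walk back into [lo, hi] by reflection (keeps step sizes;
    clipping would freeze the walk at the boundary and mimic stillness)."""
    period = 2 * (hi - lo)
    g = np.mod(x - lo, period)
    return lo + np.where(g <= hi - lo, g, period - g)


def _gravity_vectors(phi_deg: np.ndarray, psi_deg: np.ndarray) -> np.ndarray:
    phi = np.radians(phi_deg)
    psi = np.radians(psi_deg)
    return np.stack(
        [np.cos(phi) * np.cos(psi), np.cos(phi) * np.sin(psi), np.sin(phi)], axis=1
    )


def _orthonormal_pair(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    refv = np.tile([0.0, 0.0, 1.0], (len(g), 1))
    near = np.abs(g[:, 2]) > 0.95
    refv[near] = [1.0, 0.0, 0.0]
    e1 = np.cross(g, refv)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(g, e1)
    return e1, e2


def render_triaxial(
    schedule: pd.DataFrame,
    sample_rate_hz: float = 20.0,
    seed: int | np.random.Generator = 0,
    noise_sd_mg: float = 3.0,
    start: pd.Timestamp | str = "2023-11-06",
    participant: str = "sim",
    params: ScheduleParams | None = None,
) -> TriaxialRecording:
    """Render one day schedule to raw tri-axial samples in g.

    Per epoch the gravity direction follows the bout's posture angle plus a
    behaviour-specific random walk; a circular acceleration of amplitude
    ``sqrt((1 + target)^2 - 1)`` orthogonal to gravity makes every sample's
    norm ``1 + target`` exactly, so the epoch-mean ENMO equals the bout's
    target level.  Off-body bouts are static gravity with at most 3 mg of
    noise.  Samples are clipped to the +/-8 g dynamic range.
    """
    params = params or ScheduleParams()
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _check_schedule(schedule)
    epoch_s = params.epoch_s
    epm = 60 // epoch_s

    phi_parts, psi_parts, amp_parts, noise_parts = [], [], [], []
    for r in schedule.itertuples(index=False):
        n_ep = int(r.duration_min) * epm
        w = params.wander_deg_per_epoch[r.behaviour]
        steps = rng.normal(0.0, w, n_ep) if w > 0 else np.zeros(n_ep)
        # waking wander is confined to postures where the epoch-mean z-angle
        # remains sensitive to posture change despite the large dynamic
        # acceleration (the angle saturates towards +/-90 degrees)
        lo, hi = (-55.0, 55.0) if r.behaviour in ("sb", "lpa", "mvpa") else (-85.0, 85.0)
        phi = _reflect(r.z_angle_deg + np.cumsum(steps), lo, hi)
        steps_psi = rng.normal(0.0, 2 * w, n_ep) if w > 0 else np.zeros(n_ep)
        psi = r.azimuth_deg + np.cumsum(steps_psi)
        t = r.target_enmo_mg / 1000.0
        amp = np.full(n_ep, np.sqrt((1.0 + t) ** 2 - 1.0))
        sd = noise_sd_mg if r.behaviour != "nonwear" else min(noise_sd_mg, 3.0)
        noise = np.full(n_ep, sd / 1000.0)
        phi_parts.append(phi)
        psi_parts.append(psi)
        amp_parts.append(amp)
        noise_parts.append(noise)
    phi = np.concatenate(phi_parts)
    psi = np.concatenate(psi_parts)
    amp = np.concatenate(amp_parts)
    noise_sd = np.concatenate(noise_parts)

    g = _gravity_vectors(phi, psi)
    e1, e2 = _orthonormal_pair(g)
    spe = int(round(epoch_s * sample_rate_hz))  # samples per epoch
    n = len(phi) * spe
    tsec = np.arange(n) / sample_rate_hz
    phase = 2 * np.pi * params.motion_freq_hz * tsec
    rep = np.repeat(np.arange(len(phi)), spe)
    data = (
        g[rep]
        + amp[rep, None] * (np.cos(phase)[:, None] * e1[rep] + np.sin(phase)[:, None] * e2[rep])
    )
    if noise_sd_mg > 0:
        data = data + rng.normal(0.0, 1.0, data.shape) * noise_sd[rep, None]
    np.clip(data, -8.0, 8.0, out=data)
    return TriaxialRecording(
        participant=participant, start=pd.Timestamp(start), sample_rate_hz=sample_rate_hz, data=data
    )


def render_week(
    minutes,
    days: int = 7,
    start: pd.Timestamp | str = "2023-11-06",  # a Monday
    sample_rate_hz: float = 20.0,
    seed: int | np.random.Generator = 0,
    noise_sd_mg: float = 3.0,
    nonwear_plan: dict | None = None,
    participant: str = "sim",
    params: ScheduleParams | None = None,
) -> tuple[TriaxialRecording, pd.DataFrame, np.ndarray]:
    """Render a multi-day recording for one participant.

    ``nonwear_plan`` maps day index to off-body minutes injected that day.
    Returns the recording, the concatenated schedule (with a ``day`` column)
    and the per-epoch oracle labels.
    """
    params = params or ScheduleParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nonwear_plan = nonwear_plan or {}
    schedules, labels, chunks = [], [], []
    for day in range(days):
        sched = generate_day_schedule(
            minutes, rng, nonwear_minutes=int(nonwear_plan.get(day, 0)), params=params
        )
        rec = render_triaxial(
            sched,
            sample_rate_hz=sample_rate_hz,
            seed=rng,
            noise_sd_mg=noise_sd_mg,
            start=pd.Timestamp(start) + pd.Timedelta(days=day),
            participant=participant,
            params=params,
        )
        chunks.append(rec.data)
        labels.append(schedule_labels(sched, params.epoch_s))
        sched = sched.copy()
        sched.insert(0, "day", day)
        schedules.append(sched)
    rec = TriaxialRecording(
        participant=participant,
        start=pd.Timestamp(start),
        sample_rate_hz=sample_rate_hz,
        data=np.concatenate(chunks),
    )
    return rec, pd.concat(schedules, ignore_index=True), np.concatenate(labels)


# ---------------------------------------------------------------------------
# calibration fixtures


def make_stationary_recording(
    n_orientations: int = 40,
    minutes_each: float = 20.0,
    sample_rate_hz: float = 20.0,
    seed: int = 0,
    noise_sd_mg: float = 2.0,
    participant: str = "static",
    start: pd.Timestamp | str = "2023-11-06",
) -> TriaxialRecording:
    """A motionless device resting in many orientations (calibration oracle).

    40 orientations x 20 min is > 13 h, satisfying the 12-h auto-calibration
    precondition with plenty of orientation diversity for sphere fitting.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_orientations, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    m = int(round(minutes_each * 60 * sample_rate_hz))
    data = np.repeat(v, m, axis=0)
    if noise_sd_mg > 0:
        data = data + rng.normal(0.0, noise_sd_mg / 1000.0, data.shape)
    return TriaxialRecording(
        participant=participant,
        start=pd.Timestamp(start),
        sample_rate_hz=sample_rate_hz,
        data=np.clip(data, -8, 8),
    )


def distort_recording(
    rec: TriaxialRecording, offset_mg=(0.0, 0.0, 0.0), gain=(1.0, 1.0, 1.0)
) -> TriaxialRecording:
    """Apply a known per-axis sensor distortion ``x -> x * gain + offset``."""
    data = rec.data * np.asarray(gain, float) + np.asarray(offset_mg, float) / 1000.0
    return replace(rec, data=np.clip(data, -8, 8))
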