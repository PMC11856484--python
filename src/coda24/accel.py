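"""Wrist-accelerometer processing: raw tri-axial g's to daily behaviour minutes.

The processing chain mirrors standard open-source raw-accelerometry practice
(GGIR-style):

1. auto-calibration of offsets/gains against local gravity using stationary
   windows;
2. ENMO (Euclidean norm minus one g, negatives truncated) averaged over 5-s
   epochs;
3. non-wear detection from per-axis SD / value range over sliding 60-min
   windows;
4. imputation of non-wear epochs from the same clock time on other days;
5. nightly sleep-window detection from the distribution of change in the
   z-angle;
6. intensity classification by ENMO cut-points (SB <= 50 mg < LPA < 200 mg
   <= MVPA) with the sleep window taking precedence;
7. daily summaries (midnight-to-midnight), wear-time validity filtering and
   per-participant mean compositions for total / weekday / weekend / school
   segments.

All thresholds live in :class:`AccelConfig` and are expressed in physical
units so the sample rate is transparent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "AccelConfig",
    "TriaxialRecording",
    "CalibrationResult",
    "SleepWindow",
    "autocalibrate",
    "epoch_enmo",
    "detect_nonwear",
    "impute_nonwear",
    "detect_sleep_windows",
    "classify_epochs",
    "summarize_days",
    "filter_valid",
    "derive_compositions",
    "process_recording",
]

LABELS = ("sleep", "sb", "lpa", "mvpa")


@dataclass
class AccelConfig:
    """Tunable processing parameters (units in names)."""

    epoch_s: int = 5
    # non-wear rule: sliding 60-min windows in 15-min steps; a window is
    # off-body if >=2 axes have SD < 13 mg or >=2 axes have range < 50 mg,
    # and then its central 15-min block is flagged.
    nonwear_window_min: int = 60
    nonwear_step_min: int = 15
    nonwear_sd_mg: float = 13.0
    nonwear_range_mg: float = 50.0
    nonwear_min_axes: int = 2
    # sleep heuristic on the z-angle
    sleep_median_min: int = 5
    sleep_threshold_mult: float = 15.0
    sleep_percentile: float = 10.0
    sleep_min_block_min: int = 30
    sleep_merge_gap_min: int = 60
    # ENMO intensity cut-points
    cut_sb_mg: float = 50.0  # <= sb
    cut_mvpa_mg: float = 200.0  # >= mvpa
    # validity rules
    valid_day_wear_h: float = 16.0
    min_valid_days: int = 4
    max_calib_error_mg: float = 10.0
    # auto-calibration
    calib_window_s: int = 10
    calib_sd_mg: float = 13.0
    calib_min_windows: int = 10
    # school segment (weekdays)
    school_start: str = "08:45"
    school_end: str = "15:15"

    @property
    def epochs_per_day(self) -> int:
        return 86400 // self.epoch_s


@dataclass
class TriaxialRecording:
    """One participant's raw tri-axial recording, in g, at a fixed rate."""

    participant: str
    start: pd.Timestamp
    sample_rate_hz: float
    data: np.ndarray  # (n, 3) float, axes x, y, z

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise ValueError("data must be (n, 3)")
        if np.nanmax(np.abs(self.data)) > 8.0 + 1e-9:
            raise ValueError("samples exceed the +/-8 g dynamic range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def timestamps(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(np.arange(self.n_samples) / self.sample_rate_hz, unit="s")
        return pd.DatetimeIndex(self.start + offsets)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.data, columns=["x_g", "y_g", "z_g"])
        df.insert(0, "timestamp_iso8601", self.timestamps().strftime("%Y-%m-%dT%H:%M:%S.%f"))
        df.to_csv(path, index=False, float_format="%.5f")

    @classmethod
    def from_csv(cls, path, participant: str = "") -> "TriaxialRecording":
        df = pd.read_csv(path)
        ts = pd.to_datetime(df["timestamp_iso8601"])
        if len(ts) < 2:
            raise ValueError("recording too short to infer sample rate")
        dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
        return cls(
            participant=participant or str(path),
            start=ts.iloc[0],
            sample_rate_hz=round(1.0 / dt, 6),
            data=df[["x_g", "y_g", "z_g"]].to_numpy(),
        )


@dataclass
class CalibrationResult:
    offset_g: np.ndarray  # per-axis additive offset, g
    gain: np.ndarray  # per-axis multiplicative gain
    error_mg: float  # mean | ||v|| - 1 | over stationary windows, after correction
    n_windows: int
    identity_fallback: bool = False  # too few stationary windows -> no correction


@dataclass
class SleepWindow:
    night: int
    onset: pd.Timestamp | None
    offset: pd.Timestamp | None
    valid: bool = True
    capped: bool = False  # degenerate night: still block spanned the search span

    @property
    def duration_min(self) -> float:
        if self.onset is None or self.offset is None:
            return 0.0
        return (self.offset - self.onset).total_seconds() / 60.0


# ---------------------------------------------------------------------------
# calibration


def _stationary_window_means(rec: TriaxialRecording, config: AccelConfig) -> np.ndarray:
    m = int(round(config.calib_window_s * rec.sample_rate_hz))
    n = (rec.n_samples // m) * m
    blocks = rec.data[:n].reshape(-1, m, 3)
    sd = blocks.std(axis=1)
    still = (sd < config.calib_sd_mg / 1000.0).all(axis=1)
    return blocks[still].mean(axis=1)


def autocalibrate(
    rec: TriaxialRecording, config: AccelConfig | None = None
) -> tuple[TriaxialRecording, CalibrationResult]:
    """Estimate per-axis offset and gain so stationary vectors have norm 1 g.

    Stationary 10-s windows (all-axis SD below the stillness threshold) are
    collected and a least-squares fit drives their calibrated norms toward
    1 g.  With fewer than ``calib_min_windows`` stationary windows the
    recording is returned unchanged with an identity calibration and a
    fallback flag (sphere fitting is ill-posed without orientation
    diversity).
    """
    config = config or AccelConfig()
    if rec.duration_s < 12 * 3600:
        raise ValueError("auto-calibration needs at least 12 h of recording")
    M = _stationary_window_means(rec, config)
    if M.shape[0] < config.calib_min_windows:
        res = CalibrationResult(np.zeros(3), np.ones(3), float("nan"), M.shape[0], True)
        return rec, res

    def residuals(theta):
        o, g = theta[:3], theta[3:]
        return np.linalg.norm(M * g + o, axis=1) - 1.0

    sol = least_squares(residuals, x0=np.array([0, 0, 0, 1, 1, 1.0]), method="lm")
    offset, gain = sol.x[:3], sol.x[3:]
    err = float(np.mean(np.abs(np.linalg.norm(M * gain + offset, axis=1) - 1.0))) * 1000
    calibrated = replace(rec, data=np.clip(rec.data * gain + offset, -8.0, 8.0))
    return calibrated, CalibrationResult(offset, gain, err, M.shape[0], False)


# ---------------------------------------------------------------------------
# epoching


def _epoch_index(rec: TriaxialRecording, config: AccelConfig, n_epochs: int) -> pd.DatetimeIndex:
    return rec.start + pd.Timedelta(seconds=config.epoch_s) * np.arange(n_epochs)


def epoch_enmo(rec: TriaxialRecording, config: AccelConfig | None = None) -> pd.DataFrame:
    """Per-epoch mean ENMO in mg (negatives truncated per sample)."""
    config = config or AccelConfig()
    m = int(round(config.epoch_s * rec.sample_rate_hz))
    n = (rec.n_samples // m) * m
    norm = np.linalg.norm(rec.data[:n].reshape(-1, m, 3), axis=2)
    enmo = np.maximum(norm - 1.0, 0.0).mean(axis=1) * 1000.0
    idx = _epoch_index(rec, config, len(enmo))
    return pd.DataFrame({"enmo_mg": enmo}, index=idx)


def _epoch_zangle(rec: TriaxialRecording, config: AccelConfig) -> pd.Series:
    """Per-epoch mean z-angle, degrees: atan(z / sqrt(x^2 + y^2))."""
    m = int(round(config.epoch_s * rec.sample_rate_hz))
    n = (rec.n_samples // m) * m
    d = rec.data[:n]
    ang = np.degrees(np.arctan2(d[:, 2], np.hypot(d[:, 0], d[:, 1])))
    ang = ang.reshape(-1, m).mean(axis=1)
    return pd.Series(ang, index=_epoch_index(rec, config, len(ang)), name="zangle_deg")


# ---------------------------------------------------------------------------
# non-wear


def detect_nonwear(rec: TriaxialRecording, config: AccelConfig | None = None) -> pd.Series:
    """Boolean wear mask on the epoch grid (True = worn).

    For every 60-min window advanced in 15-min steps, the window's central
    15-min block is flagged off-body when at least 2 of 3 axes have SD below
    13 mg, or at least 2 of 3 axes have a value range below 50 mg (strict
    inequalities).
    """
    config = config or AccelConfig()
    step_samp = int(round(config.nonwear_step_min * 60 * rec.sample_rate_hz))
    blocks_per_win = config.nonwear_window_min // config.nonwear_step_min
    n_blocks = rec.n_samples // step_samp
    n_epochs = (rec.n_samples // int(round(config.epoch_s * rec.sample_rate_hz)))
    worn = np.ones(n_epochs, dtype=bool)
    if n_blocks < blocks_per_win:
        return pd.Series(worn, index=_epoch_index(rec, config, n_epochs), name="worn")

    d = rec.data[: n_blocks * step_samp].reshape(n_blocks, step_samp, 3)
    bsum = d.sum(axis=1)
    bsq = (d**2).sum(axis=1)
    bmin = d.min(axis=1)
    bmax = d.max(axis=1)

    epochs_per_step = config.nonwear_step_min * 60 // config.epoch_s
    for w in range(n_blocks - blocks_per_win + 1):
        sl = slice(w, w + blocks_per_win)
        cnt = blocks_per_win * step_samp
        mean = bsum[sl].sum(axis=0) / cnt
        var = bsq[sl].sum(axis=0) / cnt - mean**2
        sd = np.sqrt(np.maximum(var, 0.0))
        rng_ = bmax[sl].max(axis=0) - bmin[sl].min(axis=0)
        low_sd = (sd < config.nonwear_sd_mg / 1000.0).sum()
        low_rng = (rng_ < config.nonwear_range_mg / 1000.0).sum()
        if low_sd >= config.nonwear_min_axes or low_rng >= config.nonwear_min_axes:
            # central 15 min of the 60-min window: [start + 22.5, start + 37.5] min
            c0 = w * config.nonwear_step_min + (config.nonwear_window_min - config.nonwear_step_min) / 2
            e0 = int(round(c0 * 60 / config.epoch_s))
            e1 = e0 + epochs_per_step
            worn[max(e0, 0) : min(e1, n_epochs)] = False
    return pd.Series(worn, index=_epoch_index(rec, config, n_epochs), name="worn")


def impute_nonwear(epochs: pd.DataFrame, config: AccelConfig | None = None) -> pd.DataFrame:
    """Replace non-worn ENMO with the mean of worn epochs at the same clock
    time on the other recorded days.

    ``epochs`` must carry ``enmo_mg`` and boolean ``worn`` columns on the 5-s
    grid.  A clock slot never worn on any day falls back to the participant's
    overall worn mean (with a warning).  Returns a copy with ``enmo_mg``
    updated and an ``imputed`` flag column.
    """
    config = config or AccelConfig()
    out = epochs.copy()
    out["imputed"] = ~out["worn"].to_numpy()
    if out["worn"].all():
        return out
    if not out["worn"].any():
        raise ValueError("recording contains no worn epochs to impute from")
    midnight = out.index.normalize()
    slot = ((out.index - midnight).total_seconds() // config.epoch_s).astype(int)
    enmo = out["enmo_mg"].to_numpy()
    worn = out["worn"].to_numpy()
    slot_sum = np.bincount(slot[worn], weights=enmo[worn], minlength=config.epochs_per_day)
    slot_cnt = np.bincount(slot[worn], minlength=config.epochs_per_day)
    overall = enmo[worn].mean()
    with np.errstate(invalid="ignore"):
        slot_mean = slot_sum / slot_cnt
    never_worn = slot_cnt == 0
    if never_worn[np.unique(slot[~worn])].any():
        warnings.warn("some clock slots are worn on no day; using overall worn mean")
    slot_mean[never_worn] = overall
    filled = enmo.copy()
    filled[~worn] = slot_mean[slot[~worn]]
    out["enmo_mg"] = filled
    return out


# ---------------------------------------------------------------------------
# sleep


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def detect_sleep_windows(
    rec: TriaxialRecording,
    config: AccelConfig | None = None,
    worn: pd.Series | None = None,
) -> list[SleepWindow]:
    """Nightly sleep windows from the distribution of change in the z-angle.

    Per noon-to-noon search window: absolute successive differences of the
    per-epoch (5-s) z-angle are smoothed with a centred 5-min rolling median;
    candidate still blocks are runs where the smoothed change stays below
    (10th percentile of the night's smoothed changes x 15); blocks shorter
    than 30 min are dropped, gaps shorter than 60 min merged, and the longest
    merged block is that night's sleep window.  The first and last windows of
    a recording are the partial spans before the first / after the last noon.

    A still block spanning (almost) the whole search span means the night
    carried no angle dynamics to calibrate the threshold on -- degenerate
    input or a sleep-free span -- and is returned capped and invalid.

    When a wear mask is supplied, off-body epochs are excluded from still
    candidacy: sleep is only sought in worn time (off-body periods are
    motionless and would otherwise masquerade as sleep; they are handled by
    imputation instead).
    """
    config = config or AccelConfig()
    za = _epoch_zangle(rec, config)
    start, end = za.index[0], za.index[-1]
    noons = pd.date_range(
        (start - pd.Timedelta(hours=12)).normalize() + pd.Timedelta(hours=12),
        end,
        freq="1D",
    )
    noons = noons[(noons > start) & (noons < end)]
    bounds = [start] + list(noons) + [end + pd.Timedelta(seconds=config.epoch_s)]

    med_w = config.sleep_median_min * 60 // config.epoch_s
    min_block = config.sleep_min_block_min * 60 // config.epoch_s
    merge_gap = config.sleep_merge_gap_min * 60 // config.epoch_s

    windows: list[SleepWindow] = []
    for night, (t0, t1) in enumerate(zip(bounds[:-1], bounds[1:])):
        seg = za[(za.index >= t0) & (za.index < t1)]
        if len(seg) < 2 * min_block:
            windows.append(SleepWindow(night, None, None, valid=False))
            continue
        smoothed = (
            seg.diff().abs().iloc[1:].rolling(med_w, center=True, min_periods=1).median()
        )
        thr = config.sleep_threshold_mult * np.percentile(smoothed, config.sleep_percentile)
        still = (smoothed < thr).to_numpy() if thr > 0 else (smoothed <= 0).to_numpy()
        if worn is not None:
            w = worn.reindex(smoothed.index, fill_value=True).to_numpy(dtype=bool)
            still &= w
        runs = [(a, b) for a, b in _runs(still) if b - a >= min_block]
        if not runs:
            windows.append(SleepWindow(night, None, None, valid=False))
            continue
        merged = [runs[0]]
        for a, b in runs[1:]:
            if a - merged[-1][1] < merge_gap:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        a, b = max(merged, key=lambda r: r[1] - r[0])
        idx = smoothed.index
        capped = (b - a) >= 0.9 * len(smoothed)
        windows.append(
            SleepWindow(
                night,
                onset=idx[a],
                offset=idx[b - 1] + pd.Timedelta(seconds=config.epoch_s),
                valid=not capped,
                capped=capped,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# classification and daily summaries


def classify_epochs(
    epochs: pd.DataFrame,
    windows: list[SleepWindow],
    config: AccelConfig | None = None,
) -> pd.DataFrame:
    """Label every epoch sleep / sb / lpa / mvpa.

    Epochs inside a detected sleep window are sleep regardless of intensity;
    outside, ENMO <= 50 mg is SB, 50-200 mg exclusive is LPA and >= 200 mg is
    MVPA.
    """
    config = config or AccelConfig()
    out = epochs.copy()
    enmo = out["enmo_mg"].to_numpy()
    label = np.where(
        enmo <= config.cut_sb_mg, "sb", np.where(enmo < config.cut_mvpa_mg, "lpa", "mvpa")
    ).astype(object)
    in_sleep = np.zeros(len(out), dtype=bool)
    for w in windows:
        if w.valid and w.onset is not None:
            in_sleep |= (out.index >= w.onset) & (out.index < w.offset)
    label[in_sleep] = "sleep"
    out["label"] = label
    return out


def summarize_days(labelled: pd.DataFrame, config: AccelConfig | None = None) -> pd.DataFrame:
    """Midnight-to-midnight day records; partial first/last days are dropped.

    Returns one row per complete calendar day with minutes per behaviour
    (summing to 1440), pre-imputation wear hours, weekday/weekend type, and
    the behaviour minutes inside the school segment (08:45-15:15, weekdays).
    """
    config = config or AccelConfig()
    df = labelled.copy()
    df["date"] = df.index.normalize()
    epm = 60 // config.epoch_s  # epochs per minute
    t0 = pd.Timedelta(config.school_start + ":00")
    t1 = pd.Timedelta(config.school_end + ":00")
    tod = df.index - df["date"]
    df["in_school"] = (tod >= t0) & (tod < t1)

    rows = []
    for date, day in df.groupby("date"):
        if len(day) != config.epochs_per_day:
            continue  # partial day
        counts = day["label"].value_counts()
        weekday = date.dayofweek < 5
        row = {
            "date": date,
            "day_type": "weekday" if weekday else "weekend",
            "wear_h": day["worn"].sum() / (epm * 60) if "worn" in day else 24.0,
        }
        for lab in LABELS:
            row[f"{lab}_min"] = counts.get(lab, 0) / epm
        if weekday:
            sc = day.loc[day["in_school"], "label"].value_counts()
            for lab in LABELS:
                row[f"school_{lab}_min"] = sc.get(lab, 0) / epm
        else:
            for lab in LABELS:
                row[f"school_{lab}_min"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def filter_valid(
    days: pd.DataFrame,
    calib: CalibrationResult | None = None,
    config: AccelConfig | None = None,
) -> tuple[bool, pd.DataFrame]:
    """Apply wear-time and calibration inclusion rules.

    A day is valid iff pre-imputation wear is at least 16 h.  The participant
    is retained iff at least 4 valid days remain and the post-calibration
    error does not exceed 10 mg (strictly greater excludes).
    """
    config = config or AccelConfig()
    if days.empty:
        return False, days
    valid = days[days["wear_h"] >= config.valid_day_wear_h].reset_index(drop=True)
    included = len(valid) >= config.min_valid_days
    if calib is not None and np.isfinite(calib.error_mg):
        included = included and calib.error_mg <= config.max_calib_error_mg
    return included, valid


def derive_compositions(
    days: pd.DataFrame, segment: str = "total", config: AccelConfig | None = None
) -> pd.Series | None:
    """Mean daily behaviour minutes across the qualifying valid days.

    ``total`` / ``weekday`` / ``weekend`` give 4-part compositions summing to
    1440; ``school`` gives the 3-part waking composition (sb, lpa, mvpa)
    closed to the 390-min school day.  Returns None when no day qualifies.
    """
    config = config or AccelConfig()
    if segment == "total":
        sub = days
    elif segment in ("weekday", "weekend"):
        sub = days[days["day_type"] == segment]
    elif segment == "school":
        sub = days[(days["day_type"] == "weekday") & days["school_sb_min"].notna()]
    else:
        raise ValueError(f"unknown segment {segment!r}")
    if sub.empty:
        return None
    if segment == "school":
        vals = sub[["school_sb_min", "school_lpa_min", "school_mvpa_min"]].mean()
        vals.index = ["sb", "lpa", "mvpa"]
        total = vals.sum()
        if total <= 0:
            return None
        return vals * (390.0 / total)
    vals = sub[[f"{lab}_min" for lab in LABELS]].mean()
    vals.index = list(LABELS)
    return vals


def process_recording(
    rec: TriaxialRecording,
    config: AccelConfig | None = None,
    calibrate: bool = True,
) -> dict:
    """Run the full chain on one recording; returns all intermediates.

    Keys: ``calibration``, ``epochs`` (enmo/worn/imputed/label), ``windows``,
    ``days``, ``valid_days``, ``included``, ``compositions`` (dict by
    segment, missing segments omitted).
    """
    config = config or AccelConfig()
    calib = None
    if calibrate:
        rec, calib = autocalibrate(rec, config)
    epochs = epoch_enmo(rec, config)
    worn = detect_nonwear(rec, config)
    epochs["worn"] = worn.reindex(epochs.index, fill_value=True)
    epochs = impute_nonwear(epochs, config)
    windows = detect_sleep_windows(rec, config, worn=worn)
    epochs = classify_epochs(epochs, windows, config)
    days = summarize_days(epochs, config)
    included, valid_days = filter_valid(days, calib, config)
    comps = {}
    if included:
        for seg in ("total", "weekday", "weekend", "school"):
            c = derive_compositions(valid_days, seg, config)
            if c is not None:
                comps[seg] = c
    return {
        "participant": rec.participant,
        "calibration": calib,
        "epochs": epochs,
        "windows": windows,
        "days": days,
        "valid_days": valid_days,
        "included": included,
        "compositions": comps,
    }
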