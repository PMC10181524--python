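"""Daily feature extraction from raw two-device wearable streams.

One row per patient-day: vital-sign summaries (mean/variance of heart and
respiration rate), resting heart rate, circadian day-night and peak-nadir
heart-rate metrics, time- and frequency-domain heart-rate variability from
inter-beat intervals, heart-rate recovery after exercise bouts (HRR-1/-2
and HRR-time), heart rate conditioned on activity context, activity
summaries (steps, walking, activity counts, sedentary/upright hours,
energy expenditure) and day-to-day delta features.

Respiration-rate features come from the chest patch (more reliable at the
ribcage); heart-rate-derived features come from the wrist band (longer
coverage).  A feature is missing (NaN) when its source channel lacks the
required samples that day; heart-rate-recovery features are missing on
days without a qualifying exercise bout ("inactive" days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal, stats

from .streams import SensorStreams, EPOCH

__all__ = [
    "FeatureConfig",
    "ExerciseBout",
    "FEATURE_NAMES",
    "daily_vital_stats",
    "resting_heart_rate",
    "circadian_day_night",
    "circadian_peak_nadir",
    "hrv_time_domain",
    "hrv_frequency_domain",
    "detect_exercise_bouts",
    "heart_rate_recovery",
    "hr_by_context",
    "activity_daily",
    "extract_daily_features",
    "delta_features",
    "pearson_screen",
]

FEATURE_NAMES = [
    "hr_mean", "hr_var", "rr_mean", "rr_var", "rhr",
    "circ_day_night", "circ_peak_nadir",
    "sdnn", "rmssd", "pnn50", "vlf", "lf", "hf", "lf_hf_ratio",
    "hrr1", "hrr2", "hrr_time",
    "hr_walking", "hr_upright", "hr_sedentary",
    "hr_active", "hr_inactive", "hr_active_minus_inactive",
    "hr_high_actcount", "hr_low_actcount",
    "hr_high_actlevel", "hr_low_actlevel",
    "steps", "walkspeed", "hours_walking", "actcount_mean",
    "pct_active", "sedentary_hours", "aee",
    "upright_hours", "actlevel_mean",
]


@dataclass
class FeatureConfig:
    day_window: tuple = (8, 22)          # hours, daytime HR window
    night_window: tuple = (0, 6)         # hours, nighttime HR window
    vlf_band: tuple = (0.0033, 0.04)     # Hz
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)
    welch_fs: float = 4.0                # Hz, IBI resampling rate
    welch_segment_s: float = 300.0       # 5-min Welch segments, 50% overlap
    min_coverage: float = 0.3            # fraction of a day's expected samples
    min_ibi_intervals: int = 10
    peak_nadir_min_hours: int = 6
    bout_merge_gap_s: float = 300.0      # refractory merge of adjacent bouts
    hrr_post_window_s: float = 300.0
    actcount_threshold: float = 2000.0   # high vs low wrist activity counts
    actlevel_threshold: float = 3.0      # chest level <= 3 is 'in rest'
    hrmax_fraction: float = 0.7          # of 220 - age, bout qualification
    rhr_decile: float = 0.1
    hrr_abnormal_bpm: float = 12.0       # clinical HRR-1 flag


@dataclass
class ExerciseBout:
    """One heart-rate elevation episode qualifying as physical exercise."""

    start_s: float        # seconds from midnight
    peak_time_s: float
    peak_hr: float
    post_peak: pd.Series  # HR samples from the peak onward (seconds index)


def _day_values(series: pd.Series, day: int) -> pd.Series:
    """Samples within post-op day `day`, indexed by seconds from midnight."""
    if series is None or series.empty:
        return pd.Series(dtype=float)
    start = EPOCH + pd.Timedelta(days=day)
    sub = series[start:start + pd.Timedelta(days=1) - pd.Timedelta(nanoseconds=1)]
    sec = (sub.index - start).total_seconds()
    return pd.Series(sub.to_numpy(dtype=float), index=np.asarray(sec))


def _coverage(day_series: pd.Series) -> float:
    n = len(day_series)
    if n < 2:
        return 0.0
    dt = float(np.median(np.diff(day_series.index.to_numpy(dtype=float))))
    return min(1.0, n * dt / 86400.0)


def daily_vital_stats(stream: pd.Series, day: int,
                      config: FeatureConfig | None = None) -> tuple:
    """Sample mean and population variance of a vital sign over one day."""
    config = config or FeatureConfig()
    vals = _day_values(stream, day)
    if vals.empty or _coverage(vals) < config.min_coverage:
        return (np.nan, np.nan)
    arr = vals.to_numpy()
    return (float(arr.mean()), float(arr.var()))


def resting_heart_rate(hr: pd.Series, activity: pd.Series, day: int,
                       config: FeatureConfig | None = None,
                       activity_threshold: float | None = None) -> float:
    """Mean of the lowest decile of HR samples during inactive periods.

    Inactivity is activity level <= the chest threshold (default 3) or, if
    an activity-count series is supplied, counts below the count threshold.
    """
    config = config or FeatureConfig()
    if activity_threshold is None:
        activity_threshold = config.actlevel_threshold
    hr_day = _day_values(hr, day)
    act_day = _day_values(activity, day)
    if hr_day.empty or act_day.empty:
        return np.nan
    labels = np.interp(hr_day.index.to_numpy(), act_day.index.to_numpy(),
                       act_day.to_numpy())
    inactive = hr_day.to_numpy()[labels <= activity_threshold]
    if inactive.size == 0:
        return np.nan
    k = max(1, int(np.floor(config.rhr_decile * inactive.size)))
    return float(np.sort(inactive)[:k].mean())


def _window_mean(day_series: pd.Series, window_h: tuple) -> float:
    h = day_series.index.to_numpy() / 3600.0
    sel = day_series.to_numpy()[(h >= window_h[0]) & (h < window_h[1])]
    return float(sel.mean()) if sel.size else np.nan


def circadian_day_night(hr: pd.Series, day: int,
                        config: FeatureConfig | None = None) -> float:
    """Daytime minus nighttime mean HR; positive when the circadian rhythm
    is intact (higher HR awake than asleep)."""
    config = config or FeatureConfig()
    vals = _day_values(hr, day)
    if vals.empty:
        return np.nan
    d = _window_mean(vals, config.day_window)
    n = _window_mean(vals, config.night_window)
    if np.isnan(d) or np.isnan(n):
        return np.nan
    return d - n


def circadian_peak_nadir(hr: pd.Series, day: int,
                         config: FeatureConfig | None = None) -> float:
    """Range of hourly mean HR within the day (peak minus nadir)."""
    config = config or FeatureConfig()
    vals = _day_values(hr, day)
    if vals.empty:
        return np.nan
    hours = (vals.index.to_numpy() // 3600).astype(int)
    means = pd.Series(vals.to_numpy()).groupby(hours).mean()
    if len(means) < config.peak_nadir_min_hours:
        return np.nan
    return float(means.max() - means.min())


def hrv_time_domain(ibi: pd.Series, day: int,
                    config: FeatureConfig | None = None,
                    min_intervals: int | None = None) -> tuple:
    """SDNN, RMSSD and pNN50 over the day's inter-beat intervals (ms).

    SDNN uses the population standard deviation; pNN50 is the percentage
    of successive-interval differences exceeding 50 ms.
    """
    config = config or FeatureConfig()
    if min_intervals is None:
        min_intervals = config.min_ibi_intervals
    vals = _day_values(ibi, day).to_numpy()
    if vals.size < max(2, min_intervals):
        return (np.nan, np.nan, np.nan)
    sdnn = float(vals.std())
    diffs = np.diff(vals)
    rmssd = float(np.sqrt(np.mean(diffs ** 2)))
    pnn50 = float(100.0 * np.mean(np.abs(diffs) > 50.0))
    return (sdnn, rmssd, pnn50)


def hrv_frequency_domain(ibi: pd.Series, day: int,
                         config: FeatureConfig | None = None) -> tuple:
    """VLF/LF/HF band powers and LF/HF ratio by Welch's method.

    The unevenly sampled IBI series is cubic-interpolated onto an even
    grid (default 4 Hz), the averaged periodogram is computed over 5-min
    segments with 50% overlap, and band powers are integrated over the
    standard HRV bands.
    """
    config = config or FeatureConfig()
    vals = _day_values(ibi, day)
    span = vals.index.max() - vals.index.min() if len(vals) else 0.0
    if len(vals) < 4 or span < 2 * config.welch_segment_s:
        return (np.nan, np.nan, np.nan, np.nan)
    t = vals.index.to_numpy()
    grid = np.arange(t[0], t[-1], 1.0 / config.welch_fs)
    interp = interpolate.interp1d(t, vals.to_numpy(), kind="cubic")
    x = interp(grid)
    nperseg = int(config.welch_fs * config.welch_segment_s)
    freqs, psd = signal.welch(x - x.mean(), fs=config.welch_fs,
                              nperseg=min(nperseg, len(x)))

    def band_power(band):
        sel = (freqs >= band[0]) & (freqs < band[1])
        return float(np.trapezoid(psd[sel], freqs[sel])) if sel.sum() > 1 else 0.0

    vlf = band_power(config.vlf_band)
    lf = band_power(config.lf_band)
    hf = band_power(config.hf_band)
    # hf of a (numerically) constant series is floating-point dust, not power
    ratio = lf / hf if hf > 1e-12 else np.nan
    return (vlf, lf, hf, ratio)


def detect_exercise_bouts(hr: pd.Series, age: float, day: int,
                          config: FeatureConfig | None = None) -> list:
    """Contiguous episodes with HR at or above 70% of (220 - age).

    Episodes closer than the refractory merge gap are fused.  Each bout
    records the peak and the post-peak HR trace (for recovery metrics).
    """
    config = config or FeatureConfig()
    vals = _day_values(hr, day)
    if vals.empty:
        return []
    threshold = config.hrmax_fraction * (220.0 - age)
    t = vals.index.to_numpy()
    y = vals.to_numpy()
    above = y >= threshold
    if not above.any():
        return []
    # contiguous runs of qualifying samples
    runs = []
    idx = np.flatnonzero(above)
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    # refractory merge on time distance
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if t[a] - t[merged[-1][1]] <= config.bout_merge_gap_s:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    bouts = []
    for a, b in merged:
        seg = y[a:b + 1]
        peak_off = int(np.argmax(seg))
        peak_i = a + peak_off
        post_sel = (t >= t[peak_i]) & (t <= t[peak_i] + config.hrr_post_window_s)
        post = pd.Series(y[post_sel], index=t[post_sel] - t[peak_i])
        bouts.append(ExerciseBout(start_s=float(t[a]), peak_time_s=float(t[peak_i]),
                                  peak_hr=float(y[peak_i]), post_peak=post))
    return bouts


def heart_rate_recovery(bouts: list, hr: pd.Series = None, day: int = 0,
                        config: FeatureConfig | None = None) -> tuple:
    """Daily HRR-1, HRR-2 (bpm) and HRR-time (s), averaged over bouts.

    HRR-n is the drop from the bout peak to the HR n minutes later
    (linearly interpolated between samples); HRR-time is the first time at
    which HR has fallen 10 bpm below the peak.  A bout whose post-peak
    trace does not reach the required horizon is excluded from that
    metric; all three are missing on days without bouts.
    """
    config = config or FeatureConfig()
    h1, h2, ht = [], [], []
    for bout in bouts:
        tau = bout.post_peak.index.to_numpy(dtype=float)
        y = bout.post_peak.to_numpy()
        if tau.size < 2:
            continue
        for horizon, acc in ((60.0, h1), (120.0, h2)):
            if tau[-1] >= horizon:
                acc.append(bout.peak_hr - float(np.interp(horizon, tau, y)))
        below = np.flatnonzero(y <= bout.peak_hr - 10.0)
        if below.size:
            ht.append(float(tau[below[0]]))
    return (float(np.mean(h1)) if h1 else np.nan,
            float(np.mean(h2)) if h2 else np.nan,
            float(np.mean(ht)) if ht else np.nan)


def _context_mean(hr_day: pd.Series, mask: np.ndarray) -> float:
    sel = hr_day.to_numpy()[mask]
    return float(sel.mean()) if sel.size else np.nan


def hr_by_context(hr: pd.Series, context_labels: dict, day: int,
                  config: FeatureConfig | None = None) -> dict:
    """Mean HR within activity contexts and the active-inactive contrast.

    ``context_labels`` may provide 'walking' (0/1), 'upright' (0/1),
    'sedentary' (0/1), 'active' (0/1), 'actcount' and 'actlevel' series.
    """
    config = config or FeatureConfig()
    hr_day = _day_values(hr, day)
    out = {k: np.nan for k in (
        "hr_walking", "hr_upright", "hr_sedentary", "hr_active", "hr_inactive",
        "hr_active_minus_inactive", "hr_high_actcount", "hr_low_actcount",
        "hr_high_actlevel", "hr_low_actlevel")}
    if hr_day.empty:
        return out

    def aligned(name):
        series = context_labels.get(name)
        if series is None:
            return None
        lab = _day_values(series, day)
        if lab.empty:
            return None
        return np.interp(hr_day.index.to_numpy(), lab.index.to_numpy(),
                         lab.to_numpy())

    walking = aligned("walking")
    if walking is not None:
        out["hr_walking"] = _context_mean(hr_day, walking > 0.5)
    upright = aligned("upright")
    if upright is not None:
        out["hr_upright"] = _context_mean(hr_day, upright > 0.5)
    sed = aligned("sedentary")
    if sed is not None:
        out["hr_sedentary"] = _context_mean(hr_day, sed > 0.5)
    active = aligned("active")
    if active is not None:
        out["hr_active"] = _context_mean(hr_day, active > 0.5)
        out["hr_inactive"] = _context_mean(hr_day, active <= 0.5)
        if not (np.isnan(out["hr_active"]) or np.isnan(out["hr_inactive"])):
            out["hr_active_minus_inactive"] = out["hr_active"] - out["hr_inactive"]
    actcount = aligned("actcount")
    if actcount is not None:
        out["hr_high_actcount"] = _context_mean(hr_day, actcount > config.actcount_threshold)
        out["hr_low_actcount"] = _context_mean(hr_day, actcount <= config.actcount_threshold)
    actlevel = aligned("actlevel")
    if actlevel is not None:
        out["hr_high_actlevel"] = _context_mean(hr_day, actlevel > config.actlevel_threshold)
        out["hr_low_actlevel"] = _context_mean(hr_day, actlevel <= config.actlevel_threshold)
    return out


def activity_daily(streams: SensorStreams, day: int,
                   config: FeatureConfig | None = None) -> dict:
    """Daily activity summaries from both devices.

    Steps are the sum of the day's increments; fraction-based quantities
    (percent active, sedentary and upright hours) scale the observed
    fraction to 24 h so charging gaps do not deflate them.
    """
    config = config or FeatureConfig()
    out = {}
    steps = _day_values(streams.wrist_steps, day)
    out["steps"] = float(steps.sum()) if not steps.empty else np.nan
    speed = _day_values(streams.wrist_walkspeed, day)
    if speed.empty:
        out["walkspeed"] = np.nan
        out["hours_walking"] = np.nan
    else:
        moving = speed.to_numpy()[speed.to_numpy() > 0]
        out["walkspeed"] = float(moving.mean()) if moving.size else np.nan
        dt = float(np.median(np.diff(speed.index.to_numpy()))) if len(speed) > 1 else 0.0
        out["hours_walking"] = float((speed.to_numpy() > 0).sum() * dt / 3600.0)
    act = _day_values(streams.wrist_actcount, day)
    out["actcount_mean"] = float(act.mean()) if not act.empty else np.nan
    pct = _day_values(streams.wrist_pct_active, day)
    out["pct_active"] = float(100.0 * pct.mean()) if not pct.empty else np.nan
    sed = _day_values(streams.wrist_sedentary, day)
    out["sedentary_hours"] = float(24.0 * sed.mean()) if not sed.empty else np.nan
    aee = _day_values(streams.wrist_aee, day)
    if aee.empty:
        out["aee"] = np.nan
    else:
        dt = float(np.median(np.diff(aee.index.to_numpy()))) if len(aee) > 1 else 0.0
        out["aee"] = float(aee.sum() * dt / 3600.0)  # rate (kcal/h) -> kcal
    posture = _day_values(streams.chest_posture, day)
    out["upright_hours"] = float(24.0 * posture.mean()) if not posture.empty else np.nan
    level = _day_values(streams.chest_actlevel, day)
    out["actlevel_mean"] = float(level.mean()) if not level.empty else np.nan
    return out


def extract_daily_features(streams: SensorStreams, age: float, n_days: int,
                           config: FeatureConfig | None = None,
                           patient_id: str = "") -> pd.DataFrame:
    """Full daily feature frame for one patient (one row per post-op day)."""
    config = config or FeatureConfig()
    context = {
        "walking": streams.wrist_walkspeed,
        "upright": streams.chest_posture,
        "sedentary": streams.wrist_sedentary,
        "active": streams.wrist_pct_active,
        "actcount": streams.wrist_actcount,
        "actlevel": streams.chest_actlevel,
    }
    rows = []
    for day in range(n_days):
        row = {"patient_id": patient_id, "day": day}
        row["hr_mean"], row["hr_var"] = daily_vital_stats(streams.wrist_hr, day, config)
        row["rr_mean"], row["rr_var"] = daily_vital_stats(streams.chest_rr, day, config)
        chest_act = _day_values(streams.chest_actlevel, day)
        if not chest_act.empty:
            row["rhr"] = resting_heart_rate(streams.wrist_hr, streams.chest_actlevel,
                                            day, config)
        else:
            row["rhr"] = resting_heart_rate(streams.wrist_hr, streams.wrist_actcount,
                                            day, config,
                                            activity_threshold=config.actcount_threshold)
        row["circ_day_night"] = circadian_day_night(streams.wrist_hr, day, config)
        row["circ_peak_nadir"] = circadian_peak_nadir(streams.wrist_hr, day, config)
        row["sdnn"], row["rmssd"], row["pnn50"] = hrv_time_domain(
            streams.wrist_ibi, day, config)
        row["vlf"], row["lf"], row["hf"], row["lf_hf_ratio"] = hrv_frequency_domain(
            streams.wrist_ibi, day, config)
        bouts = detect_exercise_bouts(streams.wrist_hr, age, day, config)
        row["hrr1"], row["hrr2"], row["hrr_time"] = heart_rate_recovery(
            bouts, streams.wrist_hr, day, config)
        row.update(hr_by_context(streams.wrist_hr, context, day, config))
        row.update(activity_daily(streams, day, config))
        rows.append(row)
    return pd.DataFrame(rows, columns=["patient_id", "day"] + FEATURE_NAMES)


def delta_features(frames: pd.DataFrame) -> pd.DataFrame:
    """Append delta_<name> = value(day) - value(day - 1) per patient.

    A delta is missing when either operand is missing or when day - 1 has
    no row (in particular the first day of each patient).
    """
    frames = frames.sort_values(["patient_id", "day"]).reset_index(drop=True)
    out = frames.copy()
    for name in FEATURE_NAMES:
        deltas = np.full(len(frames), np.nan)
        for _, g in frames.groupby("patient_id", sort=False):
            by_day = g.set_index("day")[name]
            prev = by_day.reindex(by_day.index - 1)
            deltas[g.index] = by_day.to_numpy() - prev.to_numpy()
        out[f"delta_{name}"] = deltas
    return out


def pearson_screen(frames: pd.DataFrame, profiles: dict) -> pd.Series:
    """Pearson correlation of each feature with the reference score over
    all patient-days where both are present; NaN below 3 pairs or at zero
    variance."""
    target = np.array([
        profiles[pid].scores[int(d)] if pid in profiles
        and int(d) <= profiles[pid].horizon else np.nan
        for pid, d in zip(frames["patient_id"], frames["day"])
    ])
    cols = [c for c in frames.columns if c not in ("patient_id", "day")]
    out = {}
    for name in cols:
        x = frames[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(target))
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(target[ok]) == 0:
            out[name] = np.nan
        else:
            out[name] = float(stats.pearsonr(x[ok], target[ok])[0])
    return pd.Series(out, name="pearson_r")
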