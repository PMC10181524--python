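"""Two-device wearable stream synthesis driven by a latent recovery state.

A chest patch stores heart rate (8-s cadence), respiration rate (1-s),
activity level (0-10) and posture for 14 days; a wrist band stores heart
rate, inter-beat intervals, steps, walking speed, activity counts,
active/sedentary classifications and active energy expenditure at 1-s
cadence for 21 days, with one charging gap per day.

Each day's signal parameters are linear functions of that day's latent
recovery score (the engineered reference profile) plus per-channel Gaussian
noise: higher scores mean more daily steps, more upright hours, a larger
day-night heart-rate difference, a faster heart-rate recovery after an
exercise bout and a lower resting heart rate.  Once the latent score
exceeds an activity-onset value the patient performs one exercise bout per
day (heart rate driven to ~72% of 220 - age, then exponential recovery),
so heart-rate-recovery features become computable; before that the days
are "inactive" and those features are missing downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cohort import GeneratorConfig, PatientRecord
from .reference import InputError, ReferenceProfile

__all__ = [
    "SensorStreams",
    "daily_signal_expectations",
    "generate_streams",
    "write_streams",
    "read_streams",
    "StreamParseError",
    "EPOCH",
]

EPOCH = pd.Timestamp("2000-01-01")  # surgery at midnight of post-op day 0

CHEST_CHANNELS = ("chest_hr", "chest_rr", "chest_actlevel", "chest_posture")
WRIST_CHANNELS = (
    "wrist_hr", "wrist_ibi", "wrist_steps", "wrist_walkspeed", "wrist_actcount",
    "wrist_pct_active", "wrist_sedentary", "wrist_aee",
)
ALL_CHANNELS = CHEST_CHANNELS + WRIST_CHANNELS

_DAY = 86400.0


@dataclass
class SensorStreams:
    """Raw two-device signals for one patient; each field is a float Series
    with a DatetimeIndex (posture and the activity classifications are 0/1)."""

    chest_hr: pd.Series
    chest_rr: pd.Series
    chest_actlevel: pd.Series
    chest_posture: pd.Series
    wrist_hr: pd.Series
    wrist_ibi: pd.Series
    wrist_steps: pd.Series
    wrist_walkspeed: pd.Series
    wrist_actcount: pd.Series
    wrist_pct_active: pd.Series
    wrist_sedentary: pd.Series
    wrist_aee: pd.Series

    def channels(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def __eq__(self, other) -> bool:
        if not isinstance(other, SensorStreams):
            return NotImplemented
        return all(
            getattr(self, f.name).equals(getattr(other, f.name))
            for f in fields(self)
        )


def daily_signal_expectations(score: float, config: GeneratorConfig) -> dict:
    """Expected (noise-free) daily summaries at a given latent score.

    Steps, upright hours, day-night circadian amplitude and HRR-1 are
    strictly increasing in the score; resting heart rate is decreasing.
    """
    s = score - 1.0
    return {
        "steps": config.steps_base + config.steps_gain * s,
        "upright_hours": max(0.0, config.upright_gain * s),
        "circ_amp": config.circ_base + config.circ_gain * s,
        "hrr1": config.hrr1_base + config.hrr1_gain * s,
        "rest_hr": config.rest_hr_base + config.rest_hr_gain * s,
        "active": score >= config.activity_onset,
    }


def _patient_stream_seed(config: GeneratorConfig, patient_id: str) -> list:
    return [config.seed, zlib.crc32(patient_id.encode()), 0x5EA]


def _hr_base(t: np.ndarray, rest: float, amp: float) -> np.ndarray:
    """Circadian baseline: night (00-06) at rest - amp/2, day (08-22) at
    rest + amp/2, linear transitions, so day-minus-night mean equals amp."""
    h = (t % _DAY) / 3600.0
    lo, hi = rest - amp / 2.0, rest + amp / 2.0
    out = np.full_like(t, hi, dtype=float)
    out[h < 6] = lo
    ramp_up = (h >= 6) & (h < 8)
    out[ramp_up] = lo + (hi - lo) * (h[ramp_up] - 6) / 2.0
    ramp_dn = h >= 22
    out[ramp_dn] = hi + (lo - hi) * (h[ramp_dn] - 22) / 2.0
    return out


class _DayPlan:
    """Deterministic within-day schedule derived from the day's parameters."""

    RAMP_S = 180.0       # exercise ramp-up length
    DECAY_S = 600.0      # post-peak window modelled explicitly
    UPRIGHT_START = 10 * 3600.0
    WALK_START = 11 * 3600.0
    BOUT_START = 14 * 3600.0

    def __init__(self, score, age, params, config: GeneratorConfig):
        self.rest = params["rest_hr"]
        self.amp = max(0.0, params["circ_amp"])
        self.steps = max(0.0, params["steps"])
        self.upright_h = float(np.clip(params["upright_hours"], 0.0, 12.0))
        self.active = score >= config.activity_onset
        self.walk_h = min(self.steps / config.steps_rate, 3.0)
        self.walk_elev = config.walk_elev
        self.walkspeed = 1.2 + 0.3 * (score - 1.0)
        self.peak = config.peak_frac * (220.0 - age)
        self.t_peak = self.BOUT_START + self.RAMP_S
        b = self.rest + self.amp / 2.0
        self.bout_base = b
        rise = max(self.peak - b, 1.0)
        hrr1 = float(np.clip(params["hrr1"], 0.5, 0.9 * rise))
        # time constant such that the drop 60 s after the peak equals hrr1
        self.decay_tau = -60.0 / np.log1p(-hrr1 / rise)

    def upright_mask(self, t):
        h = t % _DAY
        m = (h >= self.UPRIGHT_START) & (h < self.UPRIGHT_START + self.upright_h * 3600)
        if self.active:
            m |= (h >= self.BOUT_START) & (h < self.t_peak + self.DECAY_S)
        return m

    def walking_mask(self, t):
        h = t % _DAY
        return (h >= self.WALK_START) & (h < self.WALK_START + self.walk_h * 3600)

    def exercise_mask(self, t):
        if not self.active:
            return np.zeros_like(t, dtype=bool)
        h = t % _DAY
        return (h >= self.BOUT_START) & (h < self.t_peak + self.DECAY_S)

    def hr(self, t: np.ndarray) -> np.ndarray:
        out = _hr_base(t, self.rest, self.amp)
        out[self.walking_mask(t)] += self.walk_elev
        if self.active:
            h = t % _DAY
            ramp = (h >= self.BOUT_START) & (h < self.t_peak)
            out[ramp] = self.bout_base + (self.peak - self.bout_base) * (
                (h[ramp] - self.BOUT_START) / self.RAMP_S)
            decay = (h >= self.t_peak) & (h < self.t_peak + self.DECAY_S)
            out[decay] = self.bout_base + (self.peak - self.bout_base) * np.exp(
                -(h[decay] - self.t_peak) / self.decay_tau)
        return out


def generate_streams(patient: PatientRecord, profile: ReferenceProfile,
                     config: GeneratorConfig, seed=None) -> SensorStreams:
    """Synthesize both devices' streams for one patient.

    Reproducible: the random stream is derived from (config.seed,
    patient_id) unless an explicit seed is given.  Streams stop early if
    the profile is truncated (fatal event).
    """
    if profile.horizon < config.wrist_days:
        raise InputError(
            f"profile horizon {profile.horizon} does not cover the "
            f"{config.wrist_days}-day wear period")
    rng = np.random.default_rng(
        seed if seed is not None else _patient_stream_seed(config, patient.patient_id))
    ns = config.noise_scale
    parts = {ch: [] for ch in ALL_CHANNELS}
    times = {ch: [] for ch in ALL_CHANNELS}

    for day in range(config.wrist_days):
        score = profile.scores[day]
        if np.isnan(score):
            break
        exp = daily_signal_expectations(score, config)
        params = {
            "steps": exp["steps"] + ns * config.noise_steps * rng.standard_normal(),
            "upright_hours": exp["upright_hours"]
            + ns * config.noise_upright * rng.standard_normal(),
            "circ_amp": exp["circ_amp"] + ns * config.noise_circ * rng.standard_normal(),
            "hrr1": exp["hrr1"] + ns * config.noise_hrr * rng.standard_normal(),
            "rest_hr": exp["rest_hr"]
            + ns * config.rest_hr_daily_sd * rng.standard_normal(),
        }
        plan = _DayPlan(score, patient.age, params, config)
        day0 = day * _DAY

        # ---- chest device (first 14 days) ----
        if day < config.chest_days:
            t = day0 + np.arange(0.0, _DAY, config.chest_hr_dt)
            hr = plan.hr(t) + ns * config.noise_hr * rng.standard_normal(t.size)
            parts["chest_hr"].append(np.clip(hr, 25.0, 220.0)); times["chest_hr"].append(t)

            t = day0 + np.arange(0.0, _DAY, config.chest_rr_dt)
            rr = config.rr_base + ns * config.noise_rr * rng.standard_normal(t.size)
            parts["chest_rr"].append(np.clip(rr, 4.0, 60.0)); times["chest_rr"].append(t)

            t = day0 + np.arange(0.0, _DAY, config.chest_act_dt)
            level = np.zeros(t.size)
            level[plan.upright_mask(t)] = 2.0
            level[plan.walking_mask(t)] = 5.0
            level[plan.exercise_mask(t)] = 7.0
            parts["chest_actlevel"].append(level); times["chest_actlevel"].append(t)
            upright = (plan.upright_mask(t) | plan.walking_mask(t)).astype(float)
            parts["chest_posture"].append(upright); times["chest_posture"].append(t)

        # ---- wrist device (21 days, one charging gap per day) ----
        t = day0 + np.arange(0.0, _DAY, config.wrist_dt)
        gap_len = 60.0 * rng.uniform(config.gap_min_minutes, config.gap_max_minutes)
        gap_start = day0 + rng.uniform(0.0, _DAY - gap_len)  # gap fits in the day
        keep = ~((t >= gap_start) & (t < gap_start + gap_len))
        t = t[keep]

        hr_clean = plan.hr(t)
        hr = np.clip(hr_clean + ns * config.noise_hr * rng.standard_normal(t.size),
                     25.0, 220.0)
        ibi = 60000.0 / np.clip(hr_clean, 25.0, 220.0) \
            + ns * config.ibi_jitter_ms * rng.standard_normal(t.size)
        walking = plan.walking_mask(t)
        exercising = plan.exercise_mask(t)
        upright = plan.upright_mask(t) | walking
        steps = np.zeros(t.size)
        if plan.steps > 0:
            if walking.any():
                steps[walking] = plan.steps / walking.sum()
            elif t.size:
                steps[np.argmin(np.abs((t % _DAY) - 12 * 3600.0))] = plan.steps
        walkspeed = np.where(walking, plan.walkspeed, 0.0)
        actcount = np.where(exercising, 3500.0,
                            np.where(walking, 2500.0, np.where(upright, 300.0, 50.0)))
        actcount = np.clip(
            actcount + ns * 100.0 * rng.standard_normal(t.size), 0.0, None)
        active = (walking | exercising).astype(float)
        sedentary = (~(upright | exercising)).astype(float)
        aee = np.where(exercising, 8.0, np.where(walking, 4.0,
                       np.where(upright, 2.0, 1.2)))

        for ch, vals in (
            ("wrist_hr", hr), ("wrist_ibi", ibi), ("wrist_steps", steps),
            ("wrist_walkspeed", walkspeed), ("wrist_actcount", actcount),
            ("wrist_pct_active", active), ("wrist_sedentary", sedentary),
            ("wrist_aee", aee),
        ):
            parts[ch].append(vals); times[ch].append(t)

    def _series(ch):
        if not parts[ch]:
            return pd.Series([], index=pd.DatetimeIndex([]), dtype=float, name=ch)
        t = np.concatenate(times[ch])
        idx = EPOCH + pd.to_timedelta(t, unit="s")
        return pd.Series(np.concatenate(parts[ch]), index=idx, name=ch)

    return SensorStreams(**{ch: _series(ch) for ch in ALL_CHANNELS})


class StreamParseError(ValueError):
    """Malformed stream file; message carries file and line position."""


def write_streams(streams: SensorStreams, path) -> None:
    """One delimited text file per channel: ISO-8601 timestamp, value."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, series in streams.channels().items():
        with open(path / f"{name}.csv", "w") as fh:
            fh.write("timestamp,value\n")
            for ts, v in series.items():
                fh.write(f"{ts.isoformat()},{v!r}\n")


def read_streams(path) -> SensorStreams:
    """Inverse of :func:`write_streams`; raises on malformed records rather
    than silently truncating."""
    from pathlib import Path

    path = Path(path)
    data = {}
    for name in ALL_CHANNELS:
        fpath = path / f"{name}.csv"
        if not fpath.exists():
            raise StreamParseError(f"{fpath}: missing channel file")
        ts, vals = [], []
        with open(fpath) as fh:
            header = fh.readline()
            if header.strip() != "timestamp,value":
                raise StreamParseError(f"{fpath}:1: bad header {header!r}")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                fields_ = line.split(",")
                if len(fields_) != 2:
                    raise StreamParseError(
                        f"{fpath}:{lineno}: expected 2 fields, got {len(fields_)}")
                try:
                    ts.append(pd.Timestamp(fields_[0]))
                    vals.append(float(fields_[1]))
                except ValueError as exc:
                    raise StreamParseError(f"{fpath}:{lineno}: {exc}") from exc
        data[name] = pd.Series(
            np.asarray(vals, dtype=float), index=pd.DatetimeIndex(ts), name=name)
    return SensorStreams(**data)
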