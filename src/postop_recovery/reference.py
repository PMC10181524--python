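"""Engineered daily reference recovery profiles.

Recovery after major abdominal surgery is summarised by a unitless daily
score that starts at 1.0 on the day of surgery, reaches 1.8 on the day of
hospital discharge (patients are assumed not to be fully recovered at
discharge) and converges to a plateau of 2.0 ("fully recovered") at home.
The profile is an anchored exponential

    R(t) = plateau - exp(-k * t),        k = ln(5) / LOS,

so that R(0) = 1.0 and R(LOS) = 1.8 hold exactly for any length of stay.

Surgical complications, graded with the Clavien-Dindo (CD) system, pull the
score down.  The deficit relative to the complication-free profile ramps up
linearly over a lead window before the event (the score is designed to
decrease ahead of the clinical diagnosis), equals the grade-specific
magnitude on the event day, and afterwards decays at the profile's own rate
k so that recovery resumes toward the plateau from the dropped value.
Deficits of overlapping events add.  Grade-5 events (death) terminate the
profile on the event day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReferenceProfile",
    "DropSpec",
    "base_profile",
    "apply_drops",
    "build_reference_profiles",
    "write_profiles",
    "read_profiles",
    "START_VALUE",
    "PLATEAU",
    "DISCHARGE_VALUE",
]

START_VALUE = 1.0
PLATEAU = 2.0
DISCHARGE_VALUE = 1.8


class InputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass(frozen=True)
class ReferenceProfile:
    """Daily recovery scores for one patient, indexed by post-op day 0..horizon.

    ``scores[d]`` is the score on post-op day ``d`` (day 0 = surgery day).
    NaN entries mark days after a fatal (CD 5) event.
    """

    patient_id: str
    scores: np.ndarray
    los: int
    decay_rate: float

    @property
    def horizon(self) -> int:
        return len(self.scores) - 1

    def score_at(self, day: int) -> float:
        return float(self.scores[day])


@dataclass(frozen=True)
class DropSpec:
    """Complication drop magnitudes and lead days per Clavien-Dindo grade."""

    magnitude_by_grade: dict = field(
        default_factory=lambda: {1: 0.02, 2: 0.02, 3: 0.04, 4: 0.06}
    )
    lead_days_by_grade: dict = field(
        default_factory=lambda: {1: 1, 2: 1, 3: 1, 4: 2}
    )

    def __post_init__(self) -> None:
        mags = [self.magnitude_by_grade[g] for g in sorted(self.magnitude_by_grade)]
        if any(m <= 0 for m in mags):
            raise InputError("drop magnitudes must be positive")
        if any(b < a for a, b in zip(mags, mags[1:])):
            raise InputError("drop magnitudes must be nondecreasing in CD grade")
        if any(l < 1 for l in self.lead_days_by_grade.values()):
            raise InputError("lead days must be >= 1")


def base_profile(los: int, horizon: int, patient_id: str = "") -> ReferenceProfile:
    """Complication-free profile anchored at R(0)=1.0 and R(los)=1.8.

    The decay rate k = ln(5)/los is the unique rate for which the
    exponential 2 - exp(-k t) passes through both anchors.  The profile
    extends past discharge toward the plateau: recovery continues at home.
    """
    if los < 1:
        raise InputError(f"los must be >= 1, got {los}")
    if horizon < los:
        raise InputError(f"horizon ({horizon}) must cover los ({los})")
    k = math.log(5.0) / los
    t = np.arange(horizon + 1, dtype=float)
    scores = PLATEAU - np.exp(-k * t)
    return ReferenceProfile(patient_id=patient_id, scores=scores, los=los, decay_rate=k)


def _event_deficit(event_day: int, lead: int, magnitude: float, k: float,
                   horizon: int) -> np.ndarray:
    """Per-day deficit of one event over days 0..horizon.

    Zero at day event_day - lead - 1, linear ramp to the full magnitude on
    the event day (so every day of the lead window sits strictly below the
    baseline), exponential decay at rate k afterwards.
    """
    t = np.arange(horizon + 1, dtype=float)
    d = np.zeros(horizon + 1)
    ramp_start = event_day - lead - 1  # deficit still zero here
    in_ramp = (t > ramp_start) & (t <= event_day)
    d[in_ramp] = magnitude * (t[in_ramp] - ramp_start) / (lead + 1)
    after = t > event_day
    d[after] = magnitude * np.exp(-k * (t[after] - event_day))
    return d


def apply_drops(profile: ReferenceProfile, events, spec: DropSpec) -> ReferenceProfile:
    """Superimpose complication drops on a profile.

    ``events`` is an iterable with ``day`` and ``cd_grade`` attributes (or
    (day, grade) pairs).  Deficits of multiple events add.  A CD-5 event
    truncates the profile: scores from the event day on become NaN.
    """
    scores = profile.scores.astype(float).copy()
    horizon = profile.horizon
    total_deficit = np.zeros(horizon + 1)
    truncate_at = None
    for ev in events:
        day, grade = (ev.day, ev.cd_grade) if hasattr(ev, "day") else ev
        if day < 0 or day > horizon:
            raise InputError(f"event day {day} outside profile horizon {horizon}")
        if grade == 5:
            truncate_at = day if truncate_at is None else min(truncate_at, day)
            continue
        if grade not in spec.magnitude_by_grade:
            raise InputError(f"unknown CD grade {grade!r}")
        total_deficit += _event_deficit(
            day, spec.lead_days_by_grade[grade], spec.magnitude_by_grade[grade],
            profile.decay_rate, horizon,
        )
    scores -= total_deficit
    if truncate_at is not None:
        scores[truncate_at:] = np.nan
    return ReferenceProfile(
        patient_id=profile.patient_id, scores=scores,
        los=profile.los, decay_rate=profile.decay_rate,
    )


def build_reference_profiles(cohort, spec: DropSpec | None = None,
                             horizon: int = 21) -> dict:
    """One reference profile per patient; deterministic.

    The horizon is extended per patient when the LOS exceeds it, so the
    discharge anchor always exists.
    """
    spec = spec or DropSpec()
    profiles = {}
    for patient in cohort:
        h = max(horizon, patient.los, max((e.day for e in patient.complications), default=0))
        prof = base_profile(patient.los, h, patient_id=patient.patient_id)
        profiles[patient.patient_id] = apply_drops(prof, patient.complications, spec)
    return profiles


def write_profiles(profiles: dict, path) -> None:
    rows = [
        {"patient_id": pid, "day": d, "score": p.scores[d], "los": p.los}
        for pid, p in profiles.items()
        for d in range(p.horizon + 1)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles(path) -> dict:
    df = pd.read_csv(path)
    profiles = {}
    for pid, g in df.groupby("patient_id", sort=False):
        g = g.sort_values("day")
        los = int(g["los"].iloc[0])
        scores = g["score"].to_numpy(dtype=float)
        profiles[pid] = ReferenceProfile(
            patient_id=str(pid), scores=scores, los=los,
            decay_rate=math.log(5.0) / los,
        )
    return profiles
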