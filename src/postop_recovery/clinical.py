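"""Clinical usability layer over the predicted daily recovery scores.

Predicted profiles of individual patients are compared against the
average profiles of the fast-recovering (short length of stay, LOS <= 8
days by default — the training-group median) and slow-recovering (long
LOS) groups, each rendered as a per-day mean with a 10th-90th percentile
band.  On top of this sit three simple decision aids: a per-day fast /
slow / indeterminate classification, a discharge-readiness day (first day
the predicted score reaches 1.8), and flags for sustained day-over-day
declines, which in practice sometimes precede complications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import InputError

__all__ = [
    "GroupProfile", "PatientAssessment", "group_profiles", "classify_patient",
    "discharge_readiness", "decline_flags", "feature_frame_report",
    "plot_group_comparison",
]

READINESS_THRESHOLD = 1.8
DEFAULT_LOS_THRESHOLD = 8


@dataclass
class GroupProfile:
    group: str                    # short_los | long_los
    days: np.ndarray
    mean: np.ndarray
    p10: np.ndarray
    p90: np.ndarray
    n: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.group, "day": self.days,
                             "mean": self.mean, "p10": self.p10,
                             "p90": self.p90, "n": self.n})


@dataclass
class PatientAssessment:
    patient_id: str
    days: list
    classification: list          # fast | slow | indeterminate per day
    discharge_ready_day: int | None
    unready_at_discharge: bool
    decline_flag_days: list = field(default_factory=list)


def group_profiles(predictions: pd.DataFrame, cohort,
                   los_threshold: int = DEFAULT_LOS_THRESHOLD):
    """Per-day mean and 10th/90th percentile of predicted scores for the
    short-LOS (<= threshold) and long-LOS (> threshold) groups.

    Predictions for training and test patients alike belong here: the
    bands describe the whole monitored population.
    """
    los = {p.patient_id: p.los for p in cohort}
    preds = predictions[predictions["patient_id"].isin(los)]
    short_ids = {pid for pid, l in los.items() if l <= los_threshold}
    out = []
    for name, ids in (("short_los", short_ids),
                      ("long_los", set(los) - short_ids)):
        sub = preds[preds["patient_id"].isin(ids)]
        if sub.empty:
            raise InputError(f"group {name!r} has no patients with predictions")
        g = sub.groupby("day")["score"]
        days = np.array(sorted(g.groups))
        out.append(GroupProfile(
            group=name, days=days,
            mean=g.mean().loc[days].to_numpy(),
            p10=g.quantile(0.10).loc[days].to_numpy(),
            p90=g.quantile(0.90).loc[days].to_numpy(),
            n=g.size().loc[days].to_numpy(),
        ))
    return tuple(out)


def _band_lookup(profile: GroupProfile, day):
    i = np.searchsorted(profile.days, day)
    if i >= len(profile.days) or profile.days[i] != day:
        return None
    return profile.p10[i], profile.p90[i]


def classify_patient(prediction_profile: pd.DataFrame, short: GroupProfile,
                     long: GroupProfile, readiness_threshold: float = READINESS_THRESHOLD,
                     discharge_day: int | None = None,
                     decline_k: int = 3) -> PatientAssessment:
    """Per-day fast/slow/indeterminate labels against the group bands.

    fast: at or above the short-LOS 10th percentile and above the long-LOS
    90th percentile; slow: at or below the long-LOS 90th percentile and
    below the short-LOS 10th percentile; anything in the overlap region is
    indeterminate.
    """
    days, labels = [], []
    prof = prediction_profile.sort_values("day")
    for _, row in prof.iterrows():
        day, score = int(row["day"]), float(row["score"])
        s_band = _band_lookup(short, day)
        l_band = _band_lookup(long, day)
        if s_band is None or l_band is None:
            continue
        days.append(day)
        if score >= s_band[0] and score > l_band[1]:
            labels.append("fast")
        elif score <= l_band[1] and score < s_band[0]:
            labels.append("slow")
        else:
            labels.append("indeterminate")
    ready_day, unready = discharge_readiness(
        prediction_profile, threshold=readiness_threshold,
        discharge_day=discharge_day)
    return PatientAssessment(
        patient_id=str(prof["patient_id"].iloc[0]) if len(prof) else "",
        days=days, classification=labels,
        discharge_ready_day=ready_day, unready_at_discharge=unready,
        decline_flag_days=decline_flags(prediction_profile, decline_k),
    )


def discharge_readiness(prediction_profile: pd.DataFrame,
                        threshold: float = READINESS_THRESHOLD,
                        discharge_day: int | None = None):
    """First day with predicted score >= threshold (None if never), plus a
    flag when the recorded discharge day's score is below the threshold."""
    prof = prediction_profile.sort_values("day")
    ready_day = None
    for _, row in prof.iterrows():
        if float(row["score"]) >= threshold:
            ready_day = int(row["day"])
            break
    unready = False
    if discharge_day is not None:
        at_discharge = prof[prof["day"] == discharge_day]
        if len(at_discharge) and float(at_discharge["score"].iloc[0]) < threshold:
            unready = True
    return ready_day, unready


def decline_flags(prediction_profile: pd.DataFrame, k_days: int = 3) -> list:
    """Days ending a strictly decreasing run of length >= k_days (ties
    break runs)."""
    if k_days < 2:
        raise InputError("k_days must be >= 2")
    prof = prediction_profile.sort_values("day")
    days = prof["day"].to_numpy(dtype=int)
    scores = prof["score"].to_numpy(dtype=float)
    flags = []
    run = 1
    for i in range(1, len(scores)):
        if days[i] == days[i - 1] + 1 and scores[i] < scores[i - 1]:
            run += 1
        else:
            run = 1
        if run >= k_days:
            flags.append(int(days[i]))
    return flags


def feature_frame_report(frames: pd.DataFrame, selected_features: list,
                         hrr_abnormal_bpm: float = 12.0) -> pd.DataFrame:
    """Per-day table of the selected features for one patient, rendered
    the way a clinician reads it: missing heart-rate-recovery values shown
    as 'inactive' (no exercise bout that day), missing deltas as '-', and
    abnormally low HRR-1 (< 12 bpm) marked with an asterisk."""
    frames = frames.sort_values("day")
    rows = []
    for _, row in frames.iterrows():
        rec = {"day": int(row["day"])}
        for feat in selected_features:
            v = row.get(feat, np.nan)
            if pd.isna(v):
                rec[feat] = "-" if feat.startswith("delta_") else (
                    "inactive" if feat.startswith("hrr") else "-")
            else:
                text = f"{v:.2f}".rstrip("0").rstrip(".") if isinstance(v, float) \
                    else str(v)
                if feat == "hrr1" and v < hrr_abnormal_bpm:
                    text += "*"
                rec[feat] = text
        rows.append(rec)
    return pd.DataFrame(rows)


def plot_group_comparison(short: GroupProfile, long: GroupProfile,
                          prediction_profile: pd.DataFrame | None = None,
                          events: dict | None = None, path=None):
    """Band plot of both group profiles, optionally overlaying one
    patient's predicted profile and vertical event lines
    (events: label -> day)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    for prof, color in ((short, "tab:blue"), (long, "tab:red")):
        ax.plot(prof.days, prof.mean, color=color, label=prof.group)
        ax.fill_between(prof.days, prof.p10, prof.p90, color=color, alpha=0.2)
    if prediction_profile is not None:
        prof = prediction_profile.sort_values("day")
        ax.plot(prof["day"], prof["score"], "k.-", label="patient")
    for label, day in (events or {}).items():
        ax.axvline(day, ls="--", color="gray")
        ax.text(day, ax.get_ylim()[1], label, rotation=90, va="top", fontsize=8)
    ax.axhline(READINESS_THRESHOLD, ls=":", color="green", lw=1)
    ax.set_xlabel("post-operative day")
    ax.set_ylabel("recovery score")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
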