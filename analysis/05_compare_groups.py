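"""Compare individual predicted recovery profiles against the fast
(short-LOS) and slow (long-LOS) group bands: per-day classification,
discharge readiness at the 1.8 threshold, decline flags, and the
interpretability feature table for one slow-recovering test patient.

Writes results/analysis/group_profiles.csv, assessments.csv and
figures/group_comparison.png.
"""

import json

import pandas as pd

from _common import RESULTS, study_config
from postop_recovery.clinical import (classify_patient, feature_frame_report,
                                      group_profiles, plot_group_comparison)
from postop_recovery.cohort import read_cohort


def main():
    cfg = study_config()
    cohort = read_cohort(RESULTS / "cohort.json")
    preds = pd.read_csv(RESULTS / "predictions.csv")
    split = json.loads((RESULTS / "split.json").read_text())
    selected = json.loads((RESULTS / "selected_features.json").read_text())["selected"]
    los = {p.patient_id: p.los for p in cohort}

    short, long_ = group_profiles(preds, cohort,
                                  los_threshold=cfg.clinical.los_threshold)
    pd.concat([short.frame(), long_.frame()]).to_csv(
        RESULTS / "group_profiles.csv", index=False)
    print(f"short-LOS group: {sum(1 for l in los.values() if l <= 8)} patients; "
          f"long-LOS group: {sum(1 for l in los.values() if l > 8)} patients")

    rows = []
    for pid in split["test_ids"]:
        prof = preds[preds.patient_id == pid]
        if prof.empty:
            continue
        a = classify_patient(prof, short, long_,
                             readiness_threshold=cfg.clinical.readiness_threshold,
                             discharge_day=los[pid],
                             decline_k=cfg.clinical.decline_k)
        rows.append({
            "patient_id": pid, "los": los[pid],
            "fast_days": a.classification.count("fast"),
            "slow_days": a.classification.count("slow"),
            "indeterminate_days": a.classification.count("indeterminate"),
            "discharge_ready_day": a.discharge_ready_day,
            "unready_at_discharge": a.unready_at_discharge,
            "decline_flag_days": ";".join(map(str, a.decline_flag_days)),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "assessments.csv", index=False)
    print(f"assessed {len(table)} test patients; "
          f"{table.unready_at_discharge.sum()} flagged unready at discharge")

    # one slow recoverer with a complication, rendered as a clinical table
    slow = table.sort_values("slow_days", ascending=False).iloc[0]
    frames = pd.read_csv(RESULTS / "daily_features.csv")
    patient_frames = frames[frames.patient_id == slow.patient_id]
    # the clinical six-feature view; fall back to the selected set when the
    # elimination kept a different mix
    report_cols = ["steps", "upright_hours", "delta_upright_hours",
                   "hrr1", "delta_hrr1", "circ_day_night"]
    if not set(report_cols) & set(selected):
        report_cols = selected[:6]
    report = feature_frame_report(patient_frames, report_cols,
                                  hrr_abnormal_bpm=cfg.clinical.hrr_abnormal_bpm)
    print(f"feature frame of slowest test patient ({slow.patient_id}, "
          f"LOS {slow.los} d):")
    print(report.head(12).to_string(index=False))

    figdir = RESULTS / "figures"
    figdir.mkdir(exist_ok=True)
    patient = next(p for p in cohort if p.patient_id == slow.patient_id)
    events = {f"CD{c.cd_grade}": c.day for c in patient.complications}
    events["discharge"] = patient.los
    plot_group_comparison(short, long_,
                          preds[preds.patient_id == slow.patient_id],
                          events=events,
                          path=figdir / "group_comparison.png")
    print(f"wrote {figdir/'group_comparison.png'}")


if __name__ == "__main__":
    main()
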