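"""End-to-end orchestration: simulate -> reference -> split -> features ->
tune -> (eliminate) -> train -> predict -> evaluate -> compare.

Test-cohort rows never enter any fitting path: standardization, tuning,
elimination and final training see only training patients.  A single
global seed fans out deterministically to per-stage seeds, so a fixed
(config, seed) pair reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import model as mdl
from .config import PipelineConfig
from .cohort import generate_cohort, write_cohort
from .features import delta_features, extract_daily_features, pearson_screen
from .reference import build_reference_profiles, write_profiles
from .split import balanced_split, split_report
from .streams import generate_streams

logger = logging.getLogger("postop_recovery")

__all__ = ["run_pipeline", "stage_seeds", "extract_cohort_features"]


def stage_seeds(global_seed: int) -> dict:
    """Deterministic per-stage seeds derived from one global seed."""
    state = np.random.SeedSequence(global_seed).generate_state(4)
    names = ("cohort", "split", "model", "streams")
    return {n: int(s % 2**31) for n, s in zip(names, state)}


def extract_cohort_features(cohort, profiles, gen_config, feat_config,
                            stream_seed_offset: int = 0) -> pd.DataFrame:
    """Per-patient stream synthesis + daily feature extraction.

    Streams are generated, reduced to the daily feature rows and
    discarded, one patient at a time, so cohort-scale runs never hold raw
    signals for more than one patient in memory.
    """
    frames = []
    for patient in cohort:
        streams = generate_streams(patient, profiles[patient.patient_id], gen_config)
        frames.append(extract_daily_features(
            streams, patient.age, gen_config.wrist_days, feat_config,
            patient_id=patient.patient_id))
    return delta_features(pd.concat(frames, ignore_index=True))


def _targets(frames: pd.DataFrame, profiles: dict) -> np.ndarray:
    return np.array([
        profiles[pid].scores[int(d)]
        if pid in profiles and int(d) <= profiles[pid].horizon else np.nan
        for pid, d in zip(frames["patient_id"], frames["day"])
    ])


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Execute the full analysis; returns all in-memory artifacts and, when
    an output directory is given, writes the tabular/JSON files and the
    resolved configuration."""
    t_start = time.time()
    seeds = stage_seeds(config.seed)
    timings = {}
    out_dir = Path(out_dir) if out_dir is not None else (
        Path(config.output_dir) if config.output_dir else None)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    def tick(stage, t0):
        timings[stage] = round(time.time() - t0, 3)
        logger.info("stage %-10s %6.1f s", stage, timings[stage])

    # --- simulate ---
    t0 = time.time()
    gen = dataclasses.replace(config.generator, seed=seeds["cohort"])
    cohort = generate_cohort(gen)
    tick("simulate", t0)

    # --- reference profiles ---
    t0 = time.time()
    profiles = build_reference_profiles(cohort, config.drops, horizon=config.horizon)
    tick("reference", t0)

    # --- balanced split ---
    t0 = time.time()
    split = balanced_split(cohort, fraction=config.split.fraction,
                           n_candidates=config.split.n_candidates,
                           seed=seeds["split"],
                           yates_correction=config.split.yates_correction)
    train_ids, test_ids = set(split.train_ids), set(split.test_ids)
    tick("split", t0)

    # --- features (whole cohort; extraction is per-patient and unsupervised) ---
    t0 = time.time()
    frames = extract_cohort_features(cohort, profiles, gen, config.features)
    tick("features", t0)

    feature_cols = [c for c in frames.columns if c not in ("patient_id", "day")]
    y_all = _targets(frames, profiles)
    valid = ~np.isnan(y_all)
    frames, y_all = frames[valid].reset_index(drop=True), y_all[valid]
    train_mask = frames["patient_id"].isin(train_ids).to_numpy()
    train_frames = frames[train_mask].reset_index(drop=True)
    test_frames = frames[~train_mask].reset_index(drop=True)
    y_train = y_all[train_mask]

    # training-set Pearson screening (descriptive)
    pearson = pearson_screen(train_frames, profiles)

    # --- standardize (training statistics only) ---
    mcfg = dataclasses.replace(config.model, seed=seeds["model"])
    train_z, zparams = mdl.standardize(train_frames, feature_cols=feature_cols)
    test_z, _ = mdl.standardize(test_frames, params=zparams,
                                feature_cols=feature_cols)

    # --- tune ---
    t0 = time.time()
    best = mdl.tune_hyperparameters(train_z, y_train, mcfg, features=feature_cols)
    tick("tune", t0)

    # --- eliminate ---
    selection = None
    selected = list(feature_cols)
    if config.eliminate:
        t0 = time.time()
        selection = mdl.backward_eliminate(train_z, y_train, best, mcfg,
                                           features=feature_cols)
        selected = selection.selected_features
        tick("eliminate", t0)

    # --- assess + final train ---
    t0 = time.time()
    cv_metrics = mdl.cross_validate(train_z, y_train, best, mcfg,
                                    features=selected)
    final = mdl.train_final(train_z, y_train, best, mcfg, features=selected,
                            standardization=zparams.loc[selected])
    importances = mdl.feature_importances(train_z, y_train, best, mcfg,
                                          features=selected)
    tick("train", t0)

    # --- predict + evaluate (test data first touched here) ---
    t0 = time.time()
    pred_train = mdl.predict(final, train_z)
    pred_test = mdl.predict(final, test_z)
    discharge = {p.patient_id: p.los for p in cohort}
    metrics_train = mdl.evaluate(pred_train, profiles,
                                 {k: v for k, v in discharge.items() if k in train_ids})
    metrics_test = mdl.evaluate(pred_test, profiles,
                                {k: v for k, v in discharge.items() if k in test_ids})
    tick("evaluate", t0)

    # --- clinical comparison over all predictions ---
    t0 = time.time()
    all_pred = pd.concat([pred_train, pred_test], ignore_index=True)
    short, long_ = clin.group_profiles(all_pred, cohort,
                                       los_threshold=config.clinical.los_threshold)
    assessments = {}
    for pid in sorted(test_ids):
        prof = all_pred[all_pred["patient_id"] == pid]
        if prof.empty:
            continue
        assessments[pid] = clin.classify_patient(
            prof, short, long_,
            readiness_threshold=config.clinical.readiness_threshold,
            discharge_day=discharge[pid], decline_k=config.clinical.decline_k)
    tick("compare", t0)

    results = {
        "config": config, "seeds": seeds, "cohort": cohort, "profiles": profiles,
        "split": split, "frames": frames, "train_frames": train_frames,
        "test_frames": test_frames, "pearson": pearson,
        "standardization": zparams, "hyperparams": best, "selection": selection,
        "selected_features": selected, "cv_metrics": cv_metrics, "model": final,
        "importances": importances, "predictions_train": pred_train,
        "predictions_test": pred_test, "metrics_train": metrics_train,
        "metrics_test": metrics_test, "group_short": short, "group_long": long_,
        "assessments": assessments, "timings": timings,
        "runtime_s": round(time.time() - t_start, 3),
    }
    if out_dir is not None:
        _write_artifacts(results, out_dir)
    return results


def _write_artifacts(results: dict, out_dir: Path) -> None:
    config: PipelineConfig = results["config"]
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    write_cohort(results["cohort"], out_dir / "cohort.json")
    write_profiles(results["profiles"], out_dir / "reference_profiles.csv")
    with open(out_dir / "split.json", "w") as fh:
        json.dump({"train_ids": results["split"].train_ids,
                   "test_ids": results["split"].test_ids,
                   "balance_score": results["split"].balance_score,
                   "per_variable_p": results["split"].per_variable_p}, fh, indent=1)
    split_report(results["split"], results["cohort"]).to_csv(
        out_dir / "split_report.csv", index=False)
    mdl.save_model(results["model"], out_dir / "model")
    results["frames"].to_csv(out_dir / "daily_features.csv", index=False)
    results["pearson"].to_csv(out_dir / "pearson_screen.csv")
    results["importances"].rename("total_gain").to_csv(
        out_dir / "feature_importances.csv")
    pd.concat([results["predictions_train"].assign(split="train"),
               results["predictions_test"].assign(split="test")]).to_csv(
        out_dir / "predictions.csv", index=False)
    pd.concat([results["group_short"].frame(),
               results["group_long"].frame()]).to_csv(
        out_dir / "group_profiles.csv", index=False)
    metrics = {
        "seeds": results["seeds"],
        "hyperparams": results["hyperparams"],
        "selected_features": results["selected_features"],
        "cv_mse_mean": float(np.mean([m.mse for m in results["cv_metrics"]])),
        "cv_srcc_mean": float(np.mean([m.srcc for m in results["cv_metrics"]])),
        "train": dataclasses.asdict(results["metrics_train"]),
        "test": dataclasses.asdict(results["metrics_test"]),
    }
    with open(out_dir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, default=float)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({"timings_s": results["timings"],
                   "runtime_s": results["runtime_s"]}, fh, indent=1)
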