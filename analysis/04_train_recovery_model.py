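"""Train the daily recovery-score regressor: standardize on the training
split, tune by 5-fold CV, prune features by Friedman/Nemenyi backward
elimination, assess with 10-fold CV, train the final booster with early
stopping, and evaluate on the held-out test patients.

Writes results/analysis/metrics.json, predictions.csv,
selected_features.json and feature_importances.csv.
"""

import dataclasses
import json
import time

import numpy as np
import pandas as pd

from _common import RESULTS, study_config
import postop_recovery.model as mdl
from postop_recovery.pipeline import _targets, stage_seeds
from postop_recovery.reference import read_profiles


def main():
    cfg = study_config()
    profiles = read_profiles(RESULTS / "reference_profiles.csv")
    frames = pd.read_csv(RESULTS / "daily_features.csv")
    split = json.loads((RESULTS / "split.json").read_text())
    feature_cols = [c for c in frames.columns if c not in ("patient_id", "day")]

    y = _targets(frames, profiles)
    keep = ~np.isnan(y)
    frames, y = frames[keep].reset_index(drop=True), y[keep]
    is_train = frames.patient_id.isin(set(split["train_ids"])).to_numpy()
    train, test = (frames[is_train].reset_index(drop=True),
                   frames[~is_train].reset_index(drop=True))
    y_train = y[is_train]

    mcfg = dataclasses.replace(cfg.model, seed=stage_seeds(cfg.seed)["model"])
    train_z, zparams = mdl.standardize(train, feature_cols=feature_cols)
    test_z, _ = mdl.standardize(test, params=zparams, feature_cols=feature_cols)

    t0 = time.time()
    best = mdl.tune_hyperparameters(train_z, y_train, mcfg, features=feature_cols)
    print(f"tuned hyperparameters {best} ({time.time() - t0:.0f} s)")

    t0 = time.time()
    sel = mdl.backward_eliminate(train_z, y_train, best, mcfg,
                                 features=feature_cols)
    print(f"backward elimination kept {len(sel.selected_features)} of "
          f"{len(feature_cols)} features ({time.time() - t0:.0f} s)")

    cv = mdl.cross_validate(train_z, y_train, best, mcfg,
                            features=sel.selected_features)
    print(f"10-fold CV: MSE {np.mean([m.mse for m in cv]):.4f}, "
          f"SRCC {np.mean([m.srcc for m in cv]):.3f}")

    final = mdl.train_final(train_z, y_train, best, mcfg,
                            features=sel.selected_features,
                            standardization=zparams.loc[sel.selected_features])
    imp = mdl.feature_importances(train_z, y_train, best, mcfg,
                                  sel.selected_features)
    pred_train = mdl.predict(final, train_z)
    pred_test = mdl.predict(final, test_z)
    m_train = mdl.evaluate(pred_train, profiles)
    m_test = mdl.evaluate(pred_test, profiles)
    print(f"train: MSE {m_train.mse:.4f}  SRCC {m_train.srcc:.3f}  "
          f"discharge error {m_train.discharge_error:.3f}")
    print(f"test : MSE {m_test.mse:.4f}  SRCC {m_test.srcc:.3f}  "
          f"discharge error {m_test.discharge_error:.3f}")
    print("top importances:")
    print(imp.tail(6).round(3).to_string())

    pd.concat([pred_train.assign(split="train"),
               pred_test.assign(split="test")]).to_csv(
        RESULTS / "predictions.csv", index=False)
    imp.rename("total_gain").to_csv(RESULTS / "feature_importances.csv")
    with open(RESULTS / "selected_features.json", "w") as fh:
        json.dump({"selected": sel.selected_features,
                   "removed": sel.removed_features,
                   "hyperparams": best}, fh, indent=1)
    with open(RESULTS / "metrics.json", "w") as fh:
        json.dump({"hyperparams": best,
                   "cv_mse_mean": float(np.mean([m.mse for m in cv])),
                   "cv_srcc_mean": float(np.mean([m.srcc for m in cv])),
                   "train": dataclasses.asdict(m_train),
                   "test": dataclasses.asdict(m_test)}, fh, indent=1)


if __name__ == "__main__":
    main()
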