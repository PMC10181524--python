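"""Gradient-boosted daily recovery-score regressor.

Each patient-day is one sample: standardized daily features in, engineered
reference recovery score out.  Missing feature values are handled natively
by the tree learner (samples follow a per-split default direction).
Hyperparameters are tuned by 5-fold cross-validation on the training
split, performance is assessed with 10-fold cross-validation, and backward
feature elimination drops low-importance features until the reduced model
differs significantly from the all-features model (Friedman test with
Nemenyi post hoc across the CV folds, on both MSE and Spearman rank
correlation).

Cross-validation folds group all of a patient's days together to avoid
within-patient leakage between folds; an ungrouped mode is available for
fidelity experiments with the day-as-independent-sample convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import GroupKFold, KFold
import xgboost as xgb

from .reference import InputError
from .stats import friedman_test, nemenyi_posthoc

__all__ = [
    "ModelConfig", "TrainedModel", "EvalMetrics", "EliminationResult",
    "standardize", "tune_hyperparameters", "cross_validate", "train_final",
    "predict", "evaluate", "backward_eliminate", "feature_importances",
    "save_model", "load_model", "fit_linear_baseline",
]


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    grid: list = field(default_factory=lambda: [
        {"learning_rate": lr, "max_depth": d}
        for lr in (0.05, 0.1) for d in (2, 3)
    ])
    n_estimators: int = 300
    subsample: float = 0.9
    early_stopping_rounds: int = 30
    early_stopping_holdout: float = 0.1   # fraction of training patients
    cv_folds_tuning: int = 5
    cv_folds_assess: int = 10
    elimination_alpha: float = 0.05
    grouped_folds: bool = True
    seed: int = 0

    def validate(self):
        if not 0 < self.elimination_alpha < 1:
            raise ConfigError("elimination_alpha must be in (0, 1)")
        if self.cv_folds_tuning < 2 or self.cv_folds_assess < 2:
            raise ConfigError("cross-validation folds must be >= 2")


@dataclass
class EvalMetrics:
    mse: float
    srcc: float
    discharge_error: float = np.nan


@dataclass
class TrainedModel:
    booster: "xgb.XGBRegressor"
    feature_names: list
    standardization: pd.DataFrame       # per-feature mean / sd (training data)
    hyperparams: dict
    training_log: dict = field(default_factory=dict)


@dataclass
class EliminationResult:
    selected_features: list
    removed_features: list
    history: list                        # (features, mse_folds, srcc_folds)
    p_values: list                       # (p_mse, p_srcc) per step


def standardize(frames: pd.DataFrame, params: pd.DataFrame | None = None,
                feature_cols: list | None = None):
    """Z-score features; missing values stay missing.

    Fit (params=None) computes per-feature mean and population sd on the
    given frame — the training split — and must be reused to transform any
    test frame.  Zero-sd features pass through with sd treated as 1.
    """
    if feature_cols is None:
        feature_cols = [c for c in frames.columns if c not in ("patient_id", "day")]
    if params is None:
        mean = frames[feature_cols].mean()
        sd = frames[feature_cols].std(ddof=0).replace(0.0, 1.0).fillna(1.0)
        params = pd.DataFrame({"mean": mean, "sd": sd})
    out = frames.copy()
    out[feature_cols] = (frames[feature_cols] - params["mean"]) / params["sd"]
    return out, params


def _folds(frames: pd.DataFrame, k: int, grouped: bool, seed: int):
    if grouped:
        groups = frames["patient_id"].to_numpy()
        if len(np.unique(groups)) < k:
            raise InputError(f"{k} folds require at least {k} patients")
        return list(GroupKFold(n_splits=k).split(frames, groups=groups)), groups
    return list(KFold(n_splits=k, shuffle=True, random_state=seed)
                .split(frames)), None


def _make_regressor(hyperparams: dict, config: ModelConfig,
                    early_stopping: bool) -> "xgb.XGBRegressor":
    kwargs = dict(
        n_estimators=config.n_estimators,
        subsample=config.subsample,
        random_state=config.seed,
        n_jobs=1,
        tree_method="hist",
        early_stopping_rounds=config.early_stopping_rounds if early_stopping else None,
    )
    kwargs.update(hyperparams)  # grid points may override any of these
    return xgb.XGBRegressor(**kwargs)


def _fit_fold(X_tr, y_tr, X_va, y_va, hyperparams, config):
    reg = _make_regressor(hyperparams, config, early_stopping=True)
    reg.fit(X_tr, y_tr, eval_set=[(X_va, y_va)], verbose=False)
    return reg


def _fold_metrics(frames, targets, hyperparams, features, config, k):
    """Per-fold validation MSE and SRCC for one feature set."""
    folds, _ = _folds(frames, k, config.grouped_folds, config.seed)
    X = frames[features].to_numpy(dtype=float)
    y = np.asarray(targets, dtype=float)
    mses, srccs = [], []
    for tr, va in folds:
        reg = _fit_fold(X[tr], y[tr], X[va], y[va], hyperparams, config)
        pred = reg.predict(X[va])
        mses.append(float(np.mean((pred - y[va]) ** 2)))
        srccs.append(float(sps.spearmanr(pred, y[va]).statistic))
    return np.array(mses), np.array(srccs)


def tune_hyperparameters(frames: pd.DataFrame, targets, config: ModelConfig,
                         features: list | None = None) -> dict:
    """Grid point with the lowest mean validation MSE over the tuning
    folds; ties keep the first point in declared grid order."""
    config.validate()
    if not config.grid:
        raise ConfigError("hyperparameter grid is empty")
    if features is None:
        features = [c for c in frames.columns if c not in ("patient_id", "day")]
    best, best_mse = None, np.inf
    for point in config.grid:
        mses, _ = _fold_metrics(frames, targets, point, features, config,
                                config.cv_folds_tuning)
        mean_mse = float(mses.mean())
        if mean_mse < best_mse:  # strict: first grid point wins ties
            best, best_mse = point, mean_mse
    return dict(best)


def cross_validate(frames: pd.DataFrame, targets, hyperparams: dict,
                   config: ModelConfig, k: int | None = None,
                   features: list | None = None) -> list:
    """Per-fold EvalMetrics on the assessment folds (default 10)."""
    config.validate()
    k = k or config.cv_folds_assess
    if features is None:
        features = [c for c in frames.columns if c not in ("patient_id", "day")]
    if config.grouped_folds and len(frames["patient_id"].unique()) < k:
        raise InputError(f"k={k} exceeds the number of patients")
    mses, srccs = _fold_metrics(frames, targets, hyperparams, features, config, k)
    return [EvalMetrics(mse=m, srcc=s) for m, s in zip(mses, srccs)]


def train_final(frames: pd.DataFrame, targets, hyperparams: dict,
                config: ModelConfig, features: list | None = None,
                standardization: pd.DataFrame | None = None) -> TrainedModel:
    """Fit the final booster with early stopping on a held-out slice of
    training patients.  No patient identity or day index reaches the model."""
    config.validate()
    if features is None:
        features = [c for c in frames.columns if c not in ("patient_id", "day")]
    if not features:
        raise InputError("at least one feature is required")
    y = np.asarray(targets, dtype=float)
    X = frames[features].to_numpy(dtype=float)
    all_missing = [f for i, f in enumerate(features) if np.isnan(X[:, i]).all()]
    if all_missing:
        import warnings
        warnings.warn(f"features with no observed values retained for native "
                      f"missing handling: {all_missing}", stacklevel=2)

    patients = frames["patient_id"].unique()
    rng = np.random.default_rng(config.seed)
    n_hold = max(1, int(round(config.early_stopping_holdout * len(patients))))
    hold = set(rng.choice(patients, size=n_hold, replace=False))
    hold_mask = frames["patient_id"].isin(hold).to_numpy()
    reg = _make_regressor(hyperparams, config, early_stopping=True)
    reg.fit(X[~hold_mask], y[~hold_mask],
            eval_set=[(X[hold_mask], y[hold_mask])], verbose=False)
    log = {
        "n_samples": int(len(frames)), "n_patients": int(len(patients)),
        "holdout_patients": sorted(hold), "best_iteration": int(reg.best_iteration),
    }
    if standardization is None:
        # frames were standardized upstream; record identity parameters
        standardization = pd.DataFrame(
            {"mean": pd.Series(0.0, index=features),
             "sd": pd.Series(1.0, index=features)})
    return TrainedModel(booster=reg, feature_names=list(features),
                        standardization=standardization,
                        hyperparams=dict(hyperparams), training_log=log)


def predict(model: TrainedModel, frames: pd.DataFrame) -> pd.DataFrame:
    """Daily score predictions: one row (patient_id, day, score) per input
    patient-day.  Frames must already be standardized with the training
    parameters."""
    missing = [f for f in model.feature_names if f not in frames.columns]
    if missing:
        raise InputError(f"frames lack model features: {missing}")
    if frames.empty:
        return pd.DataFrame(columns=["patient_id", "day", "score"])
    X = frames[model.feature_names].to_numpy(dtype=float)
    if isinstance(model.booster, xgb.Booster):  # loaded bundle
        best = model.booster.attr("best_iteration")
        scores = model.booster.predict(
            xgb.DMatrix(X),
            iteration_range=(0, int(best) + 1) if best is not None else None)
    else:
        scores = model.booster.predict(X)
    return pd.DataFrame({
        "patient_id": frames["patient_id"].to_numpy(),
        "day": frames["day"].to_numpy(),
        "score": scores.astype(float),
    })


def evaluate(predictions: pd.DataFrame, profiles: dict,
             discharge_days: dict | None = None) -> EvalMetrics:
    """MSE and Spearman correlation over all patient-days plus the mean
    absolute error at each patient's discharge day."""
    ref = np.array([
        profiles[pid].scores[int(d)]
        if pid in profiles and int(d) <= profiles[pid].horizon else np.nan
        for pid, d in zip(predictions["patient_id"], predictions["day"])
    ])
    pred = predictions["score"].to_numpy(dtype=float)
    ok = ~(np.isnan(ref) | np.isnan(pred))
    if ok.sum() == 0:
        raise InputError("no overlapping patient-days between predictions "
                         "and reference profiles")
    mse = float(np.mean((pred[ok] - ref[ok]) ** 2))
    srcc = float(sps.spearmanr(pred[ok], ref[ok]).statistic)

    if discharge_days is None:
        discharge_days = {pid: p.los for pid, p in profiles.items()}
    errs = []
    by_patient = predictions.set_index(["patient_id", "day"])["score"]
    for pid, d_day in discharge_days.items():
        if (pid, d_day) in by_patient.index and pid in profiles \
                and d_day <= profiles[pid].horizon:
            ref_v = profiles[pid].scores[d_day]
            if not np.isnan(ref_v):
                errs.append(abs(float(by_patient.loc[(pid, d_day)]) - ref_v))
    discharge_error = float(np.mean(errs)) if errs else np.nan
    return EvalMetrics(mse=mse, srcc=srcc, discharge_error=discharge_error)


def feature_importances(frames: pd.DataFrame, targets, hyperparams: dict,
                        config: ModelConfig, features: list) -> pd.Series:
    """Total-gain importances from a model fit on the full training frame
    (zero for features the booster never used)."""
    model = train_final(frames, targets, hyperparams, config, features)
    booster = model.booster.get_booster()
    booster.feature_names = list(features)
    gains = booster.get_score(importance_type="total_gain")
    return pd.Series({f: gains.get(f, 0.0) for f in features}).sort_values()


def backward_eliminate(frames: pd.DataFrame, targets, hyperparams: dict,
                       config: ModelConfig,
                       features: list | None = None) -> EliminationResult:
    """Iteratively remove the lowest-importance feature until the reduced
    model's per-fold MSE or SRCC differs significantly from the
    all-features model (Friedman over all models so far, Nemenyi post hoc
    on the reduced-vs-full pair, at the configured alpha).

    Returns the smallest feature set not significantly different from the
    full model; never returns an empty set.
    """
    config.validate()
    if features is None:
        features = [c for c in frames.columns if c not in ("patient_id", "day")]
    if len(features) < 2:
        raise InputError("elimination needs at least 2 features")
    k = config.cv_folds_assess
    full_mse, full_srcc = _fold_metrics(frames, targets, hyperparams,
                                        features, config, k)
    history = [(list(features), full_mse, full_srcc)]
    p_values = []
    removed = []
    current = list(features)
    while len(current) > 1:
        imp = feature_importances(frames, targets, hyperparams, config, current)
        drop = imp.index[0]
        candidate = [f for f in current if f != drop]
        mse_f, srcc_f = _fold_metrics(frames, targets, hyperparams,
                                      candidate, config, k)
        history.append((list(candidate), mse_f, srcc_f))
        significant = False
        step_p = []
        for col in (1, 2):  # 1: mse matrices, 2: srcc matrices
            mat = np.column_stack([h[col] for h in history])
            _, p = friedman_test(mat)
            step_p.append(p)
            if p < config.elimination_alpha:
                pairwise = nemenyi_posthoc(mat, config.elimination_alpha)
                if pairwise[0, mat.shape[1] - 1]:  # full vs newest reduced
                    significant = True
        p_values.append(tuple(step_p))
        if significant:
            history.pop()
            break
        removed.append(drop)
        current = candidate
    return EliminationResult(selected_features=current, removed_features=removed,
                             history=history, p_values=p_values)


def save_model(model: TrainedModel, path) -> None:
    """Persist a trained model as a directory bundle: the booster in
    xgboost's JSON format plus feature list, hyperparameters and
    standardization parameters."""
    import json
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    booster = model.booster.get_booster() \
        if hasattr(model.booster, "get_booster") else model.booster
    booster.save_model(str(path / "booster.json"))
    best_iteration = getattr(model.booster, "best_iteration", None)
    meta = {
        "format_version": 1,
        "best_iteration": None if best_iteration is None else int(best_iteration),
        "feature_names": model.feature_names,
        "hyperparams": model.hyperparams,
        "standardization": {
            "mean": model.standardization["mean"].to_dict(),
            "sd": model.standardization["sd"].to_dict(),
        },
        "training_log": model.training_log,
    }
    with open(path / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=float)


def load_model(path) -> TrainedModel:
    import json
    from pathlib import Path

    path = Path(path)
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    if meta.get("format_version") != 1:
        raise InputError(f"unsupported model bundle version: "
                         f"{meta.get('format_version')!r}")
    reg = xgb.Booster()
    reg.load_model(str(path / "booster.json"))
    if meta.get("best_iteration") is not None:
        reg.set_attr(best_iteration=str(meta["best_iteration"]))
    params = pd.DataFrame({
        "mean": pd.Series(meta["standardization"]["mean"]),
        "sd": pd.Series(meta["standardization"]["sd"]),
    }).loc[meta["feature_names"]]
    return TrainedModel(booster=reg, feature_names=meta["feature_names"],
                        standardization=params,
                        hyperparams=meta["hyperparams"],
                        training_log=meta.get("training_log", {}))


def fit_linear_baseline(frames: pd.DataFrame, targets,
                        features: list | None = None, alpha: float = 1.0):
    """Penalized-linear sanity baseline behind the same predict() shape.

    Ridge regression with median imputation for missing entries; useful
    for checking that the boosted model is not the only learner able to
    read the features.
    """
    from sklearn.impute import SimpleImputer
    from sklearn.linear_model import Ridge
    from sklearn.pipeline import Pipeline

    if features is None:
        features = [c for c in frames.columns if c not in ("patient_id", "day")]
    pipe = Pipeline([
        ("impute", SimpleImputer(strategy="median")),
        ("ridge", Ridge(alpha=alpha)),
    ])
    pipe.fit(frames[features].to_numpy(dtype=float), np.asarray(targets, float))

    def predict_frames(test_frames: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": test_frames["patient_id"].to_numpy(),
            "day": test_frames["day"].to_numpy(),
            "score": pipe.predict(test_frames[features].to_numpy(dtype=float)),
        })

    return pipe, predict_frames
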