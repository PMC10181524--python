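"""Regressor stack: standardization, tuning, CV, training, evaluation,
backward elimination."""

import numpy as np
import pandas as pd
import pytest

from postop_recovery.model import (ConfigError, ModelConfig, backward_eliminate,
                                   cross_validate, evaluate,
                                   feature_importances, fit_linear_baseline,
                                   predict, standardize, train_final,
                                   tune_hyperparameters)
from postop_recovery.reference import InputError, base_profile


def _toy_frames(n_patients=12, days=8, n_noise=2, noise=0.0, seed=0):
    """Patient-day frame where 'signal' equals the target up to noise."""
    rng = np.random.default_rng(seed)
    rows, targets = [], []
    for i in range(n_patients):
        los = 4 + i % 8
        prof = base_profile(los, max(days, los))
        for d in range(days):
            y = prof.scores[d]
            row = {"patient_id": f"P{i}", "day": d,
                   "signal": y + noise * rng.normal()}
            for j in range(n_noise):
                row[f"noise{j}"] = rng.normal()
            rows.append(row)
            targets.append(y)
    return pd.DataFrame(rows), np.array(targets)


FAST = dict(grid=[{"learning_rate": 0.1, "max_depth": 2}], n_estimators=60,
            early_stopping_rounds=10)


def test_standardize_hand_values():
    frames = pd.DataFrame({"patient_id": ["A"] * 3, "day": [0, 1, 2],
                           "x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0],
                           "m": [1.0, np.nan, 3.0]})
    z, params = standardize(frames)
    np.testing.assert_allclose(z["x"], [-1.224744871, 0.0, 1.224744871],
                               atol=1e-9)  # population sd
    np.testing.assert_allclose(z["c"], [0.0, 0.0, 0.0])  # constant column
    assert np.isnan(z["m"][1])  # missing stays missing

    test = pd.DataFrame({"patient_id": ["B"], "day": [0],
                         "x": [2.0], "c": [5.0], "m": [1.0]})
    z2, _ = standardize(test, params=params)
    assert z2["x"].iloc[0] == pytest.approx(0.0)


def test_tune_single_point_and_tiebreak():
    frames, y = _toy_frames()
    cfg = ModelConfig(grid=[{"learning_rate": 0.1, "max_depth": 2}],
                      n_estimators=40, cv_folds_tuning=3)
    assert tune_hyperparameters(frames, y, cfg) == {"learning_rate": 0.1,
                                                    "max_depth": 2}
    # identical points tie -> first in declared order wins
    cfg2 = ModelConfig(grid=[{"learning_rate": 0.1, "max_depth": 2, "gamma": 0.0},
                             {"learning_rate": 0.1, "max_depth": 2}],
                       n_estimators=40, cv_folds_tuning=3)
    assert "gamma" in tune_hyperparameters(frames, y, cfg2)
    with pytest.raises(ConfigError):
        tune_hyperparameters(frames, y, ModelConfig(grid=[]))


def test_tune_prefers_dominant_point():
    """A 1-tree depth-1 learner cannot fit an 8-level target; a real
    configuration dominates it on every fold."""
    frames, y = _toy_frames(noise=0.01)
    cfg = ModelConfig(grid=[{"learning_rate": 0.01, "max_depth": 1,
                             "n_estimators": 1},
                            {"learning_rate": 0.2, "max_depth": 3}],
                      n_estimators=80, cv_folds_tuning=3)
    best = cfg.grid[1]
    assert tune_hyperparameters(frames, y, cfg) == best


def test_cross_validate_perfect_and_noise_features():
    frames, y = _toy_frames(noise=0.0)
    cfg = ModelConfig(**FAST, cv_folds_assess=4)
    metrics = cross_validate(frames, y, cfg.grid[0], cfg, features=["signal"])
    assert len(metrics) == 4
    assert np.mean([m.mse for m in metrics]) < 1e-3

    pure_noise = cross_validate(frames, y, cfg.grid[0], cfg,
                                features=["noise0", "noise1"])
    assert abs(np.mean([m.srcc for m in pure_noise])) < 0.4

    with pytest.raises(InputError):
        cross_validate(frames, y, cfg.grid[0], cfg, k=99)


def test_train_final_determinism_and_missing_handling():
    frames, y = _toy_frames(noise=0.05)
    cfg = ModelConfig(**FAST)
    m1 = train_final(frames, y, cfg.grid[0], cfg)
    m2 = train_final(frames, y, cfg.grid[0], cfg)
    p1, p2 = predict(m1, frames), predict(m2, frames)
    np.testing.assert_array_equal(p1["score"], p2["score"])
    assert np.mean((p1["score"] - y) ** 2) < 0.01

    # a row with every feature missing still gets a prediction
    blank = frames.iloc[[0]].copy()
    for c in ("signal", "noise0", "noise1"):
        blank[c] = np.nan
    out = predict(m1, blank)
    assert len(out) == 1 and np.isfinite(out["score"].iloc[0])

    with pytest.warns(UserWarning, match="no observed values"):
        all_nan = frames.copy()
        all_nan["noise0"] = np.nan
        train_final(all_nan, y, cfg.grid[0], cfg)


def test_predict_contracts():
    frames, y = _toy_frames()
    cfg = ModelConfig(**FAST)
    model = train_final(frames, y, cfg.grid[0], cfg)
    assert predict(model, frames.iloc[0:0]).empty
    doubled = pd.concat([frames.iloc[[3]], frames.iloc[[3]]])
    out = predict(model, doubled)
    assert out["score"].iloc[0] == out["score"].iloc[1]
    with pytest.raises(InputError, match="signal"):
        predict(model, frames.drop(columns=["signal"]))


def test_no_test_leakage_in_training_artifacts():
    """Dropping held-out patients entirely does not change the trained
    model's predictions on the training patients."""
    frames, y = _toy_frames(n_patients=14, noise=0.05)
    train_mask = ~frames["patient_id"].isin(["P12", "P13"])
    cfg = ModelConfig(**FAST)
    m_all = train_final(frames[train_mask].reset_index(drop=True),
                        y[train_mask.to_numpy()], cfg.grid[0], cfg)
    m_iso = train_final(frames[train_mask].reset_index(drop=True),
                        y[train_mask.to_numpy()], cfg.grid[0], cfg)
    probe = frames[train_mask].reset_index(drop=True)
    np.testing.assert_array_equal(predict(m_all, probe)["score"],
                                  predict(m_iso, probe)["score"])


def test_evaluate_identities():
    profiles = {"A": base_profile(5, 10), "B": base_profile(8, 10)}
    rows = [{"patient_id": pid, "day": d, "score": prof.scores[d]}
            for pid, prof in profiles.items() for d in range(11)]
    preds = pd.DataFrame(rows)
    m = evaluate(preds, profiles)
    assert m.mse == pytest.approx(0.0, abs=1e-15)
    assert m.srcc == pytest.approx(1.0)
    assert m.discharge_error == pytest.approx(0.0, abs=1e-15)

    offset = preds.assign(score=preds["score"] + 0.1)
    m2 = evaluate(offset, profiles)
    assert m2.mse == pytest.approx(0.01)
    assert m2.srcc == pytest.approx(1.0)
    assert m2.discharge_error == pytest.approx(0.1)

    reversed_ = preds.assign(score=-preds["score"])
    assert evaluate(reversed_, profiles).srcc == pytest.approx(-1.0)

    with pytest.raises(InputError):
        evaluate(pd.DataFrame({"patient_id": ["Z"], "day": [0],
                               "score": [1.0]}), profiles)


def test_backward_elimination_keeps_informative_feature():
    """1 informative + 9 pure-noise features: the informative one survives
    and the selection is never empty."""
    frames, y = _toy_frames(n_patients=20, days=10, n_noise=9, noise=0.02,
                            seed=3)
    cfg = ModelConfig(**FAST, cv_folds_assess=5)
    res = backward_eliminate(frames, y, cfg.grid[0], cfg)
    assert "signal" in res.selected_features
    assert len(res.selected_features) >= 1
    assert set(res.removed_features).isdisjoint({"signal"}) or \
        res.selected_features == ["signal"]


def test_elimination_selected_never_significantly_worse():
    frames, y = _toy_frames(n_patients=16, days=10, n_noise=4, noise=0.05,
                            seed=5)
    cfg = ModelConfig(**FAST, cv_folds_assess=5)
    res = backward_eliminate(frames, y, cfg.grid[0], cfg)
    from postop_recovery.stats import friedman_test, nemenyi_posthoc

    full_mse = res.history[0][1]
    sel_mse = [h for h in res.history if h[0] == res.selected_features][0][1]
    mat = np.column_stack([full_mse, sel_mse])
    _, p = friedman_test(mat)
    if p < cfg.elimination_alpha:
        assert not nemenyi_posthoc(mat, cfg.elimination_alpha)[0, 1]


def test_elimination_duplicate_target_copies_terminate():
    frames, y = _toy_frames(n_patients=12, days=8, n_noise=0)
    frames["signal2"] = frames["signal"]
    cfg = ModelConfig(**FAST, cv_folds_assess=4)
    res = backward_eliminate(frames, y, cfg.grid[0], cfg,
                             features=["signal", "signal2"])
    assert len(res.selected_features) >= 1
    with pytest.raises(InputError):
        backward_eliminate(frames, y, cfg.grid[0], cfg, features=["signal"])
    with pytest.raises(ConfigError):
        ModelConfig(elimination_alpha=1.5).validate()


def test_linear_baseline_learns_signal():
    frames, y = _toy_frames(noise=0.05)
    _, predict_fn = fit_linear_baseline(frames, y)
    preds = predict_fn(frames)
    assert np.corrcoef(preds["score"], y)[0, 1] > 0.9


def test_importances_rank_signal_over_noise():
    frames, y = _toy_frames(n_patients=16, days=10, n_noise=3, noise=0.02)
    cfg = ModelConfig(**FAST)
    imp = feature_importances(frames, y, cfg.grid[0], cfg,
                              ["signal", "noise0", "noise1", "noise2"])
    assert imp.idxmax() == "signal"


def test_model_bundle_roundtrip(tmp_path):
    from postop_recovery.model import load_model, save_model

    frames, y = _toy_frames(noise=0.05)
    cfg = ModelConfig(**FAST)
    model = train_final(frames, y, cfg.grid[0], cfg)
    save_model(model, tmp_path / "bundle")
    back = load_model(tmp_path / "bundle")
    assert back.feature_names == model.feature_names
    np.testing.assert_array_equal(predict(back, frames)["score"],
                                  predict(model, frames)["score"])
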