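"""Daily feature extraction: hand-computed examples, brute-force oracle
agreement on random series, spectral band localization, missingness."""

import numpy as np
import pandas as pd
import pytest

import _oracles as oracle
from postop_recovery.features import (FEATURE_NAMES, activity_daily,
                                      circadian_day_night, circadian_peak_nadir,
                                      daily_vital_stats, delta_features,
                                      detect_exercise_bouts,
                                      extract_daily_features,
                                      heart_rate_recovery, hr_by_context,
                                      hrv_frequency_domain, hrv_time_domain,
                                      pearson_screen, resting_heart_rate)
from postop_recovery.reference import base_profile

from conftest import series_from_seconds


# ---------------------------------------------------------------- vital stats

def test_daily_vital_stats_hand_values():
    sec = np.arange(0, 86400, 60)
    constant = series_from_seconds(sec, np.full(sec.size, 70.0))
    assert daily_vital_stats(constant, 0) == (70.0, 0.0)

    alternating = series_from_seconds(sec, np.where(np.arange(sec.size) % 2, 80.0, 60.0))
    mean, var = daily_vital_stats(alternating, 0)
    assert mean == pytest.approx(70.0)
    assert var == pytest.approx(100.0)  # population convention


def test_daily_vital_stats_missing_on_sparse_day():
    sec = np.arange(0, 3600, 60)  # one hour of data, default 30% threshold
    series = series_from_seconds(sec, np.full(sec.size, 70.0))
    assert np.isnan(daily_vital_stats(series, 0)[0])
    assert np.isnan(daily_vital_stats(series, 3)[0])  # empty day


# ------------------------------------------------------------------ rest / circ

def test_resting_heart_rate_decile():
    sec = np.arange(10) * 600.0
    hr = series_from_seconds(sec, np.arange(55.0, 65.0))
    inactive = series_from_seconds(sec, np.zeros(10))
    # 10 inactive samples -> lowest decile is the single lowest value
    assert resting_heart_rate(hr, inactive, 0) == 55.0

    fully_active = series_from_seconds(sec, np.full(10, 8.0))
    assert np.isnan(resting_heart_rate(hr, fully_active, 0))


def test_resting_heart_rate_constant_inactive_day():
    sec = np.arange(0, 86400, 300)
    hr = series_from_seconds(sec, np.full(sec.size, 60.0))
    act = series_from_seconds(sec, np.zeros(sec.size))
    assert resting_heart_rate(hr, act, 0) == 60.0


def test_circadian_day_night_forced_values():
    sec = np.arange(0, 86400, 600)
    hours = sec / 3600.0
    hr = np.where((hours >= 8) & (hours < 22), 80.0, 70.0)
    series = series_from_seconds(sec, hr)
    assert circadian_day_night(series, 0) == pytest.approx(10.0)

    constant = series_from_seconds(sec, np.full(sec.size, 72.0))
    assert circadian_day_night(constant, 0) == pytest.approx(0.0)

    night_only = series_from_seconds(sec[hours < 6], hr[hours < 6])
    assert np.isnan(circadian_day_night(night_only, 0))


def test_circadian_peak_nadir():
    sec = np.arange(0, 86400, 600)
    hourly = 60.0 + (sec // 3600) % 24  # hourly means 60..83
    series = series_from_seconds(sec, hourly.astype(float))
    assert circadian_peak_nadir(series, 0) == pytest.approx(23.0)
    constant = series_from_seconds(sec, np.full(sec.size, 70.0))
    assert circadian_peak_nadir(constant, 0) == pytest.approx(0.0)
    single_hour = series_from_seconds(sec[sec < 3600], hourly[sec < 3600].astype(float))
    assert np.isnan(circadian_peak_nadir(single_hour, 0))


# ----------------------------------------------------------------------- HRV

def test_hrv_time_domain_hand_values():
    series = series_from_seconds([0, 1, 2], [800.0, 900.0, 800.0])
    sdnn, rmssd, pnn50 = hrv_time_domain(series, 0, min_intervals=3)
    assert sdnn == pytest.approx(47.14, abs=0.01)
    assert rmssd == pytest.approx(100.0)
    assert pnn50 == pytest.approx(100.0)

    constant = series_from_seconds(np.arange(20), np.full(20, 850.0))
    assert hrv_time_domain(constant, 0) == (0.0, 0.0, 0.0)

    two = series_from_seconds([0, 1], [800.0, 900.0])
    assert np.isnan(hrv_time_domain(two, 0, min_intervals=10)[0])


def test_hrv_time_domain_matches_bruteforce_on_random_series():
    rng = np.random.default_rng(1234)
    for _ in range(100):
        n = rng.integers(10, 60)
        vals = rng.uniform(600, 1100, n)
        series = series_from_seconds(np.arange(n, dtype=float), vals)
        got = hrv_time_domain(series, 0, min_intervals=2)
        want = oracle.sdnn_rmssd_pnn50(list(vals))
        np.testing.assert_allclose(got, want, rtol=1e-10)


@pytest.mark.parametrize("freq,band", [(0.25, "hf"), (0.10, "lf")])
def test_hrv_frequency_band_localization(freq, band):
    """A pure sinusoidal IBI modulation concentrates >= 95% of the LF+HF
    power in its own band."""
    t = np.arange(0, 3600.0, 0.8)
    ibi = 850.0 + 40.0 * np.sin(2 * np.pi * freq * t)
    series = series_from_seconds(t, ibi)
    vlf, lf, hf, ratio = hrv_frequency_domain(series, 0)
    share = {"hf": hf / (lf + hf), "lf": lf / (lf + hf)}[band]
    assert share >= 0.95
    if band == "lf":
        assert ratio > 1.0
    else:
        assert ratio < 1.0


def test_hrv_frequency_constant_and_insufficient():
    t = np.arange(0, 3600.0, 0.8)
    constant = series_from_seconds(t, np.full(t.size, 850.0))
    vlf, lf, hf, ratio = hrv_frequency_domain(constant, 0)
    assert lf < 1e-12 and hf < 1e-12
    assert np.isnan(ratio)  # hf = 0 -> ratio undefined
    short = series_from_seconds(np.arange(0, 100.0), np.full(100, 850.0))
    assert np.isnan(hrv_frequency_domain(short, 0)[0])


# ------------------------------------------------------------ bouts and HRR

def _bout_trace(peak=140.0, base=80.0):
    """3-min ramp to the peak then exponential recovery, 1-s samples."""
    t = np.arange(0, 1200.0)
    hr = np.full(t.size, base)
    ramp = (t >= 300) & (t < 480)
    hr[ramp] = base + (peak - base) * (t[ramp] - 300) / 180.0
    decay = t >= 480
    hr[decay] = base + (peak - base) * np.exp(-(t[decay] - 480) / 90.0)
    return series_from_seconds(t, hr)


def test_bout_detection_threshold():
    series = _bout_trace(peak=111.0)  # age 60 -> threshold 112
    assert detect_exercise_bouts(series, 60, 0) == []
    series = _bout_trace(peak=140.0)
    bouts = detect_exercise_bouts(series, 60, 0)
    assert len(bouts) == 1
    assert bouts[0].peak_hr == pytest.approx(140.0)


def test_two_bouts_beyond_refractory_gap():
    t = np.arange(0, 7200.0)
    hr = np.full(t.size, 80.0)
    hr[(t >= 1000) & (t < 1100)] = 130.0
    hr[(t >= 5000) & (t < 5100)] = 135.0
    series = series_from_seconds(t, hr)
    bouts = detect_exercise_bouts(series, 60, 0)
    assert len(bouts) == 2
    # within the refractory gap the two elevations merge into one bout
    hr2 = np.full(t.size, 80.0)
    hr2[(t >= 1000) & (t < 1100)] = 130.0
    hr2[(t >= 1250) & (t < 1350)] = 135.0
    merged = detect_exercise_bouts(series_from_seconds(t, hr2), 60, 0)
    assert len(merged) == 1


def test_heart_rate_recovery_hand_values():
    t = np.arange(0, 400.0)
    base = 140.0 - 0.25 * t  # linear fall: -15 at 60 s, -30 at 120 s
    series = series_from_seconds(t + 1000, base)
    hr_full = series_from_seconds(
        np.arange(0, 2000.0),
        np.concatenate([np.full(1000, 80.0), base, np.full(600, 80.0)]))
    bouts = detect_exercise_bouts(hr_full, 60, 0)
    hrr1, hrr2, hrr_time = heart_rate_recovery(bouts)
    assert hrr1 == pytest.approx(15.0)
    assert hrr2 == pytest.approx(30.0)
    assert hrr_time == pytest.approx(40.0)  # first sample 10 bpm below peak


def test_heart_rate_recovery_frozen_peak_and_no_bouts():
    t = np.arange(0, 1000.0)
    hr = np.where((t >= 200) & (t < 600), 140.0, 80.0)
    bouts = detect_exercise_bouts(series_from_seconds(t, hr), 60, 0)
    hrr1, hrr2, hrr_time = heart_rate_recovery(bouts)
    assert hrr1 == pytest.approx(0.0)   # HR frozen at the peak
    assert hrr2 == pytest.approx(0.0)
    assert np.isnan(hrr_time)           # never fell 10 bpm in the window
    assert heart_rate_recovery([]) == pytest.approx(
        (np.nan, np.nan, np.nan), nan_ok=True)


def test_hrr_matches_bruteforce_on_random_traces():
    rng = np.random.default_rng(77)
    for _ in range(100):
        peak = rng.uniform(120, 160)
        tau = rng.uniform(40, 200)
        t = np.arange(0, 300.0, rng.choice([1.0, 5.0, 15.0]))
        y = 80.0 + (peak - 80.0) * np.exp(-t / tau)
        from postop_recovery.features import ExerciseBout
        bout = ExerciseBout(start_s=0.0, peak_time_s=0.0, peak_hr=peak,
                            post_peak=pd.Series(y, index=t))
        hrr1, hrr2, hrr_time = heart_rate_recovery([bout])
        assert hrr1 == pytest.approx(
            oracle.hrr_from_trace(peak, list(t), list(y), 60.0), abs=1e-9)
        assert hrr2 == pytest.approx(
            oracle.hrr_from_trace(peak, list(t), list(y), 120.0), abs=1e-9)
        want_time = oracle.hrr_time_from_trace(peak, list(t), list(y))
        if want_time is None:
            assert np.isnan(hrr_time)
        else:
            assert hrr_time == pytest.approx(want_time, abs=1e-9)


# ------------------------------------------------------------------- context

def test_hr_by_context_forced_split():
    sec = np.arange(0, 86400, 300.0)
    high = (sec / 86400) < 0.5
    hr = series_from_seconds(sec, np.where(high, 100.0, 70.0))
    actcount = series_from_seconds(sec, np.where(high, 3000.0, 100.0))
    out = hr_by_context(hr, {"actcount": actcount}, 0)
    assert out["hr_high_actcount"] == pytest.approx(100.0)
    assert out["hr_low_actcount"] == pytest.approx(70.0)
    assert np.isnan(out["hr_walking"])  # context absent that day

    constant = series_from_seconds(sec, np.full(sec.size, 80.0))
    active = series_from_seconds(sec, high.astype(float))
    out = hr_by_context(constant, {"active": active}, 0)
    assert out["hr_active_minus_inactive"] == pytest.approx(0.0)


def test_context_means_match_bruteforce(one_patient_streams):
    patient, streams, _ = one_patient_streams
    day = 5
    ctx = hr_by_context(streams.wrist_hr, {"active": streams.wrist_pct_active}, day)
    start = pd.Timestamp("2000-01-01") + pd.Timedelta(days=day)
    end = start + pd.Timedelta(days=1)
    sel = streams.wrist_hr[(streams.wrist_hr.index >= start)
                           & (streams.wrist_hr.index < end)]
    active = streams.wrist_pct_active
    lab_series = active[(active.index >= start) & (active.index < end)]
    labels = np.interp(
        (sel.index - start).total_seconds(),
        (lab_series.index - start).total_seconds(), lab_series.to_numpy()) > 0.5
    want = oracle.context_means(sel.to_numpy(), labels)
    assert ctx["hr_active"] == pytest.approx(want[True])
    assert ctx["hr_inactive"] == pytest.approx(want[False])


# ------------------------------------------------------------------ activity

def test_activity_daily_full_upright_day(one_patient_streams):
    _, streams, _ = one_patient_streams
    import dataclasses

    sec = np.arange(0, 86400, 600.0)
    posture = series_from_seconds(sec, np.ones(sec.size))
    s = dataclasses.replace(streams, chest_posture=posture)
    assert activity_daily(s, 0)["upright_hours"] == pytest.approx(24.0)


def test_activity_daily_step_sum_and_missing_wrist(one_patient_streams):
    _, streams, _ = one_patient_streams
    import dataclasses

    sec = np.arange(0, 86400, 60.0)
    incs = np.zeros(sec.size)
    incs[100:200] = 1158.0 / 100
    steps = series_from_seconds(sec, incs)
    s = dataclasses.replace(streams, wrist_steps=steps)
    assert activity_daily(s, 0)["steps"] == pytest.approx(1158.0)

    empty = pd.Series([], index=pd.DatetimeIndex([]), dtype=float)
    bare = dataclasses.replace(
        streams, **{ch: empty for ch in (
            "wrist_steps", "wrist_walkspeed", "wrist_actcount",
            "wrist_pct_active", "wrist_sedentary", "wrist_aee")})
    out = activity_daily(bare, 0)
    assert np.isnan(out["steps"]) and np.isnan(out["pct_active"])
    assert not np.isnan(out["upright_hours"])  # chest still present


# -------------------------------------------------------------------- deltas

def test_delta_features_contract():
    frames = pd.DataFrame({
        "patient_id": ["A"] * 3 + ["B"] * 2,
        "day": [0, 1, 2, 0, 1],
        "steps": [100.0, 150.0, np.nan, 50.0, 70.0],
    }).assign(**{c: np.nan for c in FEATURE_NAMES if c != "steps"})
    out = delta_features(frames)
    a = out[out.patient_id == "A"].set_index("day")
    assert np.isnan(a.loc[0, "delta_steps"])        # first day: no predecessor
    assert a.loc[1, "delta_steps"] == pytest.approx(50.0)
    assert np.isnan(a.loc[2, "delta_steps"])        # current value missing
    b = out[out.patient_id == "B"].set_index("day")
    assert b.loc[1, "delta_steps"] == pytest.approx(20.0)


def test_delta_example_upright_decrease():
    """An upright-hours decrease of 0.08 across consecutive days yields
    delta -0.08."""
    cols = {c: np.nan for c in FEATURE_NAMES}
    frames = pd.DataFrame([
        {"patient_id": "A", "day": 7, **{**cols, "upright_hours": 0.85}},
        {"patient_id": "A", "day": 8, **{**cols, "upright_hours": 0.77}},
    ])
    out = delta_features(frames)
    assert out.set_index("day").loc[8, "delta_upright_hours"] == pytest.approx(-0.08)


# ------------------------------------------------------------------- pearson

def test_pearson_screen_identity_and_noise(small_profiles):
    rng = np.random.default_rng(5)
    rows = []
    for pid, prof in small_profiles.items():
        for d in range(21):
            if np.isnan(prof.scores[d]):
                continue
            rows.append({"patient_id": pid, "day": d,
                         "identical": prof.scores[d],
                         "negated": -prof.scores[d],
                         "noise": rng.normal()})
    frames = pd.DataFrame(rows)
    r = pearson_screen(frames, small_profiles)
    assert r["identical"] == pytest.approx(1.0)
    assert r["negated"] == pytest.approx(-1.0)
    assert abs(r["noise"]) < 0.2


def test_pearson_independent_noise_large_n():
    rng = np.random.default_rng(8)
    from postop_recovery.reference import base_profile

    prof = base_profile(8, 999)
    frames = pd.DataFrame({
        "patient_id": "A", "day": np.arange(1000),
        "noise": rng.normal(size=1000),
        "constant": np.ones(1000),
    })
    r = pearson_screen(frames, {"A": prof})
    assert abs(r["noise"]) < 0.1
    assert np.isnan(r["constant"])  # zero variance


# -------------------------------------------------------- missingness frame

def test_missingness_propagates_to_that_day_only(one_patient_streams):
    """Deleting one day's raw data blanks that day's features and no
    other's."""
    import dataclasses

    patient, streams, _ = one_patient_streams
    cut = {}
    start = pd.Timestamp("2000-01-01") + pd.Timedelta(days=4)
    end = start + pd.Timedelta(days=1)
    for name, series in streams.channels().items():
        cut[name] = series[(series.index < start) | (series.index >= end)]
    gutted = dataclasses.replace(streams, **cut)
    frames = extract_daily_features(gutted, patient.age, 7,
                                    patient_id=patient.patient_id)
    reference = extract_daily_features(streams, patient.age, 7,
                                       patient_id=patient.patient_id)
    day4 = frames[frames.day == 4].drop(columns=["patient_id", "day"])
    assert day4.isna().all().all()
    for d in (3, 5):
        got = frames[frames.day == d].drop(columns=["patient_id", "day"])
        want = reference[reference.day == d].drop(columns=["patient_id", "day"])
        pd.testing.assert_frame_equal(got.reset_index(drop=True),
                                      want.reset_index(drop=True))


def test_units_and_bounds(one_patient_streams):
    patient, streams, _ = one_patient_streams
    frames = extract_daily_features(streams, patient.age, 14,
                                    patient_id=patient.patient_id)
    assert frames["pnn50"].dropna().between(0, 100).all()
    assert frames["upright_hours"].dropna().between(0, 24).all()
    assert frames["sedentary_hours"].dropna().between(0, 24).all()
    for col in ("hr_mean", "rhr", "hr_walking"):
        assert frames[col].dropna().between(25, 220).all()
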