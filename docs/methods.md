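# Methods

This note documents the models, the synthetic data, the numerical choices
and the limitations of the package.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Reference recovery profiles

Recovery is summarised by a unitless daily score.  The complication-free
profile is the anchored exponential R(t) = 2 − e^(−kt) with
k = ln 5 / LOS, the minimal form satisfying the three anchors: 1.0 at
surgery (day 0), 1.8 at discharge (day LOS), plateau 2.0 ("fully
recovered") as t → ∞.  The profile continues past discharge with the same
rate: home recovery is treated as the continuation of the same process.
Days are calendar days with day 0 the surgery day; streams and profiles
share this indexing.

Complication drops are additive per-event deficits on top of the
baseline.  For an event of Clavien–Dindo grade g on day e:

* magnitude m(g): 0.02 for CD 1–2, 0.04 for CD 3, 0.06 for CD 4;
* lead l(g): 2 days for CD 4, 1 day otherwise;
* the deficit is 0 on day e − l − 1, rises linearly to m on day e (so
  every day of the lead window sits strictly below baseline — the score
  is designed to *decrease before* the clinical event), and decays as
  m·e^(−k(t−e)) afterwards.

The post-event decay at the profile's own rate is algebraically identical
to "resume the anchored exponential from the dropped value", so late
complications still converge to the plateau.  Deficits of overlapping
events add.  CD 5 (death) has no defined drop; the profile is truncated
(NaN) from the event day and the generator stops that patient's streams.
Early severe events can push the score below 1.0.

Default profile horizon: 21 days, the wrist-band wear period, so every
day with features has a target.

## Synthetic cohort and streams

The generator emulates a 125-patient major-abdominal-surgery cohort
monitored by a chest patch (14 days) and a wrist band (21 days).  Cohort
marginals target the published composition of such a cohort: gender
45.6% female, surgery-type mix over six categories, ~33.6% of patients
with ≥ 1 complication (1–3 per patient), lognormal LOS with median 8 and
mean ≈ 11 days, age ≈ N(62, 10).

Each day's signal parameters are linear in that day's latent score s
(the engineered reference profile, *after* drops — so the anticipatory
pre-complication dip in activity and circadian amplitude is inherited
from the profile rather than bolted on):

| daily parameter | value at s | default noise (1 sd/day) |
|---|---|---|
| steps | 20 + 1800 (s − 1) | 150 |
| upright hours | 6 (s − 1), clipped to [0, 12] | 0.3 |
| day–night HR difference | 2 + 10 (s − 1) bpm | 1.5 |
| HRR-1 | 4 + 15 (s − 1) bpm | 2 |
| resting HR | 80 − 5 (s − 1) bpm | 4 (day-to-day wander) |

Magnitudes were chosen once for plausibility against a published
single-patient feature table (steps on the order of 10–100/day right
after surgery and ~1000–1500/day mid-recovery, upright hours below 1
early on, day–night differences of ~2–9 bpm, HRR-1 of ~8–16 bpm).  The
weak resting-HR slope plus a 4 bpm/day wander reproduces the reported
structure in which activity, circadian and HRR features correlate
strongly with recovery while mean-HR/RR features correlate weakly.
Respiration rate is latent-independent by construction and serves as the
designated uninformative channel.  A global `noise_scale` multiplies all
per-channel noises (0 gives the noise-free regime used for parameter
recovery checks).

Within a day, a deterministic schedule places a night (00–06, HR at
rest − amp/2), a day plateau (08–22, rest + amp/2, linear transitions), an
upright block from 10:00, a walking block from 11:00 (duration
steps / 6000 steps·h⁻¹, walking elevates HR by 10 bpm), and — once
s ≥ 1.15, the activity-onset threshold — one exercise bout at 14:00: a
3-min HR ramp to 0.78·(220 − age) followed by exponential recovery whose
time constant is solved from the day's HRR-1 target.  The 0.78 peak
fraction leaves margin above the 0.70 qualification threshold so a bout
contains several samples even at coarse storage cadences.  Inter-beat
intervals are 60000/HR plus 20 ms jitter.  Wrist channels lose one
charging gap per day (uniform start, 30–90 min, contained within the
day).  Heart rate is clipped to [25, 220] bpm.

What the generator does **not** emulate: PPG/accelerometer waveforms and
beat-detection artifacts, posture misclassification, sensor detachment
beyond the daily gap, weekend/weekday structure, medication effects, or
any real covariance between HRV spectra and recovery.  Passing tests
therefore demonstrate that the pipeline recovers a latent daily state
encoded in channel-level statistics — not clinical validity on real
patients.

## Feature extraction

One row per patient-day.  Respiration features come from the chest patch
(more reliable at the ribcage), heart-rate-derived features from the
wrist band (longer coverage); both wirings are defaults, not hard-coded.
Conventions and thresholds:

* variance and SDNN use the population convention (divide by n);
* day window 08:00–22:00, night window 00:00–06:00 (local clock);
* HRV bands: VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.40 Hz; IBI series
  cubic-interpolated to an even grid (4 Hz default), Welch periodogram
  with 5-min segments and 50% overlap; LF/HF undefined when HF is
  numerically zero (< 1e−12);
* resting HR: mean of the lowest decile of HR samples in inactive
  periods (chest activity level ≤ 3, or activity counts below 2000 when
  the chest is off);
* exercise bouts: contiguous samples with HR ≥ 0.7·(220 − age), episodes
  closer than 5 min merged; HRR-n by linear interpolation of the
  post-peak trace at n minutes; HRR-time is the first sample ≥ 10 bpm
  below the peak; a day without bouts leaves all three missing
  ("inactive" days);
* HR-context splits: activity counts at 2000, chest activity level at 3;
* a channel-day with < 30% of expected samples (or, for HRV, < 10
  intervals / < 2 Welch segments of coverage) is missing; percent-active,
  sedentary and upright hours scale the observed fraction to 24 h so
  charging gaps do not deflate them;
* delta features: value(day) − value(day − 1), missing when either
  operand is missing and on each patient's first day (the source material
  is inconsistent on the first-day convention; missing is the contract
  here).

## Split, model, elimination

The train/test split draws 10,000 random 2/3 partitions and keeps the one
maximizing the product of p-values: chi-square (uncorrected by default;
Yates optional) for gender, complication count (0–3, ordered) and surgery
type; two-sample KS (asymptotic) for age and LOS.  Categories absent from
the cohort are dropped; an undefined statistic contributes a neutral
p = 1.  Train size is floor(2n/3): 83/42 at n = 125.  The search's
vectorized statistics are cross-checked against scipy's
`chi2_contingency`/`ks_2samp` on the chosen partition.

Features are z-scored with training-split means and population sds
(constant features pass through; missing stays missing).  The
standardization is fitted once on the full training split and reused
inside CV folds — gradient-boosted trees are invariant to monotone
per-feature scaling, and the train/test boundary is what matters for
leakage.  Each patient-day is an independent sample; the model never
sees patient identity or day index.  CV folds group all days of a
patient (GroupKFold) to avoid within-patient leakage; an ungrouped mode
exists for fidelity experiments.  Tuning minimizes mean 5-fold validation
MSE over a small grid (learning rate {0.05, 0.1} × depth {2, 3} by
default; ties keep the first grid point).  The final booster uses
native missing-value routing and early stopping (30 rounds) on a held-out
10% of training patients.

Backward elimination repeatedly drops the feature with the lowest
total-gain importance (recomputed each step), comparing each reduced
model's 10-fold MSE and SRCC vectors against the all-features model: a
Friedman test over all models so far (own implementation from the rank
formulas, tie-corrected, valid from k = 2; checked against scipy for
k ≥ 3) and, when significant at α = 0.05, a Nemenyi post hoc on the
reduced-vs-full pair (critical difference from the studentized-range
distribution).  Elimination stops before the first significant
difference on either metric and never returns an empty set.  A
ridge-with-imputation linear baseline is provided behind the same
prediction interface as a sanity comparison.

Evaluation: MSE and Spearman rank correlation over all patient-days,
plus the mean absolute prediction error on each patient's discharge day.

## Clinical comparison

Group profiles pool train and test predictions (the bands describe the
monitored population), split at LOS 8 days — the training-group median —
with per-day mean and 10th/90th percentiles (linear interpolation between
order statistics).  The per-day rule formalizing the visual band
comparison: *fast* requires the score at or above the short-LOS p10 and
strictly above the long-LOS p90; *slow* requires at or below the long-LOS
p90 and strictly below the short-LOS p10; everything else is
*indeterminate* (the overlap region).  Discharge readiness is the first
day with predicted score ≥ 1.8, with a flag when the recorded discharge
day's score is below the threshold.  Decline flags mark days ending a
strictly decreasing run of ≥ 3 days (ties break runs).  The
interpretability table renders bout-free days as "inactive", missing
deltas as "-", and HRR-1 below 12 bpm with an asterisk.

## Problem sizes and runtime

Device storage cadences (8 s chest HR, 1 s chest RR and wrist) are the
generator defaults and are exercised in unit tests on single patients.
Cohort-scale runs (125 patients × 21 days × ~12 channels) use coarser
storage cadences — 32 s chest, 30 s wrist, 2 Hz Welch grid — set in the
run configs; at these cadences every feature remains computable and the
pipeline processes one patient at a time, never holding more than one
patient's raw streams in memory.  The full 125-patient analysis
(10,000-candidate split, tuning, elimination, final training) runs in
roughly 7 minutes on one CPU; `scripts/acceptance.py` (two full
pipelines) in 10–15 minutes.

## Known limitations

* The reference profile is an engineered construct; all performance
  statements are relative to it, not to clinical ground truth.
* Readmission is annotated in the cohort but has no score mechanic.
* The drop shape inside the lead window (linear ramp) and the
  post-discharge continuation (same exponential) are modelling choices;
  only the anchors and drop magnitudes are externally fixed.
* Gain-based importances fragment across collinear features; rankings of
  individual collinear features are not stable and the package's checks
  use the Pearson screen plus grouped gain instead.
* Alarm thresholds / confidence bands for the decision aids are out of
  scope.
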