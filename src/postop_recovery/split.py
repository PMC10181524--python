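"""Covariate-balanced train/test split by random search.

The cohort is partitioned many times at a fixed fraction; for every
candidate partition a chi-square test compares the categorical variables
(gender, complication count, surgery type) and a two-sample
Kolmogorov-Smirnov test compares the numerical variables (age, LOS)
between the two sides.  The partition maximizing the product of the
per-variable p-values is kept: the least-distinguishable split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .reference import InputError

__all__ = ["SplitResult", "balanced_split", "split_report", "cohort_frame",
           "DEFAULT_CATEGORICAL", "DEFAULT_NUMERICAL"]

DEFAULT_CATEGORICAL = ("gender", "n_complications", "surgery_type")
DEFAULT_NUMERICAL = ("age", "los")


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    balance_score: float                  # product of per-variable p-values
    per_variable_p: dict = field(default_factory=dict)
    n_candidates: int = 0
    seed: int | None = None
    candidate_scores: list | None = None


def cohort_frame(cohort) -> pd.DataFrame:
    """Tabular view of the cohort variables used for balancing."""
    return pd.DataFrame({
        "patient_id": [p.patient_id for p in cohort],
        "age": [p.age for p in cohort],
        "gender": [p.gender for p in cohort],
        "surgery_type": [p.surgery_type for p in cohort],
        "los": [p.los for p in cohort],
        "n_complications": [p.n_complications for p in cohort],
    })


def _chi2_p_fast(codes: np.ndarray, n_cats: int, in_train: np.ndarray,
                 correction: bool) -> float:
    """Chi-square homogeneity p-value from pre-factorized category codes.

    Empty categories are dropped; an undefined statistic (fewer than two
    populated categories, a zero expected count, or an empty side) scores
    a neutral p of 1 so it does not veto the candidate."""
    c1 = np.bincount(codes[in_train], minlength=n_cats).astype(float)
    c2 = np.bincount(codes[~in_train], minlength=n_cats).astype(float)
    tot = c1 + c2
    keep = tot > 0
    c1, c2, tot = c1[keep], c2[keep], tot[keep]
    if len(tot) < 2 or c1.sum() == 0 or c2.sum() == 0:
        return 1.0
    n = tot.sum()
    e1 = tot * c1.sum() / n
    e2 = tot * c2.sum() / n
    if (e1 == 0).any() or (e2 == 0).any():
        return 1.0
    d1, d2 = np.abs(c1 - e1), np.abs(c2 - e2)
    if correction and len(tot) == 2:
        d1 = np.maximum(d1 - 0.5, 0.0)
        d2 = np.maximum(d2 - 0.5, 0.0)
    stat = float(np.sum(d1 ** 2 / e1) + np.sum(d2 ** 2 / e2))
    return float(stats.chi2.sf(stat, len(tot) - 1))


def score_partition(cohort, train_ids, categorical_vars=DEFAULT_CATEGORICAL,
                    numerical_vars=DEFAULT_NUMERICAL,
                    yates_correction: bool = False) -> tuple[float, dict]:
    """Balance score of one explicit partition, via the scipy contingency
    and KS routines (independent of the search's fast path)."""
    df = cohort_frame(cohort)
    in_train = df["patient_id"].isin(set(train_ids)).to_numpy()
    pvals = {}
    for v in categorical_vars:
        table = pd.crosstab(df[v].to_numpy(), in_train)
        table = table.loc[table.sum(axis=1) > 0]
        if table.shape[0] < 2 or table.shape[1] < 2:
            pvals[v] = 1.0
            continue
        try:
            pvals[v] = float(stats.chi2_contingency(
                table.to_numpy(), correction=yates_correction)[1])
        except ValueError:
            pvals[v] = 1.0
    for v in numerical_vars:
        vals = df[v].to_numpy(dtype=float)
        if in_train.all() or not in_train.any():
            pvals[v] = 1.0
        else:
            pvals[v] = float(stats.ks_2samp(
                vals[in_train], vals[~in_train], method="asymp").pvalue)
    return float(np.prod(list(pvals.values()))), pvals


def balanced_split(cohort, categorical_vars=DEFAULT_CATEGORICAL,
                   numerical_vars=DEFAULT_NUMERICAL, fraction: float = 2 / 3,
                   n_candidates: int = 10_000, seed: int = 0,
                   yates_correction: bool = False,
                   return_scores: bool = False) -> SplitResult:
    """Random-search for the best-balanced partition.

    |train| = floor(fraction * n).  Deterministic given the seed; ties on
    the p-value product keep the earliest candidate.  With
    ``return_scores`` the result carries every candidate's score in
    ``result.candidate_scores`` for re-scan assertions.
    """
    if n_candidates < 1:
        raise InputError("n_candidates must be >= 1")
    if not 0 < fraction <= 1:
        raise InputError("fraction must be in (0, 1]")
    df = cohort_frame(cohort)
    n = len(df)
    n_train = int(np.floor(fraction * n))
    rng = np.random.default_rng(seed)

    cats = {}
    for v in categorical_vars:
        codes, uniques = pd.factorize(df[v].to_numpy())
        cats[v] = (codes, len(uniques))
    num_values = {v: df[v].to_numpy(dtype=float) for v in numerical_vars}
    ids = df["patient_id"].to_numpy()

    best = None
    scores = []
    for _ in range(n_candidates):
        perm = rng.permutation(n)
        in_train = np.zeros(n, dtype=bool)
        in_train[perm[:n_train]] = True
        pvals = {}
        for v, (codes, n_cats) in cats.items():
            pvals[v] = _chi2_p_fast(codes, n_cats, in_train, yates_correction)
        for v, vals in num_values.items():
            if n_train in (0, n):
                pvals[v] = 1.0
            else:
                pvals[v] = float(stats.ks_2samp(
                    vals[in_train], vals[~in_train], method="asymp").pvalue)
        score = float(np.prod(list(pvals.values())))
        if return_scores:
            scores.append(score)
        if best is None or score > best[0]:
            best = (score, in_train.copy(), dict(pvals))

    score, in_train, pvals = best
    result = SplitResult(
        train_ids=list(ids[in_train]), test_ids=list(ids[~in_train]),
        balance_score=score, per_variable_p=pvals,
        n_candidates=n_candidates, seed=seed,
    )
    if return_scores:
        result.candidate_scores = scores
    return result


def split_report(result: SplitResult, cohort) -> pd.DataFrame:
    """Per-variable counts/percentages and means per split side, in the
    layout of a baseline-characteristics table."""
    df = cohort_frame(cohort).set_index("patient_id")
    sides = {"train": df.loc[result.train_ids], "test": df.loc[result.test_ids]}
    rows = []

    def count_row(label, mask_fn):
        counts = {s: int(mask_fn(d).sum()) for s, d in sides.items()}
        total = sum(counts.values())
        row = {"variable": label}
        for s in sides:
            pct = 100.0 * counts[s] / total if total else np.nan
            row[s] = f"{counts[s]} ({pct:.1f}%)"
        rows.append(row)

    count_row("Total patients", lambda d: np.ones(len(d), dtype=bool))
    for g in ("female", "male"):
        count_row(g.capitalize(), lambda d, g=g: d["gender"] == g)
    for k in range(4):
        label = f"Patients with {k} complication" + ("s" if k != 1 else "")
        count_row(label, lambda d, k=k: d["n_complications"] == k)
    for s_type in sorted(df["surgery_type"].unique()):
        count_row(f"Surgery: {s_type}", lambda d, s=s_type: d["surgery_type"] == s)
    for var in ("age", "los"):
        row = {"variable": f"{var.upper() if var == 'los' else var.capitalize()} (mean)"}
        for s, d in sides.items():
            row[s] = f"{d[var].mean():.1f}" if len(d) else "degenerate (empty side)"
        rows.append(row)
    return pd.DataFrame(rows)
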