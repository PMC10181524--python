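"""Friedman test and Nemenyi post hoc for comparing models across CV folds.

Implemented from the published rank formulas so they work for any number
of models k >= 2 (the two-model case arises at the first step of backward
feature elimination).

Friedman statistic with tie correction, for n blocks (folds) and k
treatments (models), using within-block average ranks R_ij:

    chi2_F = [ 12 / (n k (k+1)) * sum_j Rj^2 - 3 n (k+1) ] / C
    C      = 1 - sum_blocks sum_groups (t^3 - t) / (n k (k^2 - 1))

where Rj are rank sums and t the sizes of tied groups in a block; the
p-value is the chi-square upper tail with k - 1 degrees of freedom.

Nemenyi: two treatments differ when their average ranks differ by at least
the critical difference CD = q_alpha * sqrt(k (k+1) / (6 n)), with
q_alpha the alpha-level studentized-range quantile divided by sqrt(2).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["friedman_test", "nemenyi_critical_difference", "nemenyi_posthoc"]


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square and p-value for an (n_blocks, k_treatments)
    matrix of scores; ranks are computed within blocks, ties averaged."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 treatments")
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rank_sums ** 2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts ** 3 - counts))
    denom = 1.0 - ties / (n * k * (k ** 2 - 1))
    if denom <= 0:
        return 0.0, 1.0  # all blocks fully tied
    stat /= denom
    p = float(sps.chi2.sf(stat, k - 1))
    return float(stat), p


def nemenyi_critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """Minimum average-rank difference declared significant at alpha."""
    q = sps.studentized_range.ppf(1.0 - alpha, k, np.inf) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (6.0 * n)))


def nemenyi_posthoc(matrix: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Pairwise significance matrix (k x k bool) from average-rank
    differences against the Nemenyi critical difference."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    cd = nemenyi_critical_difference(k, n, alpha)
    diff = np.abs(mean_ranks[:, None] - mean_ranks[None, :])
    return diff >= cd
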