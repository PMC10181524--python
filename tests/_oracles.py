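"""Independent brute-force reimplementations used as oracles.

Deliberately naive (python loops, direct formulas) and kept separate from
the library code paths they check.
"""

import math

import numpy as np


def sdnn_rmssd_pnn50(intervals):
    n = len(intervals)
    mean = sum(intervals) / n
    sdnn = math.sqrt(sum((x - mean) ** 2 for x in intervals) / n)
    diffs = [intervals[i + 1] - intervals[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn50 = 100.0 * sum(1 for d in diffs if abs(d) > 50.0) / len(diffs)
    return sdnn, rmssd, pnn50


def hrr_from_trace(peak_hr, times, values, horizon):
    """Linear interpolation of the post-peak trace at the horizon."""
    for i in range(1, len(times)):
        if times[i] >= horizon:
            t0, t1 = times[i - 1], times[i]
            v0, v1 = values[i - 1], values[i]
            frac = (horizon - t0) / (t1 - t0) if t1 > t0 else 0.0
            return peak_hr - (v0 + frac * (v1 - v0))
    return None


def hrr_time_from_trace(peak_hr, times, values):
    for t, v in zip(times, values):
        if v <= peak_hr - 10.0:
            return t
    return None


def day_night_difference(hours, values, day_window=(8, 22), night_window=(0, 6)):
    day = [v for h, v in zip(hours, values) if day_window[0] <= h < day_window[1]]
    night = [v for h, v in zip(hours, values) if night_window[0] <= h < night_window[1]]
    if not day or not night:
        return None
    return sum(day) / len(day) - sum(night) / len(night)


def context_means(values, labels):
    by = {}
    for v, l in zip(values, labels):
        by.setdefault(l, []).append(v)
    return {l: sum(vs) / len(vs) for l, vs in by.items()}


def percentile_sorted(values, q):
    """Linear-interpolation percentile on sorted order statistics."""
    xs = sorted(values)
    pos = q / 100.0 * (len(xs) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    if lo == hi:
        return xs[lo]
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def friedman_chi2(matrix):
    """Rank statistic straight from the textbook formulas, ties averaged."""
    matrix = np.asarray(matrix, dtype=float)
    n, k = matrix.shape
    ranks = np.zeros_like(matrix)
    for i, row in enumerate(matrix):
        order = sorted(range(k), key=lambda j: row[j])
        j = 0
        while j < k:
            j2 = j
            while j2 + 1 < k and row[order[j2 + 1]] == row[order[j]]:
                j2 += 1
            avg = (j + j2) / 2.0 + 1.0
            for m in range(j, j2 + 1):
                ranks[i][order[m]] = avg
            j = j2 + 1
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums ** 2)) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in matrix:
        seen = {}
        for v in row:
            seen[v] = seen.get(v, 0) + 1
        ties += sum(t ** 3 - t for t in seen.values())
    denom = 1.0 - ties / (n * k * (k * k - 1))
    return stat / denom if denom > 0 else 0.0
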