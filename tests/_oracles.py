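"""Independent brute-force oracles used to validate the package's statistics.

Everything here is deliberately naive (enumeration, grid search, sliding
windows) and shares no code with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def grid_search_loglinear(times, ratios, slope_range=(-0.1, 0.01), n_grid=2001):
    """Minimize squared log-residuals over a (slope, intercept) grid.

    Two-pass refinement; returns (k, t_half) with k = -slope.
    """
    t = np.asarray(times, float)
    y = np.log(np.asarray(ratios, float))

    def sse(slope, intercept):
        return float(np.sum((y - (intercept + slope * t)) ** 2))

    lo, hi = slope_range
    best = None
    for _ in range(3):
        slopes = np.linspace(lo, hi, n_grid)
        for slope in slopes:
            # optimal intercept given slope is the mean residual
            intercept = float(np.mean(y - slope * t))
            err = sse(slope, intercept)
            if best is None or err < best[0]:
                best = (err, slope, intercept)
        width = (hi - lo) / 50
        lo, hi = best[1] - width, best[1] + width
    k = -best[1]
    return k, (math.log(2) / k if k > 0 else math.inf)


def sam_d_plain(values_a, values_b, s0):
    """Hand-rolled SAM d-statistic for one gene."""
    a = list(map(float, values_a))
    b = list(map(float, values_b))
    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ss = sum((x - ma) ** 2 for x in a) + sum((x - mb) ** 2 for x in b)
    s = math.sqrt((1 / na + 1 / nb) * ss / (na + nb - 2))
    return (ma - mb) / (s + s0)


def sam_null_enumeration(matrix, n_a, s0):
    """All C(n, n_a) label splits -> d-statistic matrix (splits x genes)."""
    matrix = np.asarray(matrix, float)
    n = matrix.shape[1]
    rows = []
    for combo in itertools.combinations(range(n), n_a):
        in_a = set(combo)
        d_row = [
            sam_d_plain(
                [g[j] for j in range(n) if j in in_a],
                [g[j] for j in range(n) if j not in in_a],
                s0,
            )
            for g in matrix
        ]
        rows.append(d_row)
    return np.array(rows)


def fisher_p_hypergeom(a, b, c, d):
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Table [[a, b], [c, d]]; sums P(x) over all tables with the same margins
    whose point probability does not exceed the observed one.
    """
    row1, col1, total = a + b, a + c, a + b + c + d

    def log_choose(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    def log_p(x):
        return (
            log_choose(col1, x)
            + log_choose(total - col1, row1 - x)
            - log_choose(total, row1)
        )

    lo = max(0, row1 - (total - col1))
    hi = min(row1, col1)
    p_obs = math.exp(log_p(a))
    p = 0.0
    for x in range(lo, hi + 1):
        px = math.exp(log_p(x))
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(1.0, p)


def ks_d_enumeration(sample1, sample2):
    """Max |ECDF1 - ECDF2| over all observed points."""
    s1 = sorted(sample1)
    s2 = sorted(sample2)
    best = 0.0
    for x in s1 + s2:
        f1 = sum(v <= x for v in s1) / len(s1)
        f2 = sum(v <= x for v in s2) / len(s2)
        best = max(best, abs(f1 - f2))
    return best


def mannwhitney_enumeration(sample1, sample2):
    """Exact two-sided Mann-Whitney by enumerating all rank arrangements.

    Returns (U1, two-sided p).  Assumes no ties across samples.
    """
    n1, n2 = len(sample1), len(sample2)
    combined = sorted(list(sample1) + list(sample2))
    ranks = {v: i + 1 for i, v in enumerate(combined)}
    u_obs = sum(ranks[v] for v in sample1) - n1 * (n1 + 1) / 2

    count_extreme = 0
    total = 0
    all_ranks = range(1, n1 + n2 + 1)
    mean_u = n1 * n2 / 2
    for combo in itertools.combinations(all_ranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-9:
            count_extreme += 1
        total += 1
    return u_obs, count_extreme / total


def scan_sliding_window(sequence, words):
    """Count windows of len(word) equal to any literal word; return positions."""
    width = len(words[0])
    hits = [
        i
        for i in range(len(sequence) - width + 1)
        if sequence[i : i + width] in words
    ]
    return len(hits), hits
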