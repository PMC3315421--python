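"""Independent brute-force reference implementations used only by tests.

Each oracle is written from the defining formula or an exhaustive procedure,
deliberately sharing no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


def ols_normal_equations(x, y):
    """Least squares by direct normal equations: returns (slope, intercept)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def percentile_sorted(values, q):
    """Linear-interpolation percentile computed from first principles."""
    v = sorted(values)
    n = len(v)
    pos = (q / 100.0) * (n - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def median_brute(values):
    v = sorted(values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])


def student_ttest_brute(a, b):
    """Equal-variance two-sample t from the textbook formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * stats.t.sf(abs(t), df)
    return t, df, p


def anova_sums_of_squares(groups):
    """One-way ANOVA F from explicit sum-of-squares accumulation."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_b / df_b) / (ss_w / df_w), df_b, df_w


def holm_sidak_stepdown(p_values):
    """Exhaustive step-down: walk sorted p's, apply the Sidak factor for the
    remaining hypothesis count, enforce monotonicity by explicit max over
    all previous steps."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    for rank, idx in enumerate(order):
        candidates = []
        for j in range(rank + 1):
            pj = p[order[j]]
            candidates.append(1.0 - (1.0 - pj) ** (m - j))
        adjusted[idx] = min(1.0, max(candidates))
    return adjusted


def average_linkage_brute(dist):
    """O(n^3) agglomeration with average linkage over a full distance matrix.

    Returns a list of merges as (frozenset_of_leaves_a, frozenset_of_leaves_b,
    height) in merge order.
    """
    n = dist.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    active = set(clusters)
    while len(active) > 1:
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            members_a, members_b = clusters[a], clusters[b]
            d = np.mean([dist[i, j] for i in members_a for j in members_b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        new_id = max(clusters) + 1
        clusters[new_id] = clusters[a] | clusters[b]
        active.discard(a)
        active.discard(b)
        active.add(new_id)
    return merges


def summary_from_raw(values):
    """(mean, sem, n) by hand."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n), n


def raw_data_with_summaries(mean, sd, n, rng):
    """Draws affine-adjusted to have exactly the given sample mean and sd."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
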