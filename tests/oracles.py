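"""Independent reference implementations used only to check the package.

Each oracle deliberately takes a different route from the implementation it
checks: local alignment by maximising global scores over all substring
pairs, Fisher by enumerating the column-margin hypergeometric, the
permutation test by exhaustive label enumeration, and BCa by a separate
re-derivation of the interval arithmetic.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm

NEG_INF = float("-inf")


def global_affine_score(a: str, b: str, score_pair, gap_open: float,
                        gap_extend: float) -> float:
    """Best global alignment score; a gap of length L costs open + L*extend."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last column was a match, 1 = gap in a, 2 = gap in b
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG_INF
        if i < len(a) and j < len(b):
            best = max(best, score_pair(a[i], b[j]) + rec(i + 1, j + 1, 0))
        if j < len(b):  # consume b, gap in a
            cost = gap_extend if state == 1 else gap_open + gap_extend
            best = max(best, -cost + rec(i, j + 1, 1))
        if i < len(a):  # consume a, gap in b
            cost = gap_extend if state == 2 else gap_open + gap_extend
            best = max(best, -cost + rec(i + 1, j, 2))
        return best

    return rec(0, 0, 0)


def local_score_by_enumeration(a: str, b: str, score_pair, gap_open: float,
                               gap_extend: float) -> float:
    """Smith-Waterman score as the max global score over all substring pairs."""
    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    s = global_affine_score(
                        a[i1:i2], b[j1:j2], score_pair, gap_open, gap_extend
                    )
                    best = max(best, s)
    return best


_fisher_cache: dict[tuple[int, int, int], tuple[int, tuple[int, ...]]] = {}


def fisher_by_column_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p enumerated over the column-margin hypergeometric."""
    m1, m2, n1 = a + c, b + d, a + b
    if m1 == 0 or m2 == 0 or n1 == 0 or c + d == 0:
        return 1.0
    key = (m1, m2, n1)
    if key not in _fisher_cache:
        k_min = max(0, n1 - m2)
        k_max = min(n1, m1)
        _fisher_cache[key] = (
            k_min,
            tuple(comb(m1, k) * comb(m2, n1 - k) for k in range(k_min, k_max + 1)),
        )
    k_min, nums = _fisher_cache[key]
    observed = nums[a - k_min]
    return sum(x for x in nums if x <= observed) / sum(nums)


def exact_permutation_p(control, group) -> float:
    """Exhaustive two-sample permutation p for |mean difference|."""
    pool = np.asarray(list(control) + list(group), float)
    n, ng = len(pool), len(group)
    observed = abs(np.mean(group) - np.mean(control))
    total = hits = 0
    for idx in combinations(range(n), ng):
        mask = np.zeros(n, bool)
        mask[list(idx)] = True
        stat = abs(pool[mask].mean() - pool[~mask].mean())
        hits += stat >= observed - 1e-12
        total += 1
    return hits / total


def bca_interval_reference(control, group, n_boot: int, seed: int,
                           level: float = 0.95) -> tuple[float, float]:
    """Re-derivation of the two-sample BCa interval, sharing only the
    documented resampling protocol (control index matrix first, then group)."""
    control = np.asarray(control, float)
    group = np.asarray(group, float)
    rng = np.random.default_rng(seed)
    ci = rng.integers(0, len(control), size=(n_boot, len(control)))
    gi = rng.integers(0, len(group), size=(n_boot, len(group)))
    deltas = group[gi].mean(axis=1) - control[ci].mean(axis=1)
    theta = group.mean() - control.mean()
    z0 = norm.ppf((deltas < theta).sum() / n_boot)
    jack = []
    for i in range(len(control)):
        jack.append(group.mean() - np.delete(control, i).mean())
    for i in range(len(group)):
        jack.append(np.delete(group, i).mean() - control.mean())
    jack = np.array(jack)
    diffs = jack.mean() - jack
    denom = (diffs**2).sum() ** 1.5
    a_hat = 0.0 if denom == 0 else (diffs**3).sum() / (6 * denom)
    alpha = 1 - level
    lo_p = norm.cdf(z0 + (z0 + norm.ppf(alpha / 2)) / (1 - a_hat * (z0 + norm.ppf(alpha / 2))))
    hi_p = norm.cdf(z0 + (z0 + norm.ppf(1 - alpha / 2)) / (1 - a_hat * (z0 + norm.ppf(1 - alpha / 2))))
    lo, hi = np.quantile(deltas, [lo_p, hi_p])
    return float(lo), float(hi)
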