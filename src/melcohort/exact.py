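"""Exact tests for small cohort tables.

Two primitives back the enrichment and predictor modules:

* Fisher's exact test on a 2x2 table, with a one-sided over-representation
  tail and the conventional two-sided "sum of tables no more probable than
  the observed one" definition, both evaluated on the hypergeometric
  distribution with fixed margins.
* An exact two-sided Mann-Whitney U test for small groups, computed from the
  full permutation distribution of the rank sum over all C(n, n1) group
  assignments. Ties are handled with midranks; the permutation distribution
  is built by dynamic programming over doubled (integer) ranks, which is
  equivalent to enumerating every labelling.

Both are deliberately independent of any omnibus statistics package call so
their tails can be verified against brute-force enumeration.
"""

from __future__ import annotations

from math import comb, sqrt

import numpy as np
from scipy import stats

__all__ = [
    "hypergeom_pmf",
    "fisher_one_sided_enrichment",
    "fisher_two_sided",
    "mannwhitney_exact_two_sided",
    "mannwhitney_p",
]

# probabilities within this relative factor of the observed table's are
# counted as "no more probable" (guards float noise in the two-sided sum)
_REL_EPS = 1.0 + 1e-7


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """P(X = k) drawing n from a population of N containing K successes."""
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def fisher_one_sided_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Upper-tail exact p for over-representation in the group.

    Table layout: a = altered in group, b = unaltered in group, c = altered
    in rest, d = unaltered in rest. The tail is P(X >= a) for X hypergeometric
    with population N = a+b+c+d, K = a+c successes and n = a+b draws.
    """
    N, K, n = a + b + c + d, a + c, a + b
    return float(sum(hypergeom_pmf(k, N, K, n) for k in range(a, min(n, K) + 1)))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact p: sum of all margin-fixed tables no more probable
    than the observed one (the definition used by R's fisher.test)."""
    N, K, n = a + b + c + d, a + c, a + b
    p_obs = hypergeom_pmf(a, N, K, n)
    lo, hi = max(0, n + K - N), min(n, K)
    total = sum(
        p
        for k in range(lo, hi + 1)
        if (p := hypergeom_pmf(k, N, K, n)) <= p_obs * _REL_EPS
    )
    return float(min(1.0, total))


def _ranksum_distribution(doubled_ranks: list[int], n1: int) -> dict[int, int]:
    """Number of size-n1 subsets of the ranks attaining each doubled rank sum.

    Dynamic programme over items; exactly equivalent to enumerating all
    C(n, n1) subsets, in O(n * n1 * max_sum) time.
    """
    # table[k][s] = number of k-subsets of the processed prefix with sum s
    table: list[dict[int, int]] = [{0: 1}] + [dict() for _ in range(n1)]
    for r in doubled_ranks:
        for k in range(min(n1, len(table) - 1), 0, -1):
            src = table[k - 1]
            dst = table[k]
            for s, cnt in src.items():
                dst[s + r] = dst.get(s + r, 0) + cnt
    return table[n1]


def mannwhitney_exact_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p via the permutation distribution.

    The statistic is the rank sum T of the first group; the permutation
    distribution of T over all group assignments is symmetric about
    n1 (n+1) / 2 even under ties (the midrank multiset is reflection
    invariant), so the two-sided p is P(|T - E[T]| >= |t_obs - E[T]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    doubled = np.rint(2 * ranks).astype(int)
    t_obs = int(doubled[:n1].sum())
    center = n1 * (n1 + n2 + 1)  # doubled scale: 2 * n1 (n+1) / 2
    dev = abs(t_obs - center)
    dist = _ranksum_distribution(doubled.tolist(), n1)
    hits = sum(cnt for s, cnt in dist.items() if abs(s - center) >= dev)
    return hits / comb(n1 + n2, n1)


#: exact enumeration is used when both groups are at most this large
EXACT_MAX_GROUP = 12


def mannwhitney_p(x, y) -> tuple[float, str]:
    """Two-sided Mann-Whitney p with automatic method choice.

    Exact permutation enumeration when both groups have <= 12 observations;
    otherwise the tie-corrected normal approximation (with continuity
    correction). Returns ``(p, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP:
        return mannwhitney_exact_two_sided(x, y), "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), "asymptotic"
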