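"""Exact-test machinery vs brute-force enumeration and scipy oracles."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from melcohort.exact import (
    fisher_one_sided_enrichment,
    fisher_two_sided,
    mannwhitney_exact_two_sided,
    mannwhitney_p,
)

# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_fisher(a, b, c, d):
    """Enumerate every table with the observed margins; probabilities from
    the row-margin product formula (independent of the implementation's
    column-margin hypergeometric route)."""
    r1, r2, k, n = a + b, c + d, a + c, a + b + c + d
    tables = []
    for a2 in range(max(0, k - r2), min(r1, k) + 1):
        p = comb(r1, a2) * comb(r2, k - a2) / comb(n, k)
        tables.append((a2, p))
    p_obs = dict(tables)[a]
    one = sum(p for a2, p in tables if a2 >= a)
    two = sum(p for _a2, p in tables if p <= p_obs * (1 + 1e-7))
    return one, min(1.0, two)


def brute_force_mwu(x, y):
    """Enumerate all C(n, n1) group labelings of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, n1 = len(pooled), len(x)
    center = n1 * (n + 1) / 2
    dev = abs(ranks[:n1].sum() - center)
    hits = sum(
        1
        for idx in itertools.combinations(range(n), n1)
        if abs(ranks[list(idx)].sum() - center) >= dev - 1e-9
    )
    return hits / comb(n, n1)


def _all_tables(max_n):
    for n in range(1, max_n + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    if a + b > 0 and c + d > 0:
                        yield a, b, c, d


# ---------------------------------------------------------------------------
# Fisher


class TestFisher:
    def test_matches_brute_force_on_all_small_tables(self):
        for a, b, c, d in _all_tables(9):
            one, two = brute_force_fisher(a, b, c, d)
            assert fisher_one_sided_enrichment(a, b, c, d) == pytest.approx(one, abs=1e-12)
            assert fisher_two_sided(a, b, c, d) == pytest.approx(two, abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    def test_matches_scipy_fisher(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        sp_great = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        sp_two = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
        assert fisher_one_sided_enrichment(a, b, c, d) == pytest.approx(sp_great, rel=1e-9)
        assert fisher_two_sided(a, b, c, d) == pytest.approx(sp_two, rel=1e-7)

    def test_saturated_table_is_uninformative(self):
        # gene altered in every patient of both groups: only one table possible
        assert fisher_one_sided_enrichment(5, 0, 10, 0) == 1.0
        assert fisher_two_sided(5, 0, 10, 0) == 1.0

    def test_absent_gene_is_uninformative(self):
        assert fisher_one_sided_enrichment(0, 5, 0, 10) == 1.0

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(1, 10), d=st.integers(0, 10),
    )
    def test_enrichment_monotone_in_group_alterations(self, a, b, c, d):
        """Moving one altered patient from the rest into the group (margins
        fixed) never increases the one-sided enrichment p."""
        if b == 0:
            return
        p_before = fisher_one_sided_enrichment(a, b, c, d)
        p_after = fisher_one_sided_enrichment(a + 1, b - 1, c - 1, d + 1)
        assert p_after <= p_before + 1e-12

    @given(
        a=st.integers(0, 10), b=st.integers(0, 10),
        c=st.integers(0, 10), d=st.integers(0, 10),
    )
    def test_two_sided_invariant_under_group_swap(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        assert fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_two_sided(c, d, a, b), rel=1e-9
        )

    def test_swapping_group_and_rest_maps_to_opposite_tail(self):
        # enrichment of the group == depletion tail of the complement:
        # P(X >= a) over group draws equals P(Y <= c) over rest draws
        a, b, c, d = 6, 2, 3, 9
        swap_lower = sum(
            stats.hypergeom.pmf(k, a + b + c + d, a + c, c + d) for k in range(0, c + 1)
        )
        assert fisher_one_sided_enrichment(a, b, c, d) == pytest.approx(swap_lower)


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_separated_samples(self):
        # U = 0; only the two extreme labelings of the 20 possible qualify
        assert mannwhitney_exact_two_sided([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples(self):
        assert mannwhitney_exact_two_sided([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3], [2, 3, 4]),
            ([1, 1, 2, 2], [2, 2, 3]),          # heavy ties
            ([5.5, 1.0, 3.2], [2.1, 2.1, 8.0, 9.0]),
            ([0, 0, 0, 1], [0, 1, 1, 1]),        # near-degenerate ties
            ([10, 20], [1, 2, 3, 4, 5, 6]),
        ],
    )
    def test_matches_brute_force_enumeration(self, x, y):
        assert mannwhitney_exact_two_sided(x, y) == pytest.approx(brute_force_mwu(x, y))

    @given(
        x=st.lists(st.integers(0, 6), min_size=1, max_size=6),
        y=st.lists(st.integers(0, 6), min_size=1, max_size=6),
    )
    def test_matches_brute_force_enumeration_property(self, x, y):
        assert mannwhitney_exact_two_sided(x, y) == pytest.approx(brute_force_mwu(x, y))

    @given(
        x=st.lists(st.floats(0, 100), min_size=2, max_size=8, unique=True),
        y=st.lists(st.floats(200, 300), min_size=2, max_size=8, unique=True),
    )
    def test_matches_scipy_exact_without_ties(self, x, y):
        sp = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mannwhitney_exact_two_sided(x, y) == pytest.approx(float(sp), rel=1e-9)

    def test_method_switches_to_asymptotic_for_large_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=8)
        p, method = mannwhitney_p(x, y)
        assert method == "asymptotic" and 0 <= p <= 1
        p2, method2 = mannwhitney_p(x[:10], y)
        assert method2 == "exact"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mannwhitney_exact_two_sided([], [1.0])
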