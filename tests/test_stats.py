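"""Exact overlap test and table-column arithmetic.

The hypergeometric tail is checked against an independent exact-rational
oracle (integer binomial sums), never against another library tail.
"""

from fractions import Fraction
from math import comb

import pytest
from hypothesis import given
from hypothesis import strategies as st

from genesect import (
    P_FLOOR,
    bonferroni,
    enrich,
    enrich_counts,
    expected_overlap,
    format_p,
    hypergeom_tail,
    overlap_ci,
    representation_factor,
    significance_label,
)
from genesect.stats import expected_pct

from conftest import make_sample, make_set


def exact_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Oracle: P(X >= k) by exact rational summation of the pmf."""
    num = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


@st.composite
def hypergeom_params(draw, max_n=60):
    N = draw(st.integers(1, max_n))
    K = draw(st.integers(0, N))
    n = draw(st.integers(0, N))
    k = draw(st.integers(0, min(K, n)))
    return k, K, n, N


class TestHypergeomTail:
    def test_tail_at_zero_is_one(self):
        assert hypergeom_tail(0, 5, 5, 10) == 1.0
        assert hypergeom_tail(0, 0, 0, 1) == 1.0

    def test_small_exact_value(self):
        # P(X >= 1) = 1 - C(5,5)/C(10,5) = 251/252
        assert hypergeom_tail(1, 5, 5, 10) == pytest.approx(251 / 252, rel=1e-12)

    def test_exhaustive_against_rational_oracle_small(self):
        for N in range(1, 26):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expect = float(exact_tail(k, K, n, N))
                        got = hypergeom_tail(k, K, n, N)
                        assert got == pytest.approx(expect, rel=1e-10), (k, K, n, N)

    @given(hypergeom_params())
    def test_matches_oracle(self, params):
        k, K, n, N = params
        assert hypergeom_tail(k, K, n, N) == pytest.approx(
            float(exact_tail(k, K, n, N)), rel=1e-10
        )

    @given(hypergeom_params())
    def test_symmetry_in_set_and_sample(self, params):
        k, K, n, N = params
        assert hypergeom_tail(k, K, n, N) == pytest.approx(
            hypergeom_tail(k, n, K, N), rel=1e-12
        )

    @given(hypergeom_params())
    def test_monotone_decreasing_in_k(self, params):
        k, K, n, N = params
        if k + 1 <= min(K, n):
            assert hypergeom_tail(k + 1, K, n, N) <= hypergeom_tail(k, K, n, N)

    @given(hypergeom_params())
    def test_monotone_in_set_size(self, params):
        k, K, n, N = params
        if K + 1 <= N:
            assert hypergeom_tail(k, K + 1, n, N) >= hypergeom_tail(k, K, n, N) - 1e-15

    @pytest.mark.parametrize("k,K,n,N", [(-1, 5, 5, 10), (6, 5, 5, 10), (1, 11, 5, 10), (1, 5, 11, 10)])
    def test_bound_violations_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_tail(k, K, n, N)


class TestExpectedAndRF:
    def test_reference_row_expectation(self):
        assert expected_overlap(6409, 345, 21000) == pytest.approx(105.29, abs=0.005)
        assert expected_pct(6409, 21000) == pytest.approx(30.5, abs=0.03)

    def test_degenerate_sets(self):
        assert expected_overlap(0, 345, 21000) == 0.0
        assert expected_overlap(21000, 345, 21000) == 345.0

    def test_rf_examples(self):
        assert representation_factor(195, 105.29) == pytest.approx(1.852, abs=0.001)
        assert representation_factor(10, 10.0) == 1.0
        E = expected_overlap(159, 345, 21000)
        assert representation_factor(31, E) == pytest.approx(11.87, abs=0.01)

    def test_rf_times_e_recovers_o_exactly(self):
        E = expected_overlap(1673, 345, 21000)
        assert representation_factor(74, E) * E == pytest.approx(74, rel=1e-14)

    def test_zero_expectation_rejected(self):
        with pytest.raises(ValueError):
            representation_factor(5, 0.0)

    def test_partition_conservation(self):
        # expected overlaps of a partition of the universe sum to n
        N, n = 1000, 77
        sizes = [100, 400, 250, 250]
        assert sum(expected_overlap(K, n, N) for K in sizes) == pytest.approx(n)


class TestOverlapCI:
    @pytest.mark.parametrize(
        "O,n,lower",
        [(139, 345, 124), (0, 345, 0), (345, 345, 342), (35, 345, 26)],
    )
    def test_examples(self, O, n, lower):
        lo, hi = overlap_ci(O, n)
        assert hi == n
        assert abs(lo - lower) <= 1
        assert lo <= O

    def test_closed_form_at_full_overlap(self):
        lo, _ = overlap_ci(345, 345)
        assert lo == round(345 * 0.05 ** (1 / 345))


class TestBonferroniAndDisplay:
    def test_correction(self):
        assert bonferroni(2.2e-16, 23) == pytest.approx(5.06e-15, rel=1e-3)
        assert bonferroni(1.1e-4, 23) == pytest.approx(2.53e-3, rel=1e-3)
        assert bonferroni(0.5, 23) == 1.0

    @given(st.floats(1e-300, 1.0), st.integers(1, 100))
    def test_monotone_and_capped(self, p, m):
        corrected = bonferroni(p, m)
        assert p <= corrected <= 1.0
        assert bonferroni(p, m + 1) >= corrected

    @pytest.mark.parametrize(
        "p,text,floored",
        [
            (2.53e-3, "2.5E-03", False),
            (1e-30, "2.2E-16", True),
            (1.0, "1.0E+00", False),
            (2.2e-16, "2.2E-16", True),
        ],
    )
    def test_format_p(self, p, text, floored):
        assert format_p(p) == (text, floored)

    def test_floor_constant(self):
        assert format_p(P_FLOOR) == (f"{P_FLOOR:.1E}", False)

    def test_stars(self):
        assert significance_label(5e-7) == "***"
        assert significance_label(5e-4) == "**"
        assert significance_label(5e-3) == "*"
        assert significance_label(0.02) == "NS"


class TestEnrich:
    def test_full_row_from_counts(self):
        r = enrich_counts("VIRND", 6409, 345, 21000, 195, family_size=23)
        assert r.observed_pct == pytest.approx(56.5, abs=0.03)
        assert r.rf == pytest.approx(1.85, abs=0.005)
        assert r.p_corrected <= 1e-6
        assert r.significance == "***"
        assert r.rf * r.expected == pytest.approx(r.observed, rel=1e-12)
        assert r.p_corrected == pytest.approx(min(1, 23 * r.p_nominal), rel=1e-12)
        assert r.ci_lower <= r.observed <= r.ci_upper == r.sample_size

    def test_non_significant_row(self):
        r = enrich_counts("VI − SY", 3273, 345, 21000, 76, family_size=23)
        assert r.p_corrected > 0.01
        assert r.significance == "NS"

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enrich_counts("empty", 0, 345, 21000, 0)

    def test_object_interface_restricts_to_universe(self, small_universe):
        sample = make_sample("s", range(10))
        fset = make_set("f", range(5, 25))
        r = enrich(sample, fset, small_universe, family_size=2)
        assert r.observed == 5
        assert r.universe_size == 100
        assert r.set_size == 20
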