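"""Alpha diversity indices: worked values and structural invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endodiv import alpha

LEAF = [1] * 18
ROOT = [1, 1]
FLOWER = [3, 1, 1, 1, 1, 1]

count_vectors = st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=30)


class TestWorkedValues:
    def test_shannon(self):
        assert alpha.shannon_entropy(LEAF) == pytest.approx(math.log(18))
        assert alpha.shannon_entropy(FLOWER) == pytest.approx(1.6675, abs=5e-4)
        assert alpha.shannon_entropy([7]) == 0.0

    def test_simpson(self):
        d, one_m_d = alpha.simpson_dominance(FLOWER)
        assert d == pytest.approx(14 / 64)
        assert one_m_d == pytest.approx(50 / 64)
        assert alpha.simpson_dominance(ROOT)[0] == pytest.approx(0.5)
        assert alpha.simpson_dominance([9])[0] == pytest.approx(1.0)

    def test_richness(self):
        d_mn, inv, d_mg = alpha.richness_indices(LEAF)
        assert d_mn == pytest.approx(18 / math.sqrt(18))
        assert d_mg == pytest.approx(17 / math.log(18))
        assert alpha.richness_indices(ROOT)[1] == pytest.approx(1 / math.sqrt(2))
        assert alpha.richness_indices([1]) == (1.0, 1.0, 0.0)

    def test_brillouin(self):
        assert alpha.brillouin_index(FLOWER) == pytest.approx(
            (math.log(math.factorial(8)) - math.log(6)) / 8
        )
        assert alpha.brillouin_index(LEAF) == pytest.approx(
            math.log(math.factorial(18)) / 18
        )
        assert alpha.brillouin_index([5]) == pytest.approx(0.0)

    def test_evenness(self):
        ev, j = alpha.evenness_measures(FLOWER)
        assert ev == pytest.approx(0.8832, abs=5e-4)
        assert j == pytest.approx(0.9307, abs=5e-4)
        assert alpha.evenness_measures(LEAF) == (pytest.approx(1.0), pytest.approx(1.0))
        assert alpha.evenness_measures([4, 4, 4])[0] == pytest.approx(1.0)

    def test_berger_parker(self):
        assert alpha.berger_parker(FLOWER) == pytest.approx(3 / 8)
        assert alpha.berger_parker(ROOT) == pytest.approx(0.5)
        assert alpha.berger_parker([9]) == 1.0

    def test_chao1(self):
        assert alpha.chao1_estimate(LEAF) == pytest.approx(171.0)
        assert alpha.chao1_estimate(ROOT) == pytest.approx(3.0)
        assert alpha.chao1_estimate(FLOWER) == pytest.approx(16.0)
        assert alpha.chao1_estimate([3, 4, 5]) == 3.0  # no singletons

    def test_brillouin_no_overflow_at_large_n(self):
        # log-gamma path: factorials of 10^6 would overflow floats
        val = alpha.brillouin_index([500_000, 500_000])
        assert 0.0 < val < math.log(2)


class TestFisherAlpha:
    def test_flower_assemblage(self):
        a = alpha.fisher_alpha(6, 8)
        assert a == pytest.approx(10.905, abs=5e-4)

    def test_undefined_when_all_singletons(self):
        assert alpha.fisher_alpha(18, 18) is None

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            alpha.fisher_alpha(5, 4)
        with pytest.raises(ValueError):
            alpha.fisher_alpha(0, 4)

    def test_agrees_with_bisection_oracle(self):
        def bisect(s, n):
            lo, hi = 1e-6, 1e6
            for _ in range(200):
                mid = (lo + hi) / 2
                if mid * math.log1p(n / mid) < s:
                    lo = mid
                else:
                    hi = mid
            return (lo + hi) / 2

        for s, n in [(10, 100), (3, 50), (40, 45), (1, 2)]:
            assert alpha.fisher_alpha(s, n) == pytest.approx(bisect(s, n), abs=1e-6)

    def test_residual_below_1e9_and_monotone_in_s(self):
        n = 200
        prev = 0.0
        for s in range(1, n, 7):
            a = alpha.fisher_alpha(s, n)
            assert abs(a * math.log1p(n / a) - s) < 1e-9
            assert a > prev
            prev = a


class TestProfile:
    def test_leaf_profile_consistent(self):
        prof = alpha.alpha_profile(LEAF)
        assert (prof.S, prof.N) == (18, 18)
        assert prof.F1 == 18 and prof.F2 == 0
        assert prof.fisher_alpha is None
        assert prof.shannon_H == alpha.shannon_entropy(LEAF)

    def test_flower_profile_consistent(self):
        prof = alpha.alpha_profile(FLOWER)
        assert (prof.S, prof.N) == (6, 8)
        assert prof.chao1 == alpha.chao1_estimate(FLOWER)
        assert prof.simpson_D == alpha.simpson_dominance(FLOWER)[0]

    def test_monodominant_vector(self):
        prof = alpha.alpha_profile([5])
        assert (prof.S, prof.N) == (1, 5)
        assert prof.shannon_H == 0.0
        assert prof.simpson_D == 1.0
        assert prof.equitability_J == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            alpha.alpha_profile([0, 0])


class TestInvariants:
    @given(counts=count_vectors)
    @settings(deadline=None, max_examples=60)
    def test_index_bounds(self, counts):
        prof = alpha.alpha_profile(counts)
        s = prof.S
        assert prof.shannon_H <= math.log(s) + 1e-9
        assert prof.brillouin_HB <= prof.shannon_H + 1e-9
        assert prof.chao1 >= s
        assert 1 / s - 1e-12 <= prof.simpson_D <= 1.0 + 1e-12
        assert prof.berger_parker_d >= 1 / s - 1e-12
        assert prof.simpson_1mD == pytest.approx(1 - prof.simpson_D)

    @given(n_species=st.integers(2, 20), n_each=st.integers(1, 30))
    @settings(deadline=None, max_examples=30)
    def test_shannon_maximal_iff_even(self, n_species, n_each):
        even = [n_each] * n_species
        assert alpha.shannon_entropy(even) == pytest.approx(math.log(n_species))
        uneven = even.copy()
        uneven[0] += 1
        assert alpha.shannon_entropy(uneven) < math.log(n_species)


class TestCompatRendering:
    def test_table_compat_rounding(self):
        # 4 significant digits, then truncation at the third decimal
        assert alpha.round_table_compat(0.21875) == 0.218
        assert alpha.round_table_compat(1 / 18) == 0.055
        assert alpha.round_table_compat(math.log(2) / 2) == 0.346
        assert alpha.round_table_compat(1 / math.log(2)) == 1.443
        assert alpha.round_table_compat(10.9051) == 10.91

    def test_undefined_fisher_renders_zero_in_compat(self):
        s = alpha.alpha_profile(LEAF).to_series(compat=True)
        assert s["Fisher_alpha diversity index"] == 0.0
        full = alpha.alpha_profile(LEAF).to_series(compat=False)
        assert math.isnan(full["Fisher_alpha diversity index"])
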