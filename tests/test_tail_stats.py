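"""Partial Spearman band statistics and synchrony matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from tailsync import (
    FULL_BAND,
    LOWER_HALF,
    UPPER_HALF,
    Panel,
    TailBand,
    driver_tail_profile,
    normalized_ranks,
    pairwise_synchrony,
    partial_spearman,
    spearman,
    tail_dependence_strength,
)

from conftest import clayton_sample, make_panel


class TestNormalizedRanks:
    def test_untied_ranks(self):
        pair = normalized_ranks([10, 20, 30, 5, 15], [1, 2, 3, 4, 5])
        assert np.allclose(np.sort(pair.u), np.arange(1, 6) / 6.0)
        assert np.isclose(pair.u.mean(), 0.5)

    def test_tied_values_get_average_ranks(self):
        pair = normalized_ranks([1, 1, 2, 3, 4], [1, 2, 3, 4, 5])
        assert np.allclose(pair.u[:2], 1.5 / 6.0)

    def test_small_example_values(self):
        # ranks/(n+1): with n=3 appended padding to satisfy the minimum,
        # check the documented 3-point pattern directly on 5 points.
        pair = normalized_ranks([10, 20, 30, 40, 50], [10, 20, 30, 40, 50])
        assert np.allclose(pair.u, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])

    def test_pairwise_complete_filtering(self):
        x = [1.0, np.nan, 3, 4, 5, 6, 7]
        y = [2.0, 2.0, np.nan, 4, 5, 1, 3]
        pair = normalized_ranks(x, y)
        assert pair.n == 5

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="complete pairs"):
            normalized_ranks([1, 2, 3, np.nan], [1, 2, 3, 4])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        a = normalized_ranks(x, y)
        b = normalized_ranks(np.exp(2 * x) + 1, y)
        assert np.allclose(a.u, b.u) and np.allclose(a.v, b.v)


class TestPartialSpearman:
    def test_comonotone_four_points(self):
        pair = normalized_ranks([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        # Comonotone symmetric sample: each half-band carries half of the
        # total, and the full band is exactly 1.
        assert np.isclose(partial_spearman(pair, LOWER_HALF), 0.5, atol=1e-12)
        assert np.isclose(partial_spearman(pair, UPPER_HALF), 0.5, atol=1e-12)
        assert np.isclose(partial_spearman(pair, FULL_BAND), 1.0, atol=1e-12)

    def test_half_bands_partition_the_sample(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 25))
            pair = normalized_ranks(x, y)
            lo = partial_spearman(pair, LOWER_HALF)
            hi = partial_spearman(pair, UPPER_HALF)
            assert np.isclose(lo + hi, partial_spearman(pair, FULL_BAND), atol=1e-12)

    def test_three_band_partition(self, rng):
        x, y = rng.normal(size=(2, 40))
        pair = normalized_ranks(x, y)
        parts = [
            partial_spearman(pair, TailBand(a, b))
            for a, b in [(0.0, 0.3), (0.3, 0.7), (0.7, 1.0)]
        ]
        assert np.isclose(sum(parts), spearman(pair), atol=1e-12)

    def test_full_band_equals_classical_spearman(self, rng):
        x, y = rng.normal(size=(2, 50))
        pair = normalized_ranks(x, y)
        assert np.isclose(spearman(pair), spearmanr(x, y).statistic, atol=1e-12)

    def test_gaussian_copula_halves_are_symmetric(self):
        rng = np.random.default_rng(7)
        n = 10_000
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=n).T
        pair = normalized_ranks(z[0], z[1])
        lo = partial_spearman(pair, LOWER_HALF)
        hi = partial_spearman(pair, UPPER_HALF)
        assert abs(hi - lo) < 0.02  # symmetric copula: equal halves
        assert np.isclose(lo + hi, spearmanr(z[0], z[1]).statistic, atol=1e-12)

    def test_empty_band_returns_zero(self):
        pair = normalized_ranks([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert partial_spearman(pair, TailBand(0.97, 0.98)) == 0.0


class TestTailDependenceStrength:
    def test_comonotone_is_zero(self):
        pair = normalized_ranks(np.arange(10.0), np.arange(10.0))
        assert np.isclose(tail_dependence_strength(pair), 0.0, atol=1e-12)

    def test_clayton_is_lower_tail_dependent(self):
        rng = np.random.default_rng(42)
        u, v = clayton_sample(rng, theta=2.0, n=100_000)
        d = tail_dependence_strength(normalized_ranks(u, v))
        assert d < -0.05

    def test_survival_reflection_negates_exactly(self):
        rng = np.random.default_rng(42)
        u, v = clayton_sample(rng, theta=2.0, n=5_000)
        d = tail_dependence_strength(normalized_ranks(u, v))
        d_reflected = tail_dependence_strength(normalized_ranks(-u, -v))
        assert np.isclose(d_reflected, -d, atol=1e-12)


class TestPairwiseSynchrony:
    def test_identical_untied_sites(self, rng):
        row = rng.normal(size=10)
        s = pairwise_synchrony(make_panel(np.vstack([row, row])))
        assert np.allclose(s.m_upper, 0.5, atol=1e-12)
        assert np.allclose(s.m_lower, 0.5, atol=1e-12)
        assert np.allclose(s.d, 0.0, atol=1e-12)

    def test_matches_per_pair_oracle(self, rng):
        panel = make_panel(rng.normal(size=(5, 12)))
        s = pairwise_synchrony(panel)
        for i in range(5):
            for j in range(5):
                pair = normalized_ranks(panel.values[i], panel.values[j])
                assert np.isclose(
                    s.m_upper[i, j], partial_spearman(pair, UPPER_HALF), atol=1e-12
                )
                assert np.isclose(
                    s.m_lower[i, j], partial_spearman(pair, LOWER_HALF), atol=1e-12
                )
        assert np.allclose(s.d, s.m_upper - s.m_lower)

    def test_missing_data_path_matches_oracle(self, rng):
        vals = rng.normal(size=(4, 15))
        vals[0, 3] = np.nan
        vals[2, [1, 7]] = np.nan
        panel = make_panel(vals)
        s = pairwise_synchrony(panel)
        pair = normalized_ranks(vals[0], vals[2])
        assert np.isclose(s.m_upper[0, 2], partial_spearman(pair, UPPER_HALF), atol=1e-12)

    def test_independent_noise_has_mean_d_near_zero(self):
        rng = np.random.default_rng(3)
        s = pairwise_synchrony(make_panel(rng.normal(size=(100, 33))))
        iu = np.triu_indices(100, k=1)
        mean_d = s.d[iu].mean()
        se = s.d[iu].std() / np.sqrt(len(iu[0]))  # optimistic SE; pairs overlap
        assert abs(mean_d) < 10 * se and abs(mean_d) < 0.02

    def test_reflection_swaps_upper_and_lower(self, rng):
        panel = make_panel(rng.normal(size=(4, 16)))
        neg = make_panel(-panel.values)
        s, sn = pairwise_synchrony(panel), pairwise_synchrony(neg)
        assert np.allclose(sn.m_upper, s.m_lower, atol=1e-12)
        assert np.allclose(sn.d, -s.d, atol=1e-12)


class TestDriverTailProfile:
    def test_self_driver_gives_zero_d(self, rng):
        panel = make_panel(rng.normal(size=(3, 12)))
        prof = driver_tail_profile(panel, panel)
        assert np.allclose(prof["d"], 0.0, atol=1e-12)
        assert np.allclose(prof["rho_l"] + prof["rho_u"], 1.0, atol=1e-12)

    def test_single_site_driver_broadcasts(self, rng):
        resp = make_panel(rng.normal(size=(4, 15)))
        idx = Panel(["index"], resp.years, rng.normal(size=(1, 15)), "index")
        prof = driver_tail_profile(resp, idx)
        for i in range(4):
            pair = normalized_ranks(resp.values[i], idx.values[0])
            assert np.isclose(prof["d"][i], tail_dependence_strength(pair), atol=1e-12)

    def test_noiseless_increasing_response(self, rng):
        drv = make_panel(rng.normal(size=(2, 10)), name="driver")
        resp = make_panel(np.exp(drv.values))
        prof = driver_tail_profile(resp, drv)
        assert np.allclose(prof["rho_l"] + prof["rho_u"], 1.0, atol=1e-12)

    def test_misaligned_years_rejected(self, rng):
        resp = make_panel(rng.normal(size=(2, 10)), start_year=2000)
        drv = make_panel(rng.normal(size=(2, 10)), start_year=2001)
        with pytest.raises(ValueError, match="years"):
            driver_tail_profile(resp, drv)
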