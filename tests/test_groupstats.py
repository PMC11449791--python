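"""Group statistics: Welch t, Shapiro-Wilk, Grubbs, Mann-Whitney, slopes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hippoquant import (
    PSDEstimate,
    compare_mean_psd_slopes,
    compare_samples,
    grubbs_test,
    mann_whitney_u,
    mean_psd,
    shapiro_wilk,
    summarize,
    welch_t,
)


def psd_of(b, noise=0.0, seed=0):
    f = np.arange(20, 80.1, 0.2)
    p = f**b
    if noise:
        p = p * 10 ** np.random.default_rng(seed).normal(0, noise, f.size)
    return PSDEstimate(f, p)


class TestWelchT:
    def test_hand_computed_example(self):
        t, df, p = welch_t([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.2879, abs=1e-4)

    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_p_shrinks_with_separation(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        ps = [welch_t(a, a + c)[2] for c in (0.5, 1.0, 2.0, 4.0)]
        assert all(x > y for x, y in zip(ps, ps[1:]))

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(10), rng.standard_normal(12)
        t1 = welch_t(a, b)[0]
        t2 = welch_t(rng.permutation(a), rng.permutation(b))[0]
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestShapiroWilk:
    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(1)
        rej = np.mean([
            shapiro_wilk(rng.standard_normal(100))[1] < 0.05
            for _ in range(1000)
        ])
        assert 0.03 <= rej <= 0.07

    def test_power_against_exponential(self):
        rng = np.random.default_rng(2)
        rej = np.mean([
            shapiro_wilk(rng.exponential(size=100))[1] < 0.05
            for _ in range(200)
        ])
        assert rej >= 0.8

    def test_constant_and_size_limits(self):
        with pytest.raises(ValueError):
            shapiro_wilk(np.ones(10))
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestGrubbs:
    def test_flags_gross_outlier(self):
        idx, G, G_crit = grubbs_test([1.0, 2.0, 3.0, 100.0])
        assert idx == 3
        # closed form: |100 - 26.5| / 49.00680 and the t-based critical value
        assert G == pytest.approx(1.49979, abs=1e-4)
        assert G_crit == pytest.approx(1.4812, abs=1e-3)
        assert G > G_crit

    def test_clean_sample_not_flagged(self):
        idx, G, G_crit = grubbs_test([1.0, 2.0, 3.0, 4.0])
        assert idx is None
        assert G < G_crit

    def test_symmetric_sample(self):
        idx, _, _ = grubbs_test([-1.0, 0.0, 1.0])
        assert idx is None

    def test_iterative_screen_terminates(self):
        # one flag per call; rerunning after removal may flag again or stop
        x = np.array([1.0, 2.0, 3.0, 100.0])
        idx, _, _ = grubbs_test(x)
        assert idx == 3
        idx2, _, _ = grubbs_test(np.delete(x, idx))
        assert idx2 is None

    def test_min_n(self):
        with pytest.raises(ValueError):
            grubbs_test([1.0, 2.0])


class TestMannWhitney:
    def test_exact_small_sample(self):
        U, p = mann_whitney_u([1, 2], [3, 4])
        assert U == 0
        assert p == pytest.approx(1 / 3, abs=1e-9)

    def test_identical_samples_midpoint_u(self):
        U, _ = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert U == pytest.approx(4.5)

    def test_extreme_separation(self):
        U, _ = mann_whitney_u([1, 2, 3], [100, 200, 300])
        assert U in (0.0, 9.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestSummarize:
    def test_closed_form(self):
        mean, sem, n = summarize([2.0, 4.0, 6.0])
        assert mean == 4.0
        assert sem == pytest.approx(2.0 / np.sqrt(3), abs=1e-9)
        assert n == 3

    def test_single_value_sem_zero_with_warning(self):
        with pytest.warns(UserWarning):
            mean, sem, n = summarize([5.0])
        assert (mean, sem, n) == (5.0, 0.0, 1)

    def test_scaling(self):
        m1, s1, _ = summarize([1.0, 2.0, 3.0])
        m2, s2, _ = summarize([3.0, 6.0, 9.0])
        assert (m2, s2) == (3 * m1, pytest.approx(3 * s1))


class TestMeanPsd:
    def test_identity_and_linearity(self):
        p = psd_of(-2.0)
        assert np.array_equal(mean_psd([p]).power, p.power)
        up = PSDEstimate(p.freq_hz, 1.3 * p.power)
        dn = PSDEstimate(p.freq_hz, 0.7 * p.power)
        assert np.allclose(mean_psd([up, dn]).power, p.power)

    def test_grid_mismatch_rejected(self):
        a = psd_of(-2.0)
        b = PSDEstimate(a.freq_hz + 0.1, a.power)
        with pytest.raises(ValueError):
            mean_psd([a, b])


class TestCompareMeanPsdSlopes:
    def test_identical_groups_null(self):
        g = [psd_of(-2.5, noise=0.05, seed=s) for s in range(4)]
        comp = compare_mean_psd_slopes(g, g)
        assert comp.difference == pytest.approx(0.0, abs=1e-12)
        assert comp.p_value == pytest.approx(1.0, abs=1e-9)

    def test_label_swap_flips_t_sign(self):
        ga = [psd_of(-2.9, noise=0.05, seed=s) for s in range(4)]
        gb = [psd_of(-2.5, noise=0.05, seed=s + 10) for s in range(4)]
        c1 = compare_mean_psd_slopes(ga, gb)
        c2 = compare_mean_psd_slopes(gb, ga)
        assert c1.t_stat == pytest.approx(-c2.t_stat, abs=1e-9)
        assert c1.p_value == pytest.approx(c2.p_value, abs=1e-9)

    def test_recovers_group_slopes(self):
        ga = [psd_of(-2.9, noise=0.02, seed=s) for s in range(6)]
        gb = [psd_of(-2.5, noise=0.02, seed=s + 20) for s in range(6)]
        comp = compare_mean_psd_slopes(ga, gb, band=(30, 50))
        assert comp.slope_A == pytest.approx(-2.9, abs=0.05)
        assert comp.slope_B == pytest.approx(-2.5, abs=0.05)
        assert comp.p_value < 0.001


class TestCompareSamples:
    def test_normal_samples_use_welch(self):
        rng = np.random.default_rng(3)
        comp = compare_samples(rng.normal(0, 1, 60), rng.normal(1, 1, 60))
        assert comp.test_name == "Welch t"
        assert comp.p_value < 0.001

    def test_skewed_samples_fall_back_to_mann_whitney(self):
        rng = np.random.default_rng(4)
        comp = compare_samples(rng.exponential(1, 80), rng.exponential(2, 80))
        assert comp.test_name == "Mann-Whitney U"
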