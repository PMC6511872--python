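import numpy as np
import pytest
from scipy import stats

from fric import (RadialProfile, compare_relative_ratio, compare_zones,
                  pooled_t_test, significance_stars, summarize_group,
                  timelapse_zone_trajectory)


def _profiles(matrix):
    """Rows = nuclei, columns = zones."""
    matrix = np.atleast_2d(np.asarray(matrix, float))
    return [RadialProfile(zone_means=row,
                          zone_pixel_counts=np.full(len(row), 10),
                          nucleus_id=i + 1)
            for i, row in enumerate(matrix)]


def _oracle_pooled_t(x, y):
    """Hand-rolled pooled-variance Student t-test (independent route)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


class TestSummarizeGroup:
    def test_mean_and_sem_of_three_nuclei(self):
        gp = summarize_group(_profiles([[1.0], [2.0], [3.0]]))
        assert gp.zone_mean[0] == pytest.approx(2.0)
        assert gp.zone_sem[0] == pytest.approx(1 / np.sqrt(3), abs=1e-4)
        assert gp.n == 3

    def test_identical_profiles_have_zero_sem(self):
        gp = summarize_group(_profiles([[1.0, 0.8]] * 4))
        np.testing.assert_allclose(gp.zone_sem, 0.0)

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="2 profiles"):
            summarize_group(_profiles([[1.0, 2.0]]))

    def test_mixed_n_zones_rejected(self):
        bad = _profiles([[1.0, 2.0]]) + _profiles([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="mixed"):
            summarize_group(bad)


class TestPooledTTest:
    def test_worked_example(self):
        t, p = pooled_t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert p == pytest.approx(0.0214, abs=1e-3)

    def test_matches_independent_oracle_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n2 = rng.integers(2, 30, 2)
            x = rng.normal(0, 1, n1)
            y = rng.normal(rng.normal(), 1, n2)
            t, p = pooled_t_test(x, y)
            to, po = _oracle_pooled_t(x, y)
            assert t == pytest.approx(to, abs=1e-9)
            assert p == pytest.approx(po, abs=1e-9)

    def test_type_i_error_calibration_under_the_null(self):
        """Per-test type-I error at alpha=0.05 is 0.05 +/- 0.02 over 2000
        null comparisons."""
        rng = np.random.default_rng(1)
        rejections = 0
        n_tests = 2000
        for _ in range(n_tests):
            x = rng.normal(1.0, 0.1, 10)
            y = rng.normal(1.0, 0.1, 10)
            _, p = pooled_t_test(x, y)
            rejections += p <= 0.05
        assert rejections / n_tests == pytest.approx(0.05, abs=0.02)


class TestSignificanceStars:
    @pytest.mark.parametrize("p,label", [
        (0.2, "ns"), (0.051, "ns"), (0.05, "*"), (0.03, "*"), (0.011, "*"),
        (0.01, "**"), (0.002, "**"), (0.001, "***"), (0.0002, "***"),
        (0.0001, "****"), (5e-5, "****"), (0.0, "****"),
    ])
    def test_star_bins(self, p, label):
        assert significance_stars(p) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestCompareZones:
    def test_single_zone_worked_example(self):
        cmp = compare_zones(_profiles([[1.0], [2.0], [3.0]]),
                            _profiles([[4.0], [5.0], [6.0]]))
        assert cmp.t[0] == pytest.approx(-3.674, abs=1e-3)
        assert cmp.p[0] == pytest.approx(0.0214, abs=1e-3)
        assert cmp.significant[0]
        assert cmp.stars[0] == "*"

    def test_identical_groups_not_significant(self):
        g = _profiles([[1.0, 0.9], [1.1, 1.0], [0.9, 1.05]])
        cmp = compare_zones(g, [RadialProfile(p.zone_means.copy(),
                                              p.zone_pixel_counts.copy())
                                for p in g])
        np.testing.assert_allclose(cmp.t, 0.0, atol=1e-12)
        np.testing.assert_allclose(cmp.p, 1.0)
        assert cmp.significant_peripheral_run == 0

    def test_label_exchange_negates_t_preserves_p(self):
        rng = np.random.default_rng(2)
        g1 = _profiles(rng.normal(1.0, 0.1, (8, 5)))
        g2 = _profiles(rng.normal(1.1, 0.1, (9, 5)))
        a = compare_zones(g1, g2)
        b = compare_zones(g2, g1)
        np.testing.assert_allclose(a.t, -b.t, atol=1e-12)
        np.testing.assert_allclose(a.p, b.p, atol=1e-12)

    def test_peripheral_run_counts_consecutive_significant_zones(self):
        """A 5x-SEM effect confined to zones 1-3 yields a run of exactly 3."""
        rng = np.random.default_rng(3)
        base = rng.normal(1.0, 0.01, (20, 10))
        shifted = base.copy() + rng.normal(0, 0.001, base.shape)
        effect = np.zeros(10)
        effect[:3] = 5 * 0.01 / np.sqrt(20) * 5
        cmp = compare_zones(_profiles(base), _profiles(shifted + effect))
        assert cmp.significant_peripheral_run == 3
        assert list(cmp.significant[:4]) == [True, True, True, False]

    def test_missing_zones_yield_nan_not_crash(self):
        g1 = _profiles([[1.0, np.nan], [1.1, np.nan], [0.9, np.nan]])
        g2 = _profiles([[2.0, np.nan], [2.1, np.nan], [1.9, np.nan]])
        cmp = compare_zones(g1, g2)
        assert np.isfinite(cmp.p[0])
        assert np.isnan(cmp.p[1])
        assert not cmp.significant[1]

    def test_holm_correction_is_more_conservative(self):
        rng = np.random.default_rng(4)
        g1 = _profiles(rng.normal(1.0, 0.05, (10, 20)))
        g2 = _profiles(rng.normal(1.02, 0.05, (10, 20)))
        plain = compare_zones(g1, g2)
        holm = compare_zones(g1, g2, holm=True)
        assert holm.significant.sum() <= plain.significant.sum()


class TestCompareRelativeRatio:
    def test_identical_samples_p_one(self):
        cmp = compare_relative_ratio([0.8, 0.8, 0.8], [0.8, 0.8, 0.8])
        assert cmp.p == 1.0 and cmp.t == 0.0

    def test_strongly_shifted_samples_highly_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.8, 0.01, 10)
        b = rng.normal(1.0, 0.01, 10)
        cmp = compare_relative_ratio(a, b)
        assert cmp.p < 1e-4
        assert cmp.stars == "****"

    def test_stars_consistent_with_mapping(self):
        rng = np.random.default_rng(6)
        for shift in (0.0, 0.005, 0.02, 0.1):
            a = rng.normal(1.0, 0.05, 12)
            b = rng.normal(1.0 + shift, 0.05, 12)
            cmp = compare_relative_ratio(a, b)
            assert cmp.stars == significance_stars(cmp.p)


class TestTimelapse:
    def _series(self, treated_slope=0.0, noise=0.001, n=8, times=(0, 15, 30, 45, 60)):
        rng = np.random.default_rng(7)
        out = {}
        for t in times:
            ctrl = _profiles(rng.normal(1.0, noise, (n, 3)))
            trt = _profiles(rng.normal(1.0 + treated_slope * t / 60, noise, (n, 3)))
            out[float(t)] = {"control": ctrl, "treated": trt}
        return out

    def test_flat_series_final_comparison_not_significant(self):
        res = timelapse_zone_trajectory(self._series(0.0), zone=1)
        assert res.final_comparison.p > 0.05
        assert len(res.time_points) == 5

    def test_rising_treated_group_significant_at_end(self):
        res = timelapse_zone_trajectory(self._series(0.1), zone=1)
        assert res.final_comparison.p < 0.001
        assert res.group_means["treated"][-1] > res.group_means["control"][-1]

    def test_out_of_order_time_points_rejected(self):
        series = self._series(0.0, times=(0, 15))
        reordered = {15.0: series[15.0], 0.0: series[0.0]}
        with pytest.raises(ValueError, match="increasing"):
            timelapse_zone_trajectory(reordered)

    def test_missing_group_rejected(self):
        series = self._series(0.0, times=(0, 15))
        del series[15.0]["treated"]
        with pytest.raises(ValueError, match="missing group"):
            timelapse_zone_trajectory(series)
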