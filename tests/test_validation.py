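import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from uvresolve import (
    CalibrationModel,
    anova_from_sums,
    f_critical,
    fit_calibration,
    lod_loq,
    mean_sd,
    one_way_anova,
    percent_rsd,
    recovery_percent,
    standard_addition,
    t_critical,
    two_sample_t_f,
)


class TestFitCalibration:
    def test_exact_line(self):
        model = fit_calibration([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert model.slope == pytest.approx(2.0, abs=1e-12)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)
        assert model.r == pytest.approx(1.0, abs=1e-12)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            fit_calibration([1, 2], [2, 4])

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_calibration([3, 3, 3], [1, 2, 3])

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(1, 18, 24)
        y = 0.07 * x + 0.01 + rng.normal(0, 0.002, 24)
        model = fit_calibration(x, y)
        # brute-force normal equations
        n = len(x)
        sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert model.slope == pytest.approx(slope, abs=1e-10)
        assert model.intercept == pytest.approx(intercept, abs=1e-10)
        resid = y - slope * x - intercept
        assert model.sigma_resid == pytest.approx(
            np.sqrt((resid**2).sum() / (n - 2)), abs=1e-10
        )

    def test_inversion_round_trip(self):
        model = fit_calibration([1, 2, 3, 4], [0.07, 0.14, 0.21, 0.28])
        assert model.to_concentration(model.predict(2.5)) == pytest.approx(2.5)


class TestLodLoq:
    def test_arithmetic(self):
        model = CalibrationModel(slope=0.1, sigma_resid=0.01)
        lod, loq = lod_loq(model)
        assert lod == pytest.approx(0.33)
        assert loq == pytest.approx(1.0)

    def test_ratio_identity(self, rng):
        for _ in range(10):
            model = CalibrationModel(
                slope=rng.uniform(0.01, 2), sigma_resid=rng.uniform(1e-4, 0.1)
            )
            lod, loq = lod_loq(model)
            assert loq / lod == pytest.approx(10 / 3.3, abs=1e-12)

    def test_published_limits_are_consistent_with_convention(self):
        # a printed LOQ/LOD pair of 0.774/0.255 µg/mL matches 10/3.3 to rounding
        assert 0.774 / 0.255 == pytest.approx(10 / 3.3, abs=0.01)

    def test_zero_slope_impossible(self):
        with pytest.raises(ValueError):
            CalibrationModel(slope=0.0)


class TestRecoveryStatistics:
    def test_recovery_percent(self):
        assert recovery_percent(4.0, 4.0) == 100.0
        assert recovery_percent(3.9, 4.0) == pytest.approx(97.5)
        with pytest.raises(ValueError):
            recovery_percent(4.0, 0.0)

    def test_five_mixture_recoveries_summary(self):
        # five per-mixture recoveries of one method/analyte column
        mean, sd = mean_sd([99.96, 99.97, 99.58, 99.47, 98.69])
        assert round(mean, 2) == 99.53
        assert round(sd, 3) == 0.522

    def test_constant_series(self):
        assert mean_sd([100.0] * 5) == (100.0, 0.0)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            mean_sd([100.0])

    def test_percent_rsd_round_trip(self, rng):
        values = rng.normal(100, 1.5, 9)
        mean, sd = mean_sd(values)
        assert percent_rsd(values) == pytest.approx(100 * sd / mean, abs=1e-12)


class TestStandardAddition:
    def test_exact_recovery(self):
        res = standard_addition(4.0, [2.0], [6.0])
        assert res.recoveries == [pytest.approx(100.0)]

    def test_three_level_series(self):
        res = standard_addition(4.0, [2.0, 4.0, 6.0], [5.9, 8.1, 10.0])
        assert res.recoveries == [pytest.approx(v) for v in (95.0, 102.5, 100.0)]
        assert res.mean == pytest.approx(99.17, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            standard_addition(4.0, [0.0], [6.0])
        with pytest.raises(ValueError):
            standard_addition(4.0, [2.0, 4.0], [6.0])
        with pytest.raises(ValueError):
            standard_addition(4.0, [], [])


class TestTwoSampleComparison:
    def test_identical_samples(self):
        res = two_sample_t_f([99.0, 100.0, 101.0], [99.0, 100.0, 101.0])
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.f_stat == pytest.approx(1.0, abs=1e-12)
        assert res.verdict == "no significant difference"

    def test_matches_formula_oracle(self, rng):
        a = rng.normal(100, 1.0, 6)
        b = rng.normal(100.5, 1.5, 5)
        res = two_sample_t_f(a, b)
        na, nb = len(a), len(b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert res.t_stat == pytest.approx(t, abs=1e-10)
        assert res.f_stat == pytest.approx(max(va, vb) / min(va, vb), abs=1e-10)
        # cross-check against the library implementation
        t_scipy = stats.ttest_ind(a, b, equal_var=True)
        assert res.t_stat == pytest.approx(t_scipy.statistic, abs=1e-10)

    def test_larger_variance_in_numerator(self, rng):
        a = rng.normal(100, 0.2, 4)
        b = rng.normal(100, 2.0, 4)
        assert two_sample_t_f(a, b).f_stat >= 1.0

    def test_welch_variant(self, rng):
        a = rng.normal(100, 0.5, 5)
        b = rng.normal(100, 2.0, 5)
        res = two_sample_t_f(a, b, welch=True)
        t_scipy = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_stat == pytest.approx(t_scipy.statistic, abs=1e-10)

    def test_both_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_f([1.0, 1.0], [2.0, 2.0])


class TestOneWayAnova:
    def test_hand_computed_sums(self):
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.ss_between == pytest.approx(13.5, abs=1e-12)
        assert res.ss_within == pytest.approx(4.0, abs=1e-12)
        assert res.eta_squared == pytest.approx(13.5 / 17.5, abs=1e-12)

    def test_identical_constant_groups_flagged(self):
        res = one_way_anova([[5.0, 5.0], [5.0, 5.0]])
        assert res.f_undefined and res.f is None

    def test_matches_scipy(self, rng):
        groups = [list(rng.normal(100, 1, 4)) for _ in range(4)]
        res = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert res.f == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_consistent_with_anova_from_sums(self, rng):
        groups = [list(rng.normal(100, 1, 3)) for _ in range(4)]
        res = one_way_anova(groups)
        ms_b, ms_w, f, eta = anova_from_sums(
            res.ss_between, res.df_between, res.ss_within, res.df_within
        )
        assert f == pytest.approx(res.f, abs=1e-12)
        assert eta == pytest.approx(res.eta_squared, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.lists(
                st.floats(min_value=-100, max_value=100, allow_nan=False),
                min_size=2,
                max_size=6,
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_sum_of_squares_additivity_and_eta_bounds(self, groups):
        res = one_way_anova(groups)
        assert res.ss_total == pytest.approx(
            res.ss_between + res.ss_within, abs=1e-6 * max(1.0, res.ss_total)
        )
        if res.eta_squared is not None:
            assert -1e-12 <= res.eta_squared <= 1 + 1e-12


class TestAnovaFromSums:
    def test_unit_case(self):
        ms_b, ms_w, f, eta = anova_from_sums(1.0, 1.0, 1.0, 1.0)
        assert (ms_b, ms_w, f, eta) == (1.0, 1.0, 1.0, 0.5)

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            anova_from_sums(1.0, 0.0, 1.0, 8.0)


class TestCriticalValues:
    def test_t_two_sided(self):
        assert round(t_critical(0.05, 4), 2) == 2.78

    def test_f_upper_tail(self):
        assert round(f_critical(0.05, 3, 8), 2) == 4.07
        assert f_critical(0.05, 2, 2) == pytest.approx(19.0, abs=0.01)

    def test_t_monotone_in_df(self):
        values = [t_critical(0.05, df) for df in (1, 2, 4, 8, 30, 120)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            t_critical(0.0, 4)
        with pytest.raises(ValueError):
            f_critical(0.05, 0, 8)
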