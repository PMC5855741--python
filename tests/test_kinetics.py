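"""Kinetics tables, summary ratios, fading, CV, KDE and group tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from focidyn import kinetics as kin
from focidyn.synthetic import SimulationConfig, kinetic_profile


def _flat_table(level, n=76, condition="control"):
    m = np.arange(n, dtype=float)
    y = np.full(n, float(level))
    return kin.KineticsTable(condition, m, y, np.zeros(n), 1, y.copy())


class TestBuildKinetics:
    def test_single_nucleus(self):
        series = np.arange(10.0)
        t = kin.build_kinetics(series, "control")
        assert np.allclose(t.mean, series)
        assert np.allclose(t.sd, 0.0)

    def test_two_constant_series(self):
        t = kin.build_kinetics(np.array([[2.0] * 8, [4.0] * 8]), "alpha")
        assert np.allclose(t.mean, 3.0)
        assert np.allclose(t.sd, np.sqrt(2.0))  # sample SD

    def test_smoother_keeps_peak_position(self):
        for cond in ("alpha", "xray", "mixed"):
            prof = kinetic_profile(SimulationConfig(condition=cond))
            sm = kin.smooth_series(prof)
            assert abs(int(np.argmax(sm)) - int(np.argmax(prof))) <= 1


class TestSummaries:
    def test_printed_ratios(self):
        ctrl = _flat_table(1.5)
        xray = _flat_table(1.0, condition="xray")
        xray.mean[:] = 9.7
        xray.mean[16] = 15.3
        xray.mean[-1] = 8.7
        row = kin.summarize_kinetics(xray, ctrl).rounded()
        assert row.max_increase == 10.2   # 15.3 / 1.5
        assert row.max_reduction == 1.8   # 15.3 / 8.7
        assert row.peak_minute == 16

    def test_peak_to_final_ratio(self):
        t = _flat_table(6.9, condition="alpha")
        t.mean[11] = 8.1
        row = kin.summarize_kinetics(t, _flat_table(1.5)).rounded()
        assert row.max_reduction == 1.2

    def test_constant_series_reduction_one(self):
        row = kin.summarize_kinetics(_flat_table(5.0), _flat_table(1.5))
        assert row.max_reduction == pytest.approx(1.0)

    def test_zero_control_errors(self):
        with pytest.raises(ValueError):
            kin.summarize_kinetics(_flat_table(5.0), _flat_table(0.0))


class TestExpectedMixed:
    def test_pointwise_half_sum(self):
        a = _flat_table(6.4, condition="alpha")
        x = _flat_table(9.7, condition="xray")
        e = kin.expected_mixed(a, x)
        assert e.fitted[0] == pytest.approx(8.05)

    def test_idempotent_on_identical_inputs(self):
        a = _flat_table(5.0)
        e = kin.expected_mixed(a, a)
        assert np.allclose(e.fitted, a.fitted)

    def test_grid_mismatch_errors(self):
        a = _flat_table(5.0, n=76)
        b = _flat_table(5.0, n=75)
        with pytest.raises(ValueError):
            kin.expected_mixed(a, b)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_linearity(self, scale):
        rng = np.random.default_rng(1)
        y1, y2 = rng.uniform(1, 10, 20), rng.uniform(1, 10, 20)
        m = np.arange(20.0)

        def table(y):
            return kin.KineticsTable("c", m, y, np.zeros(20), 1, y)

        e1 = kin.expected_mixed(table(scale * y1), table(scale * y2))
        e0 = kin.expected_mixed(table(y1), table(y2))
        assert np.allclose(e1.fitted, scale * e0.fitted)

    def test_expected_summary_row(self):
        ctrl = _flat_table(1.5)
        a = kin.SummaryRow("alpha", 6.4, 8.1, 11, 6.9, 5.4, 1.2)
        x = kin.SummaryRow("xray", 9.7, 15.3, 16, 8.7, 10.2, 1.8)
        e = kin.expected_summary(a, x, ctrl)
        assert e.initial == pytest.approx(8.05)
        assert e.highest == pytest.approx(11.7)
        assert e.final == pytest.approx(7.8)


class TestRelativeAndFading:
    def test_treated_equals_control(self):
        c = np.linspace(100, 80, 10)
        rel = kin.relative_to_control(c, c)
        assert np.allclose(rel.ratio, 1.0)

    def test_double_control(self):
        c = np.linspace(100, 80, 10)
        rel = kin.relative_to_control(2 * c, c)
        assert np.allclose(rel.ratio, 2.0)

    def test_nonpositive_control_errors(self):
        with pytest.raises(ValueError):
            kin.relative_to_control(np.ones(3), np.array([1.0, 0.0, 1.0]))

    def test_sem_propagation(self):
        rel = kin.relative_to_control(
            np.array([10.0]), np.array([5.0]),
            treated_sem=np.array([1.0]), control_sem=np.array([0.5]))
        expect = 2.0 * np.sqrt((1 / 10) ** 2 + (0.5 / 5) ** 2)
        assert rel.sem[0] == pytest.approx(expect)

    def test_exact_fading_line(self):
        t = np.arange(76.0)
        slope, intercept, loss = kin.fit_control_fading(t, 139.3 - (34.7 / 75) * t)
        assert intercept + slope * 75 == pytest.approx(104.6, abs=1e-9)
        assert round(loss) == 25

    def test_constant_series_no_loss(self):
        _, _, loss = kin.fit_control_fading(np.arange(10.0), np.full(10, 100.0))
        assert loss == 0.0

    def test_noisy_line_slope_within_2se(self):
        rng = np.random.default_rng(4)
        t = np.arange(76.0)
        y = 139.3 - 0.4627 * t + rng.normal(0, 2.0, 76)
        slope, _, _ = kin.fit_control_fading(t, y)
        se = stats.linregress(t, y).stderr
        assert abs(slope - (-0.4627)) < 2 * se


class TestCV:
    def test_constant_zero(self):
        assert kin.coefficient_of_variation(np.full(10, 3.0)) == 0.0

    def test_hand_value(self):
        assert kin.coefficient_of_variation([1.0, 3.0]) == pytest.approx(np.sqrt(2) / 2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(7)
        y = rng.uniform(1, 5, 30)
        assert kin.coefficient_of_variation(scale * y) == pytest.approx(
            kin.coefficient_of_variation(y), rel=1e-9)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            kin.coefficient_of_variation([-1.0, 1.0])


class TestKDE:
    def test_single_point_is_kernel(self):
        d = kin.kde_intensity(np.array([2.0]), bandwidth=0.5)
        assert d.grid[np.argmax(d.density)] == pytest.approx(2.0, abs=0.01)
        # density at the mode of a normal: 1/(h*sqrt(2*pi))
        assert d.density.max() == pytest.approx(1 / (0.5 * np.sqrt(2 * np.pi)), rel=0.01)

    def test_symmetric_two_points(self):
        d = kin.kde_intensity(np.array([-1.0, 1.0]), bandwidth=0.4)
        mid = d.grid.mean()
        left = np.interp(mid - 0.7, d.grid, d.density)
        right = np.interp(mid + 0.7, d.grid, d.density)
        assert left == pytest.approx(right, rel=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), h=st.floats(0.05, 2.0))
    def test_unit_area(self, n, h):
        rng = np.random.default_rng(n)
        d = kin.kde_intensity(rng.normal(size=n), bandwidth=h)
        assert d.area() == pytest.approx(1.0, abs=0.01)

    def test_matches_scipy_with_same_bandwidth(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        h = 0.3
        ours = kin.kde_intensity(x, bandwidth=h)
        ref = stats.gaussian_kde(x, bw_method=h / x.std(ddof=1))
        assert np.allclose(ours.density, ref(ours.grid), rtol=0.02, atol=1e-3)

    def test_ise_decreases_with_n(self):
        true = stats.norm.pdf

        def ise(n, seed):
            rng = np.random.default_rng(seed)
            d = kin.kde_intensity(rng.normal(size=n))
            return np.trapezoid((d.density - true(d.grid)) ** 2, d.grid)

        assert ise(2000, 3) < ise(50, 3)

    def test_bad_bandwidth_errors(self):
        with pytest.raises(ValueError):
            kin.kde_intensity(np.array([1.0]), bandwidth=0.0)


class TestGroupComparisons:
    def test_identical_groups(self):
        g = [1.0, 2.0, 3.0]
        f, p, sig = kin.anova_conditions([g, g, g])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_f_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, s, 25) for m, s in [(0, 1), (0.5, 1.2), (1.2, 0.8)]]
        f, p, _ = kin.anova_conditions(groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = len(groups), sum(len(g) for g in groups)
        f_oracle = (ssb / (k - 1)) / (ssw / (n - k))
        assert f == pytest.approx(f_oracle, rel=1e-10)

    def test_uniform_2x2_chi_square_zero(self):
        chi2, p, sig = kin.chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == pytest.approx(0.0)
        assert not sig

    def test_degenerate_groups_error(self):
        with pytest.raises(ValueError):
            kin.anova_conditions([[1.0], [2.0, 3.0]])
        with pytest.raises(ValueError):
            kin.chi_square_2x2([[1, 2, 3], [4, 5, 6]])
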