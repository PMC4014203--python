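"""DVH curves, dose/volume queries, HI/CI, and deviation statistics."""

import numpy as np
import pytest
from scipy import stats

from rtqa.core import DoseGrid
from rtqa.dvh import (DVHCurve, MetricSet, conformity_index, cumulative_dvh,
                      deviation_summary, dose_at_volume, homogeneity_index,
                      relative_deviation, volume_at_dose)


def curve_from(doses):
    return DVHCurve("s", np.sort(np.asarray(doses, float))[::-1], 0.001)


def grid_with(doses, shape=None):
    doses = np.asarray(doses, float)
    n = doses.size
    if shape is None:
        shape = (n, 1, 1)
    return DoseGrid(doses.reshape(shape), (1.0, 1.0, 1.0))


class TestCumulativeDVH:
    def test_uniform_dose_step_curve(self):
        g = grid_with(np.full(10, 7000.0))
        c = cumulative_dvh(g, np.ones(g.shape, bool))
        assert c.volume_fraction(0.0) == 1.0
        assert c.volume_fraction(7000.0) == 1.0  # inclusive boundary
        assert c.volume_fraction(7000.1) == 0.0

    def test_two_voxel_curve(self):
        g = grid_with([60.0, 100.0])
        c = cumulative_dvh(g, np.ones(g.shape, bool))
        assert c.volume_fraction(80.0) == 0.5

    def test_empty_mask_raises(self):
        g = grid_with([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            cumulative_dvh(g, np.zeros(g.shape, bool), "cord")

    def test_curve_monotone_nonincreasing(self, rng):
        g = grid_with(rng.uniform(0, 100, 200))
        c = cumulative_dvh(g, np.ones(g.shape, bool))
        d = np.linspace(0, 110, 300)
        v = c.volume_fraction(d)
        assert np.all(np.diff(v) <= 0)
        assert v[0] == 1.0 and v[-1] == 0.0

    def test_mean_dose_is_arithmetic_mean(self, rng):
        doses = rng.uniform(0, 100, 321)
        c = curve_from(doses)
        assert c.mean_dose == pytest.approx(doses.mean(), abs=1e-12)

    def test_radial_ramp_in_ball_closed_form(self):
        # dose = 100 * r/R inside a ball: V(d) = 1 - (d/100)^3,
        # D50% = 100 * 2^(-1/3), Dmean = 75
        R = 20.0
        n = 45
        g = DoseGrid(np.zeros((n, n, n)), (1.0, 1.0, 1.0),
                     origin=(-(n - 1) / 2.0,) * 3)
        xs, ys, zs = g.coords()
        gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
        r = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        mask = r <= R
        dose = g.like(np.where(mask, 100.0 * r / R, 0.0))
        c = cumulative_dvh(dose, mask)
        assert dose_at_volume(c, 0.50) == pytest.approx(100 * 2 ** (-1 / 3),
                                                        rel=0.02)
        assert c.mean_dose == pytest.approx(75.0, rel=0.02)
        assert c.volume_fraction(50.0) == pytest.approx(1 - 0.5 ** 3, rel=0.02)


class TestDoseVolumeQueries:
    def test_uniform_dose_every_quantile(self):
        c = curve_from(np.full(7, 123.0))
        for v in (0.02, 0.5, 0.95, 1.0):
            assert dose_at_volume(c, v) == 123.0

    def test_order_statistic_interpolation(self):
        c = curve_from(np.arange(1.0, 101.0))
        assert dose_at_volume(c, 0.50) == pytest.approx(50.5, abs=1e-12)
        assert dose_at_volume(c, 1.0) == 1.0   # minimum voxel dose
        # brute-force oracle: interpolate dose vs (i-0.5)/n over sorted doses
        desc = np.arange(100.0, 0.0, -1.0)
        pos = (np.arange(1, 101) - 0.5) / 100.0
        for v in (0.02, 0.10, 0.333, 0.98):
            assert dose_at_volume(c, v) == pytest.approx(
                np.interp(v, pos, desc), abs=1e-9)

    def test_v_at_dose_boundary_inclusive(self):
        c = curve_from([90.0, 95.0, 100.0, 105.0])
        assert volume_at_dose(c, 95.0, percent=True, prescription=100.0) == 0.75
        assert volume_at_dose(c, 200.0) == 0.0
        assert volume_at_dose(c, 100.0, percent=True, prescription=100.0) == 0.5

    def test_percent_without_prescription_raises(self):
        c = curve_from([1.0, 2.0])
        with pytest.raises(ValueError, match="prescription"):
            volume_at_dose(c, 95.0, percent=True)

    def test_invalid_volume_fraction(self):
        c = curve_from([1.0, 2.0])
        for v in (0.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                dose_at_volume(c, v)

    def test_queries_mutually_inverse_on_monotone_curve(self, rng):
        doses = np.sort(rng.uniform(10, 90, 500))
        c = curve_from(doses)
        for v in (0.1, 0.33, 0.5, 0.77, 0.9):
            d = dose_at_volume(c, v)
            # counting V(d) brackets the query fraction to within one voxel
            assert abs(c.volume_fraction(d) - v) <= 1.5 / c.n


class TestIndices:
    def test_uniform_dose_hi_zero(self):
        m = MetricSet("t", d2=70.0, d50=70.0, d95=70.0, d98=70.0, dmean=70.0)
        assert homogeneity_index(m) == 0.0

    def test_hi_arithmetic(self):
        m = MetricSet("t", d2=74.8, d50=70.0, d95=0, d98=66.2, dmean=0)
        assert homogeneity_index(m) == pytest.approx(0.122857, abs=1e-6)

    def test_hi_scale_invariant(self):
        m1 = MetricSet("t", d2=74.8, d50=70.0, d95=0, d98=66.2, dmean=0)
        m2 = MetricSet("t", d2=149.6, d50=140.0, d95=0, d98=132.4, dmean=0)
        assert homogeneity_index(m1) == pytest.approx(homogeneity_index(m2),
                                                      abs=1e-12)

    def test_ci_perfectly_conformal(self):
        vals = np.zeros((10, 10, 10))
        mask = np.zeros((10, 10, 10), bool)
        mask[3:7, 3:7, 3:7] = True
        vals[mask] = 100.0
        g = DoseGrid(vals, (1.0, 1.0, 1.0))
        assert conformity_index(g, mask, 100.0) == 1.0

    def test_ci_arithmetic(self):
        # PTV 100 voxels, 95 covered, total hot volume 120 -> 0.752083
        vals = np.zeros((300, 1, 1))
        mask = np.zeros((300, 1, 1), bool)
        mask[:100] = True
        vals[:95] = 100.0       # covered PTV voxels
        vals[150:175] = 100.0   # 25 hot voxels outside the PTV
        g = DoseGrid(vals, (1.0, 1.0, 1.0))
        assert conformity_index(g, mask, 100.0 / 0.95) == pytest.approx(
            (95 / 100) * (95 / 120), abs=1e-12)
        assert conformity_index(g, mask, 100.0 / 0.95) == pytest.approx(
            0.752083, abs=1e-6)

    def test_ci_no_coverage_zero_with_warning(self):
        g = DoseGrid(np.full((4, 4, 4), 10.0), (1.0, 1.0, 1.0))
        mask = np.ones((4, 4, 4), bool)
        with pytest.warns(UserWarning, match="CI"):
            assert conformity_index(g, mask, 7000.0) == 0.0

    def test_ci_bounded_by_coverage_and_selectivity(self, rng):
        vals = rng.uniform(0, 110, (12, 12, 12))
        mask = np.zeros((12, 12, 12), bool)
        mask[4:9, 4:9, 4:9] = True
        g = DoseGrid(vals, (1.0, 1.0, 1.0))
        ci = conformity_index(g, mask, 100.0)
        assert 0.0 <= ci <= 1.0


class TestDeviations:
    def test_relative_deviation_examples(self):
        assert relative_deviation(2.1, 2.0) == pytest.approx(5.0)
        assert relative_deviation(3.3, 3.3) == 0.0
        assert relative_deviation(67.55, 100.0) == pytest.approx(-32.45)
        with pytest.raises(ValueError):
            relative_deviation(1.0, 0.0)

    def test_summary_frozen_values(self):
        s = deviation_summary([1, 2, 3, 4, 5])
        assert s.mean == 3.0
        assert s.std == pytest.approx(1.58114, abs=1e-5)
        assert s.t == pytest.approx(4.24264, abs=1e-5)
        assert s.df == 4
        assert s.p == pytest.approx(0.01324, abs=1e-5)
        assert s.minimum == 1.0 and s.maximum == 5.0

    def test_summary_degenerate_conventions(self):
        assert deviation_summary([0.0, 0.0, 0.0]).p == 1.0
        s = deviation_summary([-1.0, 1.0])
        assert s.t == 0.0 and s.p == 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            s = deviation_summary([2.0, 2.0, 2.0])
        assert s.degenerate and np.isnan(s.p)

    def test_summary_needs_two_points(self):
        with pytest.raises(ValueError):
            deviation_summary([1.0])

    def test_matches_reference_t_test(self, rng):
        for _ in range(25):
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2.0),
                           size=rng.integers(3, 40))
            s = deviation_summary(x)
            ref = stats.ttest_1samp(x, 0.0)
            assert s.t == pytest.approx(ref.statistic, abs=1e-9)
            assert s.p == pytest.approx(ref.pvalue, abs=1e-9)
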