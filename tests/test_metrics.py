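"""Performance metrics: bias, RC/wCV, linearity, b-value dependence,
random error and difference-method SNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qdwiqc import (RepeatedMeasurements, adc_bias, bvalue_dependence,
                    linearity, make_noise_image, random_error,
                    rc_wcv_from_summary, repeatability, round1, snr)
from qdwiqc.roi import VOIStats


class TestBias:
    @pytest.mark.parametrize("mu, dc, bias, pct", [
        (1100.0, 1100.0, 0.0, 0.0),
        (1078.0, 1100.0, -22.0, -2.0),
        (1056.0, 1100.0, -44.0, -4.0),
    ])
    def test_closed_form(self, mu, dc, bias, pct):
        b, p = adc_bias(mu, dc)
        assert b == pytest.approx(bias)
        assert p == pytest.approx(pct)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            adc_bias(1000.0, 0.0)


class TestRepeatability:
    def test_single_group_summary_reproduces_patient_table_row(self):
        """sigma_w 16.2 about mean 801.4 gives RC 44.9 and wCV 2.0."""
        rc, wcv = rc_wcv_from_summary(801.4, 16.2)
        assert round1(rc) == 44.9
        assert round1(wcv) == 2.0

    def test_identical_observations_have_zero_spread(self):
        rep = repeatability(RepeatedMeasurements(
            {"a": [1100.0, 1100.0], "b": [900.0, 900.0, 900.0]}))
        assert rep.sigma_w == 0.0
        assert rep.rc == 0.0
        assert rep.wcv_percent == 0.0

    def test_pooled_variance_oracle(self):
        """Groups with variances 4 and 16 pool to sigma_w = sqrt(10)."""
        g1 = [100.0 - np.sqrt(2.0), 100.0 + np.sqrt(2.0)]  # var 4
        g2 = [200.0 - np.sqrt(8.0), 200.0 + np.sqrt(8.0)]  # var 16
        rep = repeatability(RepeatedMeasurements({"g1": g1, "g2": g2}))
        assert rep.sigma_w == pytest.approx(np.sqrt(10.0), rel=1e-12)
        assert rep.rc == pytest.approx(2.77 * np.sqrt(10.0), rel=1e-12)
        assert rep.grand_mean == pytest.approx(150.0)

    def test_all_singletons_rejected(self):
        with pytest.raises(ValueError):
            repeatability(RepeatedMeasurements({"a": [1.0], "b": [2.0]}))

    def test_singleton_groups_ignored_when_pairs_exist(self):
        rep = repeatability(RepeatedMeasurements(
            {"a": [10.0, 12.0], "b": [999.0]}))
        assert rep.n_groups == 1
        assert rep.n_observations == 2

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 9999))
    def test_identities_and_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        groups = {f"g{i}": list(rng.normal(800, 20, rng.integers(2, 5)))
                  for i in range(4)}
        rep = repeatability(RepeatedMeasurements(groups))
        assert rep.rc == pytest.approx(2.77 * rep.sigma_w, rel=1e-12)
        assert rep.wcv_percent == pytest.approx(
            100.0 * rep.sigma_w / rep.grand_mean, rel=1e-12)
        relabeled = {f"x{i}": v for i, (_, v) in enumerate(groups.items())}
        rep2 = repeatability(RepeatedMeasurements(relabeled))
        assert rep2.sigma_w == pytest.approx(rep.sigma_w, rel=1e-12)

    def test_duplicated_data_has_zero_sigma(self):
        groups = {"a": [810.0, 810.0], "b": [795.5, 795.5]}
        assert repeatability(RepeatedMeasurements(groups)).sigma_w == 0.0


class TestLinearity:
    def test_exact_identity_line(self):
        pts = [(v, v) for v in (1100.0, 900.0, 600.0, 400.0, 250.0)]
        fit = linearity(pts)
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        lo, hi = fit.slope_ci
        assert lo == pytest.approx(hi, abs=1e-8)

    def test_exact_proportional_fit_recovers_attenuated_slope(self):
        pts = [(v, 0.98 * v) for v in (1100.0, 900.0, 600.0, 400.0, 250.0)]
        fit = linearity(pts)
        assert fit.slope == pytest.approx(0.98, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_normal_equations_and_t_interval(self):
        # x = 1,2,3; y = 1,2.1,2.9: slope 0.95, intercept 0.1,
        # SSres 0.015, SE = sqrt(0.015/2), t(0.975, 1) = 12.7062
        fit = linearity([(1.0, 1.0), (2.0, 2.1), (3.0, 2.9)])
        assert fit.slope == pytest.approx(0.95, rel=1e-12)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        se = np.sqrt(0.015 / 2.0)
        half = 12.706204736 * se
        assert fit.slope_ci[0] == pytest.approx(0.95 - half, rel=1e-6)
        assert fit.slope_ci[1] == pytest.approx(0.95 + half, rel=1e-6)

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ValueError):
            linearity([(1.0, 1.0), (1.0, 1.1), (1.0, 0.9)])
        with pytest.raises(ValueError):
            linearity([(1.0, 1.0), (2.0, 2.0)])


class TestBValueDependence:
    def test_equal_adcs_give_zero(self):
        assert bvalue_dependence({500.0: 1000.0, 1000.0: 1000.0}) == 0.0

    def test_arithmetic_oracle(self):
        # values {1000, 1000, 1020, 1000}: mean 1005, max |dev| 15
        dep = bvalue_dependence({500.0: 1000.0, 1000.0: 1000.0,
                                 1500.0: 1020.0, 2000.0: 1000.0})
        assert dep == pytest.approx(100.0 * 15.0 / 1005.0, rel=1e-12)

    def test_single_nonzero_b_not_evaluable(self):
        assert bvalue_dependence({1000.0: 990.0}) is None


class TestRandomError:
    def test_closed_form(self):
        voi = VOIStats("c", 10, mean=1100.0, sd=11.0, min=1000.0,
                       max=1200.0)
        assert random_error(voi) == pytest.approx(1.0)

    def test_zero_sd(self):
        voi = VOIStats("c", 10, mean=1100.0, sd=0.0, min=1100.0,
                       max=1100.0)
        assert random_error(voi) == 0.0


class TestNoiseImageAndSNR:
    def test_identical_repeats_zero_noise(self):
        vol = np.full((2, 4, 4), 450.0)
        assert np.all(make_noise_image(vol, vol) == 0.0)

    def test_constant_offset(self):
        a = np.full((2, 4, 4), 100.0)
        img = make_noise_image(a, a + 2.0)
        assert np.allclose(img, 2.0 / np.sqrt(2.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_noise_image(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_gaussian_noise_level_matches_monte_carlo_oracle(self, rng):
        """Mean of |d|/sqrt(2), d ~ N(0, 2 sigma^2), is sigma*sqrt(2/pi)."""
        sigma = 5.0
        r1 = rng.normal(0, sigma, 100_000)
        r2 = rng.normal(0, sigma, 100_000)
        mc = np.mean(np.abs(r1 - r2)) / np.sqrt(2.0)
        assert mc == pytest.approx(sigma * np.sqrt(2.0 / np.pi), rel=0.02)
        img = make_noise_image(r1.reshape(100, 100, 10) + 400.0,
                               r2.reshape(100, 100, 10) + 400.0)
        assert img.mean() == pytest.approx(mc, rel=1e-12)

    def test_snr_is_ratio_of_spatial_means(self):
        signal = np.full((1, 4, 4), 450.0)
        noise = np.full((1, 4, 4), 10.0)
        mask = np.ones_like(signal, dtype=bool)
        assert snr(signal, noise, mask) == pytest.approx(45.0)

    def test_zero_noise_not_evaluable(self):
        signal = np.full((1, 4, 4), 450.0)
        mask = np.ones_like(signal, dtype=bool)
        assert snr(signal, np.zeros_like(signal), mask) is None


class TestRounding:
    @pytest.mark.parametrize("x, expected", [
        (2.94, 2.9), (2.95, 3.0), (44.874, 44.9), (2.0215, 2.0),
        (-2.25, -2.3),
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round1(x) == expected
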