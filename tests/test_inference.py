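"""z_F estimation: bounds, robust regressions, segment/slope, model fits."""

import numpy as np
import pytest

from hitsurv import (
    AlphaBetaRecord,
    SegmentConfig,
    SimulationConfig,
    SurvivalCurve,
    SurvivalModel,
    detect_linear_segment,
    fit_survival_model,
    lq_alpha,
    lq_beta,
    predict_zfmax,
    prune_model_order,
    regress_zfmax_loglinear,
    regress_zfmax_polynomial,
    simulate_alpha_beta_dataset,
    simulate_curve,
    zf_from_slope,
    zf_upper_bound,
)
from hitsurv.inference import (
    InsufficientDataError,
    NotAsymptoticError,
    _rlm_fit,
)

from conftest import random_valid_models


def records_on_line(a, b, lets):
    """Noise-free records whose z_F,max sits exactly on a*ln(LET) + b."""
    recs = []
    for i, let in enumerate(lets):
        z = a * np.log(let) + b
        t = (i % 5) / 5.0  # deterministic alpha/beta splits
        recs.append(
            AlphaBetaRecord(alpha=t / z, beta=(1 - t) ** 2 / (2 * z ** 2), let=let)
        )
    return recs


class TestUpperBound:
    @pytest.mark.parametrize(
        "alpha,beta,expected",
        [(1.0, 0.0, 1.0), (0.0, 0.5, 1.0), (0.5, 0.045, 1.25)],
    )
    def test_closed_form(self, alpha, beta, expected):
        assert zf_upper_bound(alpha, beta) == pytest.approx(expected, rel=1e-12)

    def test_unbounded_flagged_as_inf(self):
        assert np.isinf(zf_upper_bound(0.0, 0.0))

    def test_monotone_decreasing_in_both_arguments(self):
        a = np.linspace(0.01, 2, 30)
        assert np.all(np.diff(zf_upper_bound(a, 0.05)) < 0)
        assert np.all(np.diff(zf_upper_bound(0.3, a)) < 0)

    def test_bounds_any_valid_model(self):
        # zf_upper_bound(alpha(m), beta(m)) >= m.z_f whenever s2 <= s1^2
        rng = np.random.default_rng(11)
        for m in random_valid_models(rng, 50):
            assert zf_upper_bound(lq_alpha(m), lq_beta(m)) >= m.z_f - 1e-12


class TestRegression:
    def test_noiseless_recovery_exact(self):
        recs = records_on_line(-0.3, 2.5, np.geomspace(0.5, 70, 40))
        res = regress_zfmax_loglinear(recs, n_boot=0)
        assert res.coef == pytest.approx([-0.3, 2.5], abs=1e-10)

    def test_robust_equals_ols_on_clean_data(self):
        recs = records_on_line(-0.3, 2.5, np.geomspace(0.5, 70, 40))
        x = np.log([r.let for r in recs])
        y = zf_upper_bound(
            np.array([r.alpha for r in recs]), np.array([r.beta for r in recs])
        )
        ols = np.polyfit(x, y, 1)
        rob = _rlm_fit(x, y, 1).params
        assert rob == pytest.approx(ols, abs=1e-8)

    def test_noisy_recovery_and_outlier_resistance(self):
        truth = np.array([-0.3, 2.5])
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            recs = simulate_alpha_beta_dataset(
                truth, (0.5, 70), 100, SimulationConfig(seed=seed),
                scatter=0.1, outlier_rate=0.05,
            )
            res = regress_zfmax_loglinear(recs, n_boot=0)
            x = np.log([r.let for r in recs])
            y = np.asarray(zf_upper_bound(
                np.array([r.alpha for r in recs]),
                np.array([r.beta for r in recs]),
            ))
            ols = np.polyfit(x, y, 1)
            if np.linalg.norm(res.coef - truth) < np.linalg.norm(ols - truth):
                wins += 1
            err = np.abs(res.coef - truth)
            assert np.all(err < 2 * np.hypot(res.se, res.se))  # 2 combined se
        assert wins >= 0.9 * n_seeds

    def test_polynomial_noiseless_recovery(self):
        coef = np.array([0.27, -2.7, 7.4])
        lets = np.geomspace(21.8, 654, 50)
        recs = []
        for i, let in enumerate(lets):
            z = np.polyval(coef, np.log(let))
            t = (i % 4) / 4.0
            recs.append(AlphaBetaRecord(alpha=t / z, beta=(1 - t) ** 2 / (2 * z ** 2), let=let))
        res = regress_zfmax_polynomial(recs, 2, n_boot=0)
        assert res.coef == pytest.approx(coef, abs=1e-9)

    def test_polynomial_noisy_recovery(self):
        coef = np.array([0.27, -2.7, 7.4])
        recs = simulate_alpha_beta_dataset(
            coef, (21.8, 654), 82, SimulationConfig(seed=4), scatter=0.2
        )
        res = regress_zfmax_polynomial(recs, 2, n_boot=0)
        assert np.all(np.abs(res.coef - coef) < 2 * res.se)

    def test_insufficient_distinct_let_rejected(self):
        recs = records_on_line(-0.3, 2.5, [1.0, 1.0, 1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            regress_zfmax_loglinear(recs)

    def test_band_contains_point_estimate(self):
        recs = simulate_alpha_beta_dataset(
            [-0.31, 2.5], (0.42, 73.2), 60, SimulationConfig(seed=9), scatter=0.3
        )
        res = regress_zfmax_loglinear(recs, n_boot=200, seed=0)
        center = res.predict(res.band_let)
        assert np.all(res.band_lo <= center + 1e-12)
        assert np.all(res.band_hi >= center - 1e-12)


class TestPrediction:
    def test_photon_coefficients_at_xray_let(self):
        # fixed-coefficient regression evaluated at the 55 kV x-ray LET
        from hitsurv.inference import RegressionResult

        res = RegressionResult(
            kind="loglinear",
            coef=np.array([-0.37, 2.4]),
            se=np.array([0.12, 0.1]),
            cov=np.diag([0.12 ** 2, 0.1 ** 2]),
            loss="huber",
            let_range=(0.40, 10.5),
            n_records=139,
        )
        pred = predict_zfmax(res, 2.29)
        assert pred.zf_max == pytest.approx(2.09, abs=0.005)
        assert not pred.extrapolated
        assert pred.sd > 0

    def test_constant_model(self):
        from hitsurv.inference import RegressionResult

        res = RegressionResult(
            kind="loglinear", coef=np.array([0.0, 1.7]), se=np.zeros(2),
            cov=np.zeros((2, 2)), loss="huber", let_range=(1, 10), n_records=10,
        )
        assert predict_zfmax(res, 3.3).zf_max == pytest.approx(1.7)

    def test_extrapolation_flagged(self):
        from hitsurv.inference import RegressionResult

        res = RegressionResult(
            kind="loglinear", coef=np.array([-0.31, 2.5]), se=np.zeros(2),
            cov=np.zeros((2, 2)), loss="huber", let_range=(1.0, 73.2), n_records=91,
        )
        assert predict_zfmax(res, 0.74).extrapolated
        assert predict_zfmax(res, 0.74).zf_max == pytest.approx(2.59, abs=0.005)


class TestLinearSegment:
    def test_exactly_linear_returns_full_range(self):
        d = np.linspace(0.5, 14, 12)
        curve = SurvivalCurve(doses=d, surviving_fraction=np.exp(-d / 2))
        assert detect_linear_segment(curve) == (0, 12)

    def test_shoulder_excluded(self, xray_model):
        d = np.arange(0.5, 14.1, 0.5)
        curve = simulate_curve(xray_model, d, SimulationConfig(seed=1, noise_sigma=0.05))
        start, stop = detect_linear_segment(curve)
        assert stop == len(curve)
        assert curve.doses[start] >= 4.0  # shoulder (low-dose curvature) excluded

    def test_minimum_points_honored(self, xray_model):
        d = np.arange(1.0, 8.1, 1.0)
        curve = simulate_curve(xray_model, d, SimulationConfig(seed=3))
        start, stop = detect_linear_segment(curve, SegmentConfig(min_points=2))
        assert stop - start >= 2
        assert stop == len(curve)

    def test_too_few_points_rejected(self):
        d = np.array([1.0, 2.0, 3.0])
        curve = SurvivalCurve(doses=d, surviving_fraction=np.exp(-d))
        with pytest.raises(InsufficientDataError):
            detect_linear_segment(curve)


class TestZfFromSlope:
    def test_exact_exponential(self):
        d = np.linspace(1, 10, 10)
        curve = SurvivalCurve(doses=d, surviving_fraction=np.exp(-d / 2))
        est = zf_from_slope(curve, (0, 10))
        assert est.z_f == pytest.approx(2.0, rel=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_converges_with_window_position(self, xray_model):
        # residual curvature of ln S decays like 2 z_F / D, so the slope
        # estimate approaches the true z_F as the window moves right
        estimates = []
        for lo in (10.0, 30.0, 80.0):
            d = np.linspace(lo, lo + 6, 7)
            curve = simulate_curve(xray_model, d, SimulationConfig(seed=0))
            estimates.append(zf_from_slope(curve, (0, 7)).z_f)
        assert estimates[0] == pytest.approx(1.148, abs=0.01)
        assert estimates[2] == pytest.approx(1.024, abs=0.01)
        assert estimates[0] > estimates[1] > estimates[2] > 1.0

    def test_unbiased_under_noise_with_nominal_coverage(self, xray_model):
        # 100 replicates at 5% lognormal noise over a high-dose window
        d = np.linspace(30, 44, 8)
        truth = zf_from_slope(
            simulate_curve(xray_model, d, SimulationConfig(seed=0)), (0, 8)
        ).z_f  # noiseless window value; noise should scatter around it
        hits, ests = 0, []
        for seed in range(100):
            c = simulate_curve(xray_model, d, SimulationConfig(seed=seed, noise_sigma=0.05))
            est = zf_from_slope(c, (0, 8))
            ests.append(est.z_f)
            if abs(est.z_f - truth) <= est.se:
                hits += 1
        ests = np.array(ests)
        assert abs(np.median(ests) - truth) < 3 * ests.std() / 10  # unbiased
        assert 0.50 <= hits / 100 <= 0.85  # ~68% nominal coverage

    def test_positive_slope_rejected(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        curve = SurvivalCurve(doses=d, surviving_fraction=np.exp(d / 10 - 1))
        with pytest.raises(NotAsymptoticError):
            zf_from_slope(curve, (0, 4))


class TestModelFit:
    def test_noiseless_self_consistency(self, xray_model, dose_grid):
        curve = simulate_curve(xray_model, dose_grid, SimulationConfig(seed=0))
        fit = fit_survival_model(curve, 2)
        assert fit.model.z_f == pytest.approx(1.0, abs=1e-6)
        assert fit.model.s[0] == pytest.approx(1.0, abs=1e-6)
        assert fit.model.s[1] == pytest.approx(0.35, abs=1e-6)

    def test_noisy_recovery_within_2se(self, xray_model, dose_grid):
        curve = simulate_curve(
            xray_model, dose_grid, SimulationConfig(seed=12, noise_sigma=0.05)
        )
        fit = fit_survival_model(curve, 2)
        truth = np.array([1.0, 1.0, 0.35])
        est = np.array([fit.model.z_f, *fit.model.s])
        assert np.all(np.abs(est - truth) <= 2 * np.maximum(fit.se, 1e-6))

    def test_too_few_points_rejected(self, xray_model):
        curve = SurvivalCurve(
            doses=np.array([1.0, 2.0, 3.0]),
            surviving_fraction=np.array([0.9, 0.6, 0.3]),
        )
        with pytest.raises(InsufficientDataError):
            fit_survival_model(curve, 2)


class TestOrderPruning:
    def test_selects_true_order_two(self, xray_model, dose_grid):
        curve = simulate_curve(
            xray_model, dose_grid, SimulationConfig(seed=5, noise_sigma=0.05)
        )
        assert prune_model_order(curve, 3).selected_order == 2

    def test_pure_exponential_selects_zero(self, dose_grid):
        m = SurvivalModel(z_f=1.0, s=())
        curve = simulate_curve(m, dose_grid, SimulationConfig(seed=2))
        assert prune_model_order(curve, 2).selected_order == 0

    def test_strong_s3_keeps_order_three(self, dose_grid):
        m = SurvivalModel(z_f=1.0, s=(1.0, 0.8, 0.5))
        curve = simulate_curve(m, dose_grid, SimulationConfig(seed=2, noise_sigma=0.02))
        assert prune_model_order(curve, 3).selected_order == 3


class TestCurveValidation:
    def test_non_increasing_doses_rejected(self):
        with pytest.raises(ValueError):
            SurvivalCurve(doses=np.array([1.0, 1.0]), surviving_fraction=np.array([0.5, 0.4]))

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ValueError):
            SurvivalCurve(doses=np.array([1.0, 2.0]), surviving_fraction=np.array([1.2, 0.4]))

    def test_negative_beta_record_rejected(self):
        with pytest.raises(ValueError):
            AlphaBetaRecord(alpha=0.1, beta=-0.01, let=2.0)
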