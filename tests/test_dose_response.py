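"""Logistic dose-response fitting, SCD50 bootstrap, TER and significance."""

import numpy as np
import pytest
from scipy.special import expit, xlogy

from scpassay import (
    DoseResponsePoint,
    ExperimentDesign,
    ResponseParams,
    SCPCurveFit,
    bootstrap_scd50,
    compare_scd50,
    compute_ter,
    dose_response_points,
    fit_scp_curve,
    scp_logistic,
    simulate_control_outcomes,
)
from scpassay.errors import DegenerateDataError, FitError, ParameterError

DOSES_11 = tuple(np.arange(0.0, 25.01, 2.5))


def points_from_probs(doses, a, b, n, round_counts=True):
    pts = []
    for d in doses:
        p = expit(a + b * d)
        k = int(round(n * p)) if round_counts else int(n * p)
        pts.append(DoseResponsePoint(dose_gy=d, controlled=k, total=n))
    return pts


def _loglik_oracle(a, b, points):
    # written independently of the package's likelihood helper
    d = np.array([p.dose_gy for p in points])
    y = np.array([p.controlled for p in points], float)
    m = np.array([p.total for p in points], float)
    pi = expit(a + b * d)
    return float(np.sum(xlogy(y, pi) + xlogy(m - y, 1 - pi)))


class TestScpLogistic:
    def test_midpoint_at_zero_dose(self):
        assert scp_logistic(0.0, 0.0, 1.0) == 0.5

    def test_midpoint_at_scd50(self):
        assert scp_logistic(11.1, -5.55, 0.5) == pytest.approx(0.5, abs=1e-12)

    def test_high_dose_value(self):
        # 1/(1 + e^(-6.95))
        assert scp_logistic(25.0, -5.55, 0.5) == pytest.approx(0.9990422829475397, abs=1e-12)

    def test_overflow_safe(self):
        assert scp_logistic(1e4, -5.55, 0.5) == 1.0
        assert scp_logistic(0.0, -1e4, 0.5) == 0.0

    def test_nonfinite_params_rejected(self):
        with pytest.raises(ParameterError):
            scp_logistic(1.0, np.nan, 0.5)


class TestFitScpCurve:
    def test_recovers_truth_at_vanishing_binomial_noise(self):
        pts = points_from_probs(DOSES_11, -5.55, 0.5, n=100_000)
        fit = fit_scp_curve(pts)
        assert fit.converged
        assert fit.scd50_gy == pytest.approx(11.1, abs=0.05)

    def test_scd50_identity(self):
        pts = points_from_probs(DOSES_11, -5.55, 0.5, n=200)
        fit = fit_scp_curve(pts)
        assert fit.scd50_gy == -fit.a / fit.b

    def test_mle_beats_grid_oracle(self, rng):
        # 200 x 200 likelihood grid around the optimum for 20 random datasets
        for _ in range(20):
            a_true = -rng.uniform(2, 7)
            b_true = rng.uniform(0.2, 0.8)
            doses = np.linspace(0, 25, 8)
            n = 30
            pts = [
                DoseResponsePoint(
                    dose_gy=d,
                    controlled=int(rng.binomial(n, expit(a_true + b_true * d))),
                    total=n,
                )
                for d in doses
            ]
            tot = sum(p.controlled for p in pts)
            if tot == 0 or tot == n * len(pts):
                continue
            fit = fit_scp_curve(pts)
            aa = np.linspace(fit.a - 1.0, fit.a + 1.0, 200)
            bb = np.linspace(fit.b - 0.1, fit.b + 0.1, 200)
            grid_max = max(_loglik_oracle(a, b, pts) for a in aa for b in bb)
            assert _loglik_oracle(fit.a, fit.b, pts) >= grid_max - 1e-6

    def test_dose_unit_reparameterization(self):
        pts = points_from_probs(DOSES_11, -5.55, 0.5, n=500)
        pts_cgy = [
            DoseResponsePoint(dose_gy=p.dose_gy * 100, controlled=p.controlled, total=p.total)
            for p in pts
        ]
        fit_gy = fit_scp_curve(pts)
        fit_cgy = fit_scp_curve(pts_cgy)
        assert fit_cgy.b == pytest.approx(fit_gy.b / 100, rel=1e-6)
        assert fit_cgy.scd50_gy == pytest.approx(fit_gy.scd50_gy * 100, rel=1e-6)

    def test_fitted_curve_monotone_when_b_positive(self):
        fit = fit_scp_curve(points_from_probs(DOSES_11, -5.55, 0.5, n=100))
        grid = np.linspace(0, 25, 100)
        assert np.all(np.diff(fit.predict(grid)) > 0)

    def test_complete_separation_falls_back_to_firth(self):
        pts = [
            DoseResponsePoint(dose_gy=d, controlled=0 if d < 12 else 20, total=20)
            for d in DOSES_11
        ]
        fit = fit_scp_curve(pts)
        assert fit.method == "firth"
        assert fit.converged
        assert np.isfinite(fit.a) and np.isfinite(fit.b)
        assert 7.5 < fit.scd50_gy < 15.0

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        pts = points_from_probs(DOSES_11, -4.0, 0.4, n=60)
        fit = fit_scp_curve(pts)
        endog = np.array([[p.controlled, p.total - p.controlled] for p in pts], float)
        exog = sm.add_constant(np.array([p.dose_gy for p in pts]))
        glm = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        assert fit.a == pytest.approx(glm.params[0], abs=1e-6)
        assert fit.b == pytest.approx(glm.params[1], abs=1e-6)

    def test_single_dose_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_scp_curve([DoseResponsePoint(5.0, 3, 10)])

    def test_all_relapsed_rejected(self):
        pts = [DoseResponsePoint(d, 0, 10) for d in (0.0, 10.0, 20.0)]
        with pytest.raises(DegenerateDataError):
            fit_scp_curve(pts)

    def test_least_squares_mode_close_to_mle(self):
        pts = points_from_probs(DOSES_11, -5.55, 0.5, n=500)
        mle = fit_scp_curve(pts, method="mle")
        lsq = fit_scp_curve(pts, method="lsq")
        assert lsq.method == "lsq"
        assert lsq.scd50_gy == pytest.approx(mle.scd50_gy, abs=0.3)


def sim_flags(scd50, n=56, seed=0, b=0.5):
    resp = ResponseParams(a_true=-scd50 * b, b_true=b, ht_dose_shift={})
    design = ExperimentDesign(n_per_arm=n)
    return simulate_control_outcomes(design, resp, seed=seed)


class TestBootstrap:
    def test_n_boot_zero_is_point_estimate_only(self):
        fit = bootstrap_scd50(sim_flags(11.1), n_boot=0)
        assert fit.ci95_gy is None and fit.bootstrap_scd50 is None

    def test_seed_determinism(self):
        f1 = bootstrap_scd50(sim_flags(11.1), n_boot=300, seed=42)
        f2 = bootstrap_scd50(sim_flags(11.1), n_boot=300, seed=42)
        assert f1.ci95_gy == f2.ci95_gy
        np.testing.assert_array_equal(f1.bootstrap_scd50, f2.bootstrap_scd50)

    def test_ci_contains_point_estimate(self):
        fit = bootstrap_scd50(sim_flags(11.1), n_boot=400, seed=3)
        lo, hi = fit.ci95_gy
        assert lo <= fit.scd50_gy <= hi

    def test_replicate_scd50_identity(self):
        fit = bootstrap_scd50(sim_flags(8.0), n_boot=200, seed=1)
        assert np.all(np.isfinite(fit.bootstrap_scd50))
        assert fit.n_failed + fit.bootstrap_scd50.size == fit.n_boot


class TestTER:
    @pytest.mark.parametrize(
        "scd50_rt,scd50_ht,expected",
        [
            (11.1, 8.7, 1.3),
            (11.1, 7.3, 1.5),
            (11.1, 7.5, 1.5),
            (16.5, 12.4, 1.3),
            (16.5, 10.2, 1.6),
            (16.5, 8.0, 2.1),
        ],
    )
    def test_enhancement_ratio_worked_examples(self, scd50_rt, scd50_ht, expected):
        rt = SCPCurveFit(a=-scd50_rt * 0.5, b=0.5, converged=True)
        ht = SCPCurveFit(a=-scd50_ht * 0.5, b=0.5, converged=True)
        assert round(compute_ter(rt, ht).ter, 1) == expected

    def test_identical_fits_give_unity_with_ci_containing_one(self):
        fit = bootstrap_scd50(sim_flags(11.1), n_boot=400, seed=9)
        res = compute_ter(fit, fit)
        assert res.ter == 1.0
        assert res.ci95[0] <= 1.0 <= res.ci95[1]

    def test_radiosensitized_condition_gives_ter_above_one(self):
        rt = bootstrap_scd50(sim_flags(11.1, seed=1), n_boot=400, seed=5)
        ht = bootstrap_scd50(sim_flags(7.0, seed=2), n_boot=400, seed=6)
        res = compute_ter(rt, ht)
        assert res.ter > 1.3
        assert res.ci95[0] > 1.0
        assert res.p_boot < 0.01

    def test_unconverged_fit_rejected(self):
        good = SCPCurveFit(a=-5.0, b=0.5, converged=True)
        bad = SCPCurveFit(a=-5.0, b=0.5, converged=False)
        with pytest.raises(FitError):
            compute_ter(good, bad)

    def test_negative_scd50_rejected(self):
        good = SCPCurveFit(a=-5.0, b=0.5, converged=True)
        bad = SCPCurveFit(a=5.0, b=0.5, converged=True)  # scd50 < 0
        with pytest.raises(FitError):
            compute_ter(good, bad)


class TestCompareScd50:
    def test_same_replicates_give_p_one(self):
        fit = bootstrap_scd50(sim_flags(11.1), n_boot=300, seed=2)
        assert compare_scd50(fit, fit) == 1.0

    def test_symmetric_under_swap(self):
        f1 = bootstrap_scd50(sim_flags(11.1, seed=1), n_boot=300, seed=3)
        f2 = bootstrap_scd50(sim_flags(9.5, seed=2), n_boot=300, seed=4)
        assert compare_scd50(f1, f2) == compare_scd50(f2, f1)

    def test_missing_bootstrap_directs_user(self):
        f1 = bootstrap_scd50(sim_flags(11.1), n_boot=200, seed=1)
        f2 = fit_scp_curve(dose_response_points(sim_flags(9.5)))
        with pytest.raises(FitError, match="bootstrap"):
            compare_scd50(f1, f2)

    def test_left_shift_lowers_fitted_scd50(self):
        # adding a positive intercept shift (radiosensitization) must lower
        # the fitted SCD50
        shifted = ResponseParams(
            ht_dose_shift={(42.5, 30.0): 1.5}
        )
        design = ExperimentDesign(n_per_arm=500)
        rt = fit_scp_curve(
            dose_response_points(
                simulate_control_outcomes(design, shifted, (37.0, 0.0), seed=8)
            )
        )
        ht = fit_scp_curve(
            dose_response_points(
                simulate_control_outcomes(design, shifted, (42.5, 30.0), seed=9)
            )
        )
        assert ht.scd50_gy < rt.scd50_gy
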