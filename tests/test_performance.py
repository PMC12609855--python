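import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar
from scipy.special import expit

from lipidval import models, performance
from lipidval.exceptions import (DegenerateInputError, EstimationError,
                                 ParameterError)
from tests.conftest import make_labelled_cohort


def brute_force_concordance(y, p):
    """Pairwise Mann-Whitney oracle (ties count one half)."""
    pos = p[y == 1]
    neg = p[y == 0]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation_is_one(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.8, 0.6, 0.4, 0.2])
        assert performance.auroc(y, p).value == 1.0

    def test_pure_ties_is_half(self):
        y = np.array([1, 0, 1, 0])
        p = np.full(4, 0.3)
        assert performance.auroc(y, p).value == 0.5

    def test_four_pair_worked_example(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.6, 0.3, 0.5, 0.2])
        # 3 of 4 case-control pairs concordant
        assert performance.auroc(y, p).value == pytest.approx(0.75)

    @given(st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_equals_brute_force_concordance(self, data):
        n = data.draw(st.integers(4, 50))
        y = np.array(data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
        ))
        if y.min() == y.max():
            y[0], y[-1] = 0, 1
        p = np.array(data.draw(st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=n, max_size=n
        )))
        est = performance.auroc(y, p)
        assert est.value == pytest.approx(brute_force_concordance(y, p),
                                          abs=1e-12)

    def test_matches_sklearn_on_simulated_data(self, calibrated_cohort_20k):
        from sklearn.metrics import roc_auc_score
        sub = calibrated_cohort_20k.iloc[:3000]
        y = sub["y_nonhdl"].to_numpy()
        p = models.predicted_probability(models.NONHDL_MODEL, sub)
        assert performance.auroc(y, p).value == pytest.approx(
            roc_auc_score(y, p), abs=1e-12
        )

    def test_invariant_under_monotone_transform(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        p = rng.random(200)
        a = performance.auroc(y, p).value
        b = performance.auroc(y, np.sqrt(p) ** 3 + 2).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            performance.auroc(np.ones(5, dtype=int), np.linspace(0, 1, 5))

    def test_delong_interval_covers_truth_on_calibrated_sim(self, calibrated_cohort_20k):
        y = calibrated_cohort_20k["y_nonhdl"].to_numpy()
        p = models.predicted_probability(models.NONHDL_MODEL,
                                         calibrated_cohort_20k)
        est = performance.auroc(y, p)
        assert est.ci_low < est.value < est.ci_high
        assert 0 < est.se < 0.02


class TestCitl:
    def test_symmetric_solution_is_zero(self):
        est = performance.citl(np.array([1, 0]), np.zeros(2))
        assert est.value == pytest.approx(0.0, abs=1e-8)

    def test_closed_form_three_quarters(self):
        # expit(a) = 3/4  =>  a = ln 3
        est = performance.citl(np.array([1, 1, 1, 0]), np.zeros(4))
        assert est.value == pytest.approx(np.log(3), abs=1e-6)

    def test_recovers_planted_intercept_drift(self):
        df = make_labelled_cohort(50_000, drift_intercept=-0.5, seed=51)
        lp = models.linear_predictor(models.NONHDL_MODEL, df)
        est = performance.citl(df["y_nonhdl"].to_numpy(), lp)
        assert est.value == pytest.approx(-0.5, abs=0.05)


class TestCalibrationSlope:
    def test_self_consistency_at_unit_slope(self, calibrated_cohort_20k):
        lp = models.linear_predictor(models.NONHDL_MODEL, calibrated_cohort_20k)
        est = performance.calibration_slope(
            calibrated_cohort_20k["y_nonhdl"].to_numpy(), lp
        )
        assert est.value == pytest.approx(1.0, abs=0.06)

    def test_recovers_planted_slope_within_ci(self, drifted_cohort_20k):
        lp = models.linear_predictor(models.NONHDL_MODEL, drifted_cohort_20k)
        est = performance.calibration_slope(
            drifted_cohort_20k["y_nonhdl"].to_numpy(), lp
        )
        assert est.covers(0.71)

    def test_matches_grid_search_mle_oracle(self):
        # overlapping classes so the MLE is finite and interior
        lp = np.array([-2.0, -1.0, 0.0, 0.0, 1.0, 2.0])
        y = np.array([0, 1, 0, 1, 0, 1])

        def neg_profile_loglik(b):
            # profile out the intercept by inner 1-d optimisation
            def nll_a(a):
                p = np.clip(expit(a + b * lp), 1e-12, 1 - 1e-12)
                return -np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
            inner = minimize_scalar(nll_a, bounds=(-10, 10), method="bounded")
            return inner.fun

        outer = minimize_scalar(neg_profile_loglik, bounds=(0.01, 10),
                                method="bounded",
                                options={"xatol": 1e-10})
        est = performance.calibration_slope(y, lp)
        assert est.value == pytest.approx(outer.x, abs=1e-3)

    def test_constant_lp_unidentifiable(self):
        with pytest.raises(DegenerateInputError):
            performance.calibration_slope(np.array([0, 1, 0, 1]), np.ones(4))

    def test_perfect_separation_is_estimation_error(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        lp = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        with pytest.raises(EstimationError):
            performance.calibration_slope(y, lp)

    def test_same_data_recalibration_identities(self, drifted_cohort_20k):
        # refitting LP on the same data must zero out miscalibration exactly
        y = drifted_cohort_20k["y_nonhdl"].to_numpy()
        lp = models.linear_predictor(models.NONHDL_MODEL, drifted_cohort_20k)
        a, b = performance.recalibration_fit(y, lp)
        lp2 = a + b * lp
        assert performance.calibration_slope(y, lp2).value == pytest.approx(
            1.0, abs=1e-6
        )
        assert performance.citl(y, lp2).value == pytest.approx(0.0, abs=1e-6)


class TestEoRatio:
    def test_worked_example(self):
        est = performance.eo_ratio(np.array([0, 0, 1, 1]),
                                   np.array([0.1, 0.3, 0.6, 0.8]))
        assert est.value == pytest.approx(0.9)

    def test_perfect_predictions_give_unity(self):
        y = np.array([0, 1, 0, 1])
        assert performance.eo_ratio(y, y.astype(float)).value == 1.0

    def test_calibrated_simulation_near_unity(self, calibrated_cohort_20k):
        p = models.predicted_probability(models.NONHDL_MODEL,
                                         calibrated_cohort_20k)
        est = performance.eo_ratio(
            calibrated_cohort_20k["y_nonhdl"].to_numpy(), p
        )
        assert est.value == pytest.approx(1.0, abs=0.05)

    def test_zero_events_rejected(self):
        with pytest.raises(DegenerateInputError):
            performance.eo_ratio(np.zeros(4, dtype=int), np.full(4, 0.2))


class TestCalibrationCurve:
    def test_calibrated_bins_hug_diagonal(self, calibrated_cohort_20k):
        p = models.predicted_probability(models.NONHDL_MODEL,
                                         calibrated_cohort_20k)
        curve = performance.calibration_curve(
            calibrated_cohort_20k["y_nonhdl"].to_numpy(), p, bins=10
        )
        pts = curve.points
        inside = ((pts["ci_low"] <= pts["predicted"])
                  & (pts["predicted"] <= pts["ci_high"]))
        assert inside.sum() >= 8

    def test_constant_risk_collapses_to_single_point(self, rng):
        y = (rng.random(400) < 0.3).astype(int)
        curve = performance.calibration_curve(y, np.full(400, 0.3), bins=10)
        assert len(curve.points) == 1
        assert curve.points.iloc[0]["predicted"] == pytest.approx(0.3)
        assert curve.points.iloc[0]["observed"] == pytest.approx(y.mean())

    def test_overestimation_sign_pattern_when_slope_below_one(self):
        # slope drift pivoted at the mean LP: the overfitting-style
        # miscalibration that leaves overall event rates roughly right but
        # makes extreme predictions too extreme
        from lipidval import cohort as cohort_mod
        base = cohort_mod.generate_cohort(cohort_mod.CohortSpec(n=20_000,
                                                                seed=61))
        lp = models.linear_predictor(models.NONHDL_MODEL, base)
        sim = cohort_mod.OutcomeSimSpec(
            true_model=models.NONHDL_MODEL, drift_slope=0.64,
            drift_intercept=(1 - 0.64) * float(np.mean(lp)), seed=62,
        )
        df = cohort_mod.simulate_outcomes(base, sim)
        p = models.predicted_probability(models.NONHDL_MODEL, df)
        curve = performance.calibration_curve(df["y_nonhdl"].to_numpy(), p,
                                              bins=10)
        pts = curve.points
        # slope < 1: observed above predicted at low risk, below at high risk
        assert pts.iloc[0]["observed"] > pts.iloc[0]["predicted"]
        assert pts.iloc[-1]["observed"] < pts.iloc[-1]["predicted"]

    def test_loess_mode_returns_monotone_grid(self, calibrated_cohort_20k):
        sub = calibrated_cohort_20k.iloc[:2000]
        p = models.predicted_probability(models.NONHDL_MODEL, sub)
        curve = performance.calibration_curve(sub["y_nonhdl"].to_numpy(), p,
                                              smoother="loess")
        assert curve.smoother == "loess"
        assert curve.points["predicted"].is_monotonic_increasing

    def test_too_few_records_rejected(self):
        with pytest.raises(ParameterError):
            performance.calibration_curve(np.array([0, 1] * 10),
                                          np.linspace(0.1, 0.9, 20), bins=10)


class TestValidateReport:
    def test_report_assembles_consistently(self, calibrated_cohort_20k):
        rep = performance.validate(calibrated_cohort_20k, models.NONHDL_MODEL)
        assert rep.n == len(calibrated_cohort_20k)
        assert rep.events == calibrated_cohort_20k["y_nonhdl"].sum()
        assert rep.prevalence == pytest.approx(rep.events / rep.n)
        assert rep.discrimination_label == performance.discrimination_label(
            rep.auroc.value
        )

    @pytest.mark.parametrize(
        "auc, label",
        [(0.5, "no discrimination"), (0.65, "poor"), (0.75, "acceptable"),
         (0.85, "excellent"), (0.95, "outstanding")],
    )
    def test_hosmer_lemeshow_labels(self, auc, label):
        assert performance.discrimination_label(auc) == label
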