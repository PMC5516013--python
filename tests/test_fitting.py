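"""Estimators: AIC machinery, recovery on noiseless data, CI behaviour."""

import math

import numpy as np
import pytest

from doxopkpd.errors import ValidationError
from doxopkpd.fitting import (
    CompartmentModelEstimator,
    DoseData,
    LogisticGrowthEstimator,
    PKCondition,
    ResponseSurfaceEstimator,
    akaike_weights,
    compute_aic,
    fit_growth,
    fit_pk_parameters,
    fit_response_models,
    regularized_objective,
)
from doxopkpd.growth import GrowthParameters, ResponseParamsA, ResponseParamsB, solve_population
from doxopkpd.pk import PKParameters, compute_dose_summary, make_pulse_input, simulate_pk_forced

GROWTH = GrowthParameters(k_p=2.69e-2, theta=3.81e4)
PK_TRUE = PKParameters(k_EF=2e-3, k_FE=0.4, k_FB=0.1, v_I=0.02, v_E=250.0)


class TestInformationCriteria:
    def test_aic_formula(self):
        assert compute_aic(10, 2.5, 3) == pytest.approx(10 * math.log(0.25) + 6)

    def test_aic_rejects_degenerate_inputs(self):
        for n, rss, p in [(0, 1.0, 1), (10, -1.0, 1), (10, 0.0, 1), (10, 1.0, -1)]:
            with pytest.raises(ValidationError):
                compute_aic(n, rss, p)

    def test_equal_aics_give_equal_weights(self):
        w = akaike_weights([12.3, 12.3])
        assert np.allclose(w, [0.5, 0.5])

    def test_delta_two_weight(self):
        # exp(-1) / (1 + exp(-1)) = 0.26894...
        w = akaike_weights([0.0, 2.0])
        assert w[0] == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), rel=1e-12)
        assert w[1] == pytest.approx(math.exp(-1.0) / (1.0 + math.exp(-1.0)), rel=1e-12)

    def test_weights_sum_to_one_and_order(self):
        w = akaike_weights([5.0, 1.0, 3.0])
        assert w.sum() == pytest.approx(1.0)
        assert w[1] > w[2] > w[0]

    def test_perfect_fit_dominates(self):
        w = akaike_weights([-np.inf, 10.0])
        assert w[0] == 1.0 and w[1] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            akaike_weights([])


class TestRegularizedObjective:
    def test_alpha_zero_is_plain_sse(self):
        res = [np.array([0.1, -0.2]), np.array([0.3])]
        P = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert regularized_objective(P, res, 0.0) == pytest.approx(0.01 + 0.04 + 0.09)

    def test_penalty_grows_with_roughness(self):
        res = [np.zeros(2), np.zeros(2), np.zeros(2)]
        smooth = np.array([[1.0], [1.0], [1.0]])
        rough = np.array([[1.0], [5.0], [1.0]])
        a = regularized_objective(smooth, res, 1.0)
        b = regularized_objective(rough, res, 1.0)
        assert a == 0.0 and b > 0.0

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValidationError):
            regularized_objective(np.ones((2, 1)), [np.zeros(1)], -0.5)


def make_pk_conditions():
    times = np.arange(0.25, 24.01, 0.25)
    conds = []
    for conc in (312.5, 1250.0):
        for exposure in (6.0, 12.0):
            fn = make_pulse_input(conc, exposure, 24.0)
            tc = simulate_pk_forced(PK_TRUE, fn, times)
            conds.append(PKCondition(fn, times, tc.intracellular_total))
    return conds


class TestCompartmentModelEstimator:
    def test_noiseless_recovery_is_exact(self):
        est = fit_pk_parameters(make_pk_conditions())
        assert est.k_EF_ == pytest.approx(PK_TRUE.k_EF, rel=1e-6)
        assert est.k_FE_ == pytest.approx(PK_TRUE.k_FE, rel=1e-6)
        assert est.k_FB_ == pytest.approx(PK_TRUE.k_FB, rel=1e-6)
        assert est.mean_percent_error_ < 1e-4
        assert est.converged_

    def test_sklearn_protocol(self):
        est = CompartmentModelEstimator(n_starts=2)
        params = est.get_params()
        assert params["n_starts"] == 2
        est.set_params(n_starts=4)
        assert est.n_starts == 4
        assert not hasattr(est, "params_")

    def test_predict_matches_truth_after_fit(self):
        est = fit_pk_parameters(make_pk_conditions())
        fn = make_pulse_input(625.0, 6.0, 24.0)
        times = np.linspace(1, 24, 24)
        pred = est.predict(fn, times)
        truth = simulate_pk_forced(PK_TRUE, fn, times)
        assert np.allclose(pred.intracellular_total, truth.intracellular_total, rtol=1e-5)

    def test_empty_conditions_rejected(self):
        with pytest.raises(ValidationError):
            CompartmentModelEstimator().fit([])

    def test_all_zero_data_rejected(self):
        times = np.arange(0.25, 6.0, 0.25)
        fn = make_pulse_input(100.0, 6.0, 24.0)
        with pytest.raises(ValidationError):
            CompartmentModelEstimator().fit([PKCondition(fn, times, np.zeros(times.size))])


class TestLogisticGrowthEstimator:
    def make_control(self):
        times = np.arange(-72.0, 30 * 24.0 + 1, 24.0)
        counts = solve_population(2500.0, GROWTH, None, None, times).counts
        return times, counts

    def test_noiseless_recovery(self):
        times, counts = self.make_control()
        est = fit_growth(times, counts)
        assert est.k_p_ == pytest.approx(GROWTH.k_p, rel=1e-6)
        assert est.theta_ == pytest.approx(GROWTH.theta, rel=1e-6)
        assert est.N0_ == pytest.approx(2500.0, rel=1e-5)
        assert est.theta_identifiable_

    def test_theta_flagged_unidentifiable_far_from_plateau(self):
        # purely exponential data: no plateau information at all
        times = np.arange(0.0, 5 * 24.0 + 1, 24.0)
        counts = 500.0 * np.exp(GROWTH.k_p * times)
        est = fit_growth(times, counts)
        assert not est.theta_identifiable_

    def test_ci_brackets_truth_under_noise(self):
        times, counts = self.make_control()
        hits_kp = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            sigma = math.sqrt(math.log(1 + 0.05**2))
            noisy = counts * np.exp(rng.normal(0, sigma, counts.shape) - sigma**2 / 2)
            est = fit_growth(times, noisy)
            lo, hi = est.conf_int_["k_p"]
            hits_kp += int(lo <= GROWTH.k_p <= hi)
        assert hits_kp >= 8

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            fit_growth([0.0, 24.0], [100.0, 120.0])


def make_dose_data(variant, concs=(78.0, 312.0, 1250.0), flat_theta=True):
    """Noiseless per-dose counts from truth inside the fitted model class."""
    times = np.arange(24.0, 30 * 24.0 + 1, 24.0)
    data, truth = [], []
    for conc in concs:
        dose = compute_dose_summary(PK_TRUE, make_pulse_input(conc, 12.0, 36.0))
        cb = dose.C_Bmax
        kd = 0.045 * cb**2 / (cb**2 + (2e4) ** 2)
        theta = GROWTH.theta
        if variant == "A":
            p = ResponseParamsA(k_dA=kd, theta=theta)
        else:
            r = 2e-3 + 2.8e-2 * cb / (cb + 1e4)
            kdb = 0.05 * cb**2 / (cb**2 + (5e3) ** 2)
            p = ResponseParamsB(k_dB=kdb, r=r, theta=theta)
        counts = solve_population(8000.0, GROWTH, variant, p, times, t0=times[0]).counts
        data.append(DoseData(dose=dose, times=times, counts=counts))
        truth.append(p)
    return data, truth


class TestResponseSurfaceEstimator:
    @pytest.mark.parametrize("variant", ["A", "B"])
    def test_noiseless_recovery_unregularized(self, variant):
        data, truth = make_dose_data(variant)
        est = ResponseSurfaceEstimator(variant=variant, alpha=0.0).fit(data, GROWTH)
        for p_hat, p_true in zip(est.params_, truth):
            if variant == "A":
                assert p_hat.k_dA == pytest.approx(p_true.k_dA, rel=1e-4, abs=1e-8)
            else:
                assert p_hat.k_dB == pytest.approx(p_true.k_dB, rel=1e-4, abs=1e-8)
                assert p_hat.r == pytest.approx(p_true.r, rel=1e-3)

    def test_regularization_reduces_roughness(self):
        rng = np.random.default_rng(5)
        data, _ = make_dose_data("A", concs=(39.0, 78.0, 156.0, 312.0, 625.0))
        noisy = []
        for d in data:
            sigma = math.sqrt(math.log(1 + 0.08**2))
            factors = np.exp(rng.normal(0, sigma, d.counts.shape) - sigma**2 / 2)
            noisy.append(DoseData(dose=d.dose, times=d.times, counts=d.counts * factors))
        rough0 = ResponseSurfaceEstimator(variant="A", alpha=0.0).fit(noisy, GROWTH).roughness_
        rough1 = ResponseSurfaceEstimator(variant="A", alpha=5.0).fit(noisy, GROWTH).roughness_
        assert rough1 <= rough0 + 1e-12

    def test_theta_fixed_in_regressing_populations(self):
        times = np.arange(24.0, 30 * 24.0 + 1, 24.0)
        dose = compute_dose_summary(PK_TRUE, make_pulse_input(2500.0, 12.0, 36.0))
        p = ResponseParamsA(k_dA=GROWTH.k_p + 0.02, theta=GROWTH.theta)
        counts = solve_population(8000.0, GROWTH, "A", p, times, t0=times[0]).counts
        est = ResponseSurfaceEstimator(variant="A", alpha=0.0).fit(
            [DoseData(dose=dose, times=times, counts=counts)], GROWTH
        )
        assert est.fits_[0].extras["theta_fixed"]
        assert est.params_[0].theta == GROWTH.theta
        assert est.params_[0].k_dA == pytest.approx(p.k_dA, rel=1e-5)

    def test_invalid_variant_and_alpha_rejected(self):
        data, _ = make_dose_data("A")
        with pytest.raises(ValidationError):
            ResponseSurfaceEstimator(variant="C").fit(data, GROWTH)
        with pytest.raises(ValidationError):
            ResponseSurfaceEstimator(variant="A", alpha=-1.0).fit(data, GROWTH)


class TestFitResponseModels:
    def test_weights_favor_generating_variant(self):
        # data generated from variant B at a visible dose: w_B should win
        data, _ = make_dose_data("B", concs=(312.0, 625.0, 1250.0))
        coll = fit_response_models(data, GROWTH, exposure=12.0, alpha=0.0)
        assert coll.exposure == 12.0
        for fit in coll.fits:
            assert fit.weights.w_B > 0.9

    def test_collection_structure(self, training_12h):
        assert len(training_12h.fits) == 10  # control + 9 doses
        for fit in training_12h.fits:
            assert fit.weights.w_A + fit.weights.w_B == pytest.approx(1.0)
            assert fit.fit_A.n == fit.fit_B.n
            assert fit.N0 > 0
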