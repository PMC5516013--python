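"""Parameter interpolation, weight model and trajectory prediction."""

import numpy as np
import pytest

from doxopkpd.errors import ValidationError
from doxopkpd.predict import (
    LocalLinearSurface,
    ResponseParameterSurfaces,
    TrajectoryPredictor,
    WeightModel,
    bootstrap_band,
    fit_weight_model,
    mean_percent_error,
    predict_response,
    predict_weight,
)
from doxopkpd.pk import DoseSummary
from doxopkpd.workflow import dose_data_for_exposure


class TestMeanPercentError:
    def test_exact_match_is_zero(self):
        assert mean_percent_error([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_known_value(self):
        # |10-9|/10 = 10%, |20-22|/20 = 10%
        assert mean_percent_error([10.0, 20.0], [9.0, 22.0]) == pytest.approx(10.0)


class TestLocalLinearSurface:
    def test_recovers_linear_function_exactly(self, rng):
        X = rng.uniform(-1, 1, size=(30, 2))
        y = 2.0 + 3.0 * X[:, 0] - 1.5 * X[:, 1]
        s = LocalLinearSurface(span=0.5).fit(X, y)
        Xq = rng.uniform(-0.8, 0.8, size=(10, 2))
        yq = 2.0 + 3.0 * Xq[:, 0] - 1.5 * Xq[:, 1]
        assert np.allclose(s.predict(Xq), yq, rtol=1e-8, atol=1e-8)

    def test_interpolates_training_points_of_smooth_curve(self, rng):
        x = np.linspace(0, 1, 25)[:, None]
        y = np.sin(3 * x[:, 0])
        s = LocalLinearSurface(span=0.3).fit(x, y)
        pred = s.predict(x)
        assert np.max(np.abs(pred - y)) < 0.02

    def test_extrapolation_flag(self):
        X = np.linspace(0, 1, 10)[:, None]
        s = LocalLinearSurface(span=0.5).fit(X, X[:, 0])
        flags = s.is_extrapolated(np.array([[0.5], [1.5], [-0.2]]))
        assert list(flags) == [False, True, True]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            LocalLinearSurface().fit(np.zeros((2, 1)), np.zeros(2))

    def test_bad_span_rejected(self):
        with pytest.raises(ValidationError):
            LocalLinearSurface(span=0.0).fit(np.zeros((5, 1)), np.zeros(5))


class TestWeightModel:
    def make_data(self, rng, n=30):
        X = rng.uniform(-2, 2, size=(n, 2))
        eta = 1.5 * X[:, 0] - 0.5
        w = 1.0 / (1.0 + np.exp(-eta))
        return X, w

    def test_recovers_monotone_trend(self, rng):
        X, w = self.make_data(rng)
        m = WeightModel().fit(X, w)
        lo = m.predict([[-2.0, 0.0]])[0]
        hi = m.predict([[2.0, 0.0]])[0]
        assert lo < 0.3 and hi > 0.7

    def test_predictions_in_unit_interval(self, rng):
        X, w = self.make_data(rng)
        m = WeightModel().fit(X, w)
        p = m.predict(rng.uniform(-5, 5, size=(50, 2)))
        assert np.all((p > 0) & (p < 1))

    def test_separable_data_falls_back_to_ridge(self):
        # hard 0/1 labels perfectly separated by the first feature
        X = np.column_stack([np.r_[-np.ones(5), np.ones(5)], np.zeros(10)])
        w = np.r_[np.zeros(5), np.ones(5)]
        m = WeightModel().fit(X, w)
        assert m.used_ridge_fallback_
        assert m.predict([[-1.0, 0.0]])[0] < 0.5 < m.predict([[1.0, 0.0]])[0]

    def test_invalid_weights_rejected(self, rng):
        X, w = self.make_data(rng)
        with pytest.raises(ValidationError):
            WeightModel().fit(X, w + 2.0)


@pytest.fixture(scope="module")
def predictor(training_12h, pk_params_true):
    return TrajectoryPredictor().fit(training_12h, pk_params_true)


@pytest.fixture(scope="module")
def band_inputs(response_dataset_noisy, pk_params_true, growth_noisy):
    df, rec = response_dataset_noisy
    sub = df[df.concentration_nM.isin([0.0, 20.0, 78.0, 312.0, 1250.0])]
    data = dose_data_for_exposure(sub, 12.0, pk_params_true)
    reps = []
    for dd in data:
        mask = (
            (sub.exposure_hr == 12.0)
            & (sub.concentration_nM == dd.dose.concentration)
            & (sub.time_hr >= dd.times[0])
        )
        piv = sub[mask].pivot_table(index="replicate", columns="time_hr", values="count")
        reps.append(piv.to_numpy())
    return data, reps, growth_noisy.growth_


class TestTrajectoryPredictor:
    def test_fitted_attributes(self, predictor):
        assert predictor.surfaces_ is not None
        assert predictor.weight_model_ is not None

    def test_prediction_starts_at_first_count(self, predictor):
        times = np.arange(24.0, 720.0, 24.0)
        res = predictor.predict(156.0, 6.0, 9000.0, 24.0, times)
        assert res.trajectory.counts[0] == pytest.approx(9000.0, rel=1e-9)

    def test_weights_shift_with_dose(self, predictor):
        times = np.arange(24.0, 720.0, 24.0)
        low = predictor.predict(20.0, 6.0, 9000.0, 24.0, times)
        high = predictor.predict(2500.0, 24.0, 9000.0, 24.0, times)
        # synthetic truth: delayed-kill dominates at low dose, immediate at high
        assert low.weights.w_B > high.weights.w_B

    def test_interior_condition_not_flagged_extrapolated(self, predictor):
        times = np.arange(24.0, 720.0, 24.0)
        res = predictor.predict(156.0, 12.0, 9000.0, 24.0, times)
        assert not res.extrapolated

    def test_score_attaches_errors(self, predictor):
        times = np.arange(24.0, 720.0, 24.0)
        res = predictor.predict(156.0, 6.0, 9000.0, 24.0, times)
        res.score(res.trajectory.counts * 1.1)
        assert res.mean_percent_error == pytest.approx(100 * (1 - 1 / 1.1), rel=1e-6)
        assert res.eoe_percent_error is not None

    def test_nonpositive_initial_count_rejected(self, predictor):
        with pytest.raises(ValidationError):
            predictor.predict(156.0, 6.0, 0.0, 24.0, np.arange(24.0, 240.0, 24.0))

    def test_surfaces_require_enough_doses(self, training_12h, pk_params_true):
        from dataclasses import replace

        thin = replace(training_12h, fits=training_12h.fits[:3])
        with pytest.raises(ValidationError):
            TrajectoryPredictor().fit(thin, pk_params_true)


class TestCrossExposurePrediction:
    def test_sublethal_prediction_within_tolerance(
        self, training_12h, pk_params_true, response_dataset_noisy
    ):
        """Train on 12 h exposure, predict 6 h; compare to the noiseless truth."""
        df, rec = response_dataset_noisy
        times_all = np.asarray(rec["times_hr"])
        post = times_all[times_all >= 24.0]
        predictor = TrajectoryPredictor().fit(training_12h, pk_params_true)
        test_data = dose_data_for_exposure(df, 6.0, pk_params_true, include_control=False)
        errs = []
        for dd in test_data:
            conc = dd.dose.concentration
            cond = rec["conditions"][f"c{conc:g}_e6"]
            if cond["k_dA"] >= rec["growth"]["k_p"]:
                continue  # supra-lethal doses are known to degrade
            truth = np.asarray(cond["noiseless_counts"])[times_all >= 24.0]
            res = predictor.predict(conc, 6.0, dd.counts[1], dd.times[1], post)
            errs.append(mean_percent_error(truth, res.trajectory.counts))
        assert len(errs) >= 4
        assert max(errs) < 20.0

    def test_predict_response_wrapper_equivalent(self, training_12h, pk_params_true):
        times = np.arange(24.0, 720.0, 24.0)
        a = predict_response(training_12h, pk_params_true, 156.0, 6.0, 9000.0, 24.0, times)
        b = TrajectoryPredictor().fit(training_12h, pk_params_true).predict(
            156.0, 6.0, 9000.0, 24.0, times
        )
        assert np.allclose(a.trajectory.counts, b.trajectory.counts)


class TestBootstrapBand:
    def test_band_contains_point_and_is_reproducible(
        self, band_inputs, pk_params_true
    ):
        data, reps, growth = band_inputs
        times = np.arange(24.0, 480.0, 48.0)
        lo1, hi1, point = bootstrap_band(
            data, reps, growth, pk_params_true, (156.0, 6.0),
            9000.0, 24.0, times, B=8, seed=3,
        )
        assert np.all(lo1 <= point.trajectory.counts + 1e-9)
        assert np.all(hi1 >= point.trajectory.counts - 1e-9)
        lo2, hi2, _ = bootstrap_band(
            data, reps, growth, pk_params_true, (156.0, 6.0),
            9000.0, 24.0, times, B=8, seed=3,
        )
        assert np.array_equal(lo1, lo2) and np.array_equal(hi1, hi2)

    def test_small_b_rejected(self, band_inputs, pk_params_true):
        data, reps, growth = band_inputs
        with pytest.raises(ValidationError):
            bootstrap_band(
                data, reps, growth, pk_params_true, (156.0, 6.0),
                9000.0, 24.0, np.arange(24.0, 240.0, 24.0), B=1,
            )


class TestSurfacesFromTraining:
    def test_interpolation_matches_training_scale(self, training_12h):
        surfaces = ResponseParameterSurfaces.from_training(training_12h)
        mid = training_12h.fits[5].dose
        pA, pB, extrapolated = surfaces.interpolate(mid)
        assert not extrapolated
        ks = [f.params_A.k_dA for f in training_12h.fits if f.dose.C_Bmax > 0]
        assert 0.0 <= pA.k_dA <= 2.0 * max(ks)
        assert pB.r > 0 and pB.theta > 0

    def test_weight_prediction_in_unit_interval(self, training_12h):
        m = fit_weight_model(training_12h)
        f = training_12h.fits[4]
        w = predict_weight(m, f.dose, f.params_A, f.params_B)
        assert 0.0 < w.w_B < 1.0
        assert w.w_A + w.w_B == pytest.approx(1.0)
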