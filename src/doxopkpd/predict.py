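"""Prediction of treatment response at unseen concentration/exposure pairs.

The fitted response parameters of a training exposure-time experiment are
viewed as surfaces over the dose summaries (C_B,max, AUC).  For a new
treatment condition:

1. its (C_B,max, AUC) is computed from the cell line's compartment model;
2. each response parameter is interpolated with a locally weighted linear
   regression (tricube kernel, degree 1) on standardized log10 dose
   features;
3. the Akaike weight w_B is predicted with a fractional-response logistic
   model trained on the training conditions' estimated weights;
4. both response variants are initialized at the first post-treatment
   count of the test condition and run forward; the prediction is their
   weighted average.

Uncertainty bands come from a residual bootstrap: replicate residuals
around the training fits are resampled, the surfaces refit, and the
prediction repeated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator
import statsmodels.api as sm

from .errors import ValidationError
from .fitting import (
    DoseData,
    ResponseFitCollection,
    fit_response_models,
)
from .growth import (
    ModelWeights,
    ResponseParamsA,
    ResponseParamsB,
    Trajectory,
    averaged_prediction,
    solve_population,
)
from .pk import DoseSummary, PKParameters, compute_dose_summary, make_pulse_input

__all__ = [
    "LocalLinearSurface",
    "ResponseParameterSurfaces",
    "WeightModel",
    "PredictionResult",
    "TrajectoryPredictor",
    "interpolate_parameters",
    "fit_weight_model",
    "predict_weight",
    "predict_response",
    "bootstrap_band",
    "mean_percent_error",
]


def mean_percent_error(observed, predicted) -> float:
    """Mean of |obs - pred| / obs across timepoints, as a percentage."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    return 100.0 * float(np.mean(np.abs(observed - predicted) / observed))


class LocalLinearSurface(BaseEstimator):
    """LOESS-style degree-1 local regression on standardized features.

    At each query point the ``span``-nearest training points get tricube
    weights by distance and a weighted linear model is solved; this
    interpolates smooth parameter surfaces without assuming a global form.
    """

    def __init__(self, span: float = 0.5):
        self.span = span

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        if not (0.0 < self.span <= 1.0):
            raise ValidationError("span must lie in (0, 1]")
        if X.shape[0] < 3:
            raise ValidationError("local regression needs at least 3 training points")
        if X.shape[0] != y.size:
            raise ValidationError("X and y must align")
        self.X_ = X
        self.y_ = y
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), 1e-12)
        self.Z_ = (X - self.mean_) / self.scale_
        self.bbox_ = (X.min(axis=0), X.max(axis=0))
        return self

    def _predict_one(self, z: np.ndarray) -> float:
        d = np.linalg.norm(self.Z_ - z, axis=1)
        n = self.Z_.shape[0]
        k = max(3, int(math.ceil(self.span * n)))
        k = min(k, n)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax <= 0:  # all neighbours coincide with the query
            return float(np.mean(self.y_[d == 0]))
        w = np.clip(1.0 - (d / (dmax * (1.0 + 1e-12))) ** 3, 0.0, None) ** 3
        mask = w > 0
        A = np.column_stack([np.ones(mask.sum()), self.Z_[mask] - z])
        W = w[mask]
        AtW = A.T * W
        try:
            beta = np.linalg.lstsq(AtW @ A, AtW @ self.y_[mask], rcond=None)[0]
        except np.linalg.LinAlgError:
            return float(np.average(self.y_[mask], weights=W))
        return float(beta[0])

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.mean_) / self.scale_
        return np.array([self._predict_one(z) for z in Z])

    def is_extrapolated(self, X, rtol: float = 1e-9) -> np.ndarray:
        """Flag queries outside the training bounding box."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo, hi = self.bbox_
        pad = rtol * np.maximum(np.abs(lo), np.abs(hi))
        return np.any((X < lo - pad) | (X > hi + pad), axis=1)


_PARAM_NAMES = ("k_dA", "theta_A", "k_dB", "r", "theta_B")


def _dose_features(doses: Sequence[DoseSummary]) -> np.ndarray:
    feats = []
    for d in doses:
        if d.C_Bmax <= 0 or d.AUC <= 0:
            raise ValidationError("dose features require positive C_Bmax and AUC")
        feats.append([math.log10(d.C_Bmax), math.log10(d.AUC)])
    return np.asarray(feats)


@dataclass
class ResponseParameterSurfaces:
    """One local-regression surface per response parameter."""

    surfaces: dict[str, LocalLinearSurface]
    span: float

    @classmethod
    def from_training(
        cls, training: ResponseFitCollection, span: float = 0.5
    ) -> "ResponseParameterSurfaces":
        fits = [f for f in training.fits if f.dose.C_Bmax > 0 and f.dose.AUC > 0]
        if len(fits) < 3:
            raise ValidationError("need >= 3 treated training doses for interpolation")
        X = _dose_features([f.dose for f in fits])
        values = {
            "k_dA": [f.params_A.k_dA for f in fits],
            "theta_A": [f.params_A.theta for f in fits],
            "k_dB": [f.params_B.k_dB for f in fits],
            "r": [f.params_B.r for f in fits],
            "theta_B": [f.params_B.theta for f in fits],
        }
        surfaces = {
            name: LocalLinearSurface(span=span).fit(X, np.asarray(vals))
            for name, vals in values.items()
        }
        return cls(surfaces=surfaces, span=span)

    def interpolate(self, dose: DoseSummary):
        """Interpolated (variant A, variant B) parameters at a dose.

        Negative interpolants are clipped to zero (rates) or to a small
        positive floor (r, theta, which must stay positive).
        """
        X = _dose_features([dose])
        vals = {name: float(s.predict(X)[0]) for name, s in self.surfaces.items()}
        extrapolated = bool(
            any(s.is_extrapolated(X)[0] for s in self.surfaces.values())
        )
        pA = ResponseParamsA(
            k_dA=max(vals["k_dA"], 0.0), theta=max(vals["theta_A"], 1.0)
        )
        pB = ResponseParamsB(
            k_dB=max(vals["k_dB"], 0.0),
            r=max(vals["r"], 1e-6),
            theta=max(vals["theta_B"], 1.0),
        )
        return pA, pB, extrapolated


def interpolate_parameters(surfaces: ResponseParameterSurfaces, dose: DoseSummary):
    return surfaces.interpolate(dose)


class WeightModel:
    """Fractional-response logistic model for the variant-B weight.

    Trained on the training conditions' estimated Akaike weights (continuous
    in [0, 1]) against standardized features: log10 C_B,max, log10 AUC and
    the response parameter values.  Each condition can carry a sample
    weight reflecting how informative its label is — a weight near 0.5
    produced by two near-identical AICs is a prior artifact, not evidence,
    and should not pull the fitted surface.  Fit by (weighted) binomial
    maximum likelihood; if the GLM degenerates (perfect separation or
    unbounded coefficients) a ridge-stabilized fit takes over and is
    flagged.
    """

    _BETA_CAP = 50.0

    def __init__(self, ridge_lambda: float = 1e-2):
        self.ridge_lambda = ridge_lambda

    def fit(
        self, features: np.ndarray, w_B: np.ndarray, sample_weight=None
    ) -> "WeightModel":
        X = np.atleast_2d(np.asarray(features, dtype=float))
        y = np.asarray(w_B, dtype=float)
        if X.shape[0] < 4:
            raise ValidationError("weight model needs >= 4 training conditions")
        if np.any((y < 0) | (y > 1)):
            raise ValidationError("weights must lie in [0, 1]")
        if sample_weight is None:
            sw = np.ones(X.shape[0])
        else:
            sw = np.asarray(sample_weight, dtype=float)
            if sw.shape != (X.shape[0],) or np.any(sw < 0) or not np.any(sw > 0):
                raise ValidationError(
                    "sample_weight must be non-negative with at least one positive entry"
                )
            sw = sw / sw[sw > 0].mean()
        self.mean_ = X.mean(axis=0)
        self.scale_ = np.maximum(X.std(axis=0), 1e-12)
        Z = sm.add_constant((X - self.mean_) / self.scale_, has_constant="add")
        yc = np.clip(y, 1e-6, 1.0 - 1e-6)
        self.used_ridge_fallback_ = False
        beta = None
        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.GLM(
                    yc, Z, family=sm.families.Binomial(), var_weights=sw
                ).fit(maxiter=200)
            beta = np.asarray(res.params)
            if not np.all(np.isfinite(beta)) or np.any(
                np.abs(beta[1:]) > self._BETA_CAP
            ):
                beta = None
        except Exception:
            beta = None
        if beta is None:
            beta = self._ridge_fit(Z, yc, sw)
            self.used_ridge_fallback_ = True
        self.beta_ = beta
        return self

    def _ridge_fit(self, Z: np.ndarray, y: np.ndarray, sw: np.ndarray) -> np.ndarray:
        lam = self.ridge_lambda

        def nll(b):
            eta = Z @ b
            # log-likelihood of fractional logistic, intercept unpenalized
            ll = sw * (y * eta - np.logaddexp(0.0, eta))
            return -ll.sum() + lam * float(b[1:] @ b[1:])

        b0 = np.zeros(Z.shape[1])
        res = minimize(nll, b0, method="BFGS", options={"maxiter": 500})
        return res.x

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Z = sm.add_constant((X - self.mean_) / self.scale_, has_constant="add")
        return np.clip(expit(Z @ self.beta_), 1e-9, 1.0 - 1e-9)


def _weight_features(dose: DoseSummary, pA: ResponseParamsA, pB: ResponseParamsB):
    return [
        math.log10(max(dose.C_Bmax, 1e-12)),
        math.log10(max(dose.AUC, 1e-12)),
        pA.k_dA,
        pB.k_dB,
        pB.r,
    ]


def fit_weight_model(training: ResponseFitCollection, **kw) -> WeightModel:
    """Evidence-weighted logistic fit of w_B over the training conditions.

    Each condition's label is weighted by |AIC_A - AIC_B| (capped at 50):
    where the two variants fit equally well the Akaike weight is ~0.5 by
    construction and carries no information about which regime the dose
    belongs to.
    """
    fits = [f for f in training.fits if f.dose.C_Bmax > 0 and f.dose.AUC > 0]
    if len(fits) < 4:
        raise ValidationError("weight model needs >= 4 treated training conditions")
    X = np.array([_weight_features(f.dose, f.params_A, f.params_B) for f in fits])
    y = np.array([f.weights.w_B for f in fits])
    evidence = np.array(
        [min(abs(f.fit_A.aic - f.fit_B.aic), 50.0) for f in fits]
    )
    if not np.any(evidence > 0):
        evidence = None  # no dose distinguishes the variants: uniform weights
    return WeightModel(**kw).fit(X, y, sample_weight=evidence)


def predict_weight(model: WeightModel, dose: DoseSummary, pA, pB) -> ModelWeights:
    w_B = float(model.predict([_weight_features(dose, pA, pB)])[0])
    return ModelWeights(w_A=1.0 - w_B, w_B=w_B)


@dataclass
class PredictionResult:
    """Predicted trajectory for one test condition, with diagnostics."""

    trajectory: Trajectory
    dose: DoseSummary
    weights: ModelWeights
    params_A: ResponseParamsA
    params_B: ResponseParamsB
    extrapolated: bool
    band: tuple[np.ndarray, np.ndarray] | None = None
    mean_percent_error: float | None = None
    eoe_percent_error: float | None = None

    def score(self, observed_counts) -> "PredictionResult":
        """Attach mean and end-of-experiment percent errors vs observations."""
        obs = np.asarray(observed_counts, dtype=float)
        pred = self.trajectory.counts
        self.mean_percent_error = mean_percent_error(obs, pred)
        self.eoe_percent_error = 100.0 * float(abs(obs[-1] - pred[-1]) / obs[-1])
        return self


class TrajectoryPredictor(BaseEstimator):
    """Full prediction scheme: surfaces + weight model over a training set."""

    def __init__(self, span: float = 0.5, ridge_lambda: float = 1e-2):
        self.span = span
        self.ridge_lambda = ridge_lambda

    def fit(self, training: ResponseFitCollection, pk_params: PKParameters):
        self.training_ = training
        self.pk_params_ = pk_params
        self.surfaces_ = ResponseParameterSurfaces.from_training(training, span=self.span)
        self.weight_model_ = fit_weight_model(training, ridge_lambda=self.ridge_lambda)
        self.growth_ = training.growth
        return self

    def predict(
        self,
        concentration: float,
        exposure: float,
        N_first: float,
        t_first: float,
        times,
    ) -> PredictionResult:
        """Predict the population trajectory of an unseen condition.

        ``N_first`` is the first post-treatment (replicate-mean) count of
        the test condition, observed at ``t_first``; both variants are
        initialized there and run forward over ``times``.
        """
        if N_first <= 0:
            raise ValidationError("N_first must be > 0")
        times = np.asarray(times, dtype=float)
        pulse = make_pulse_input(concentration, exposure, max(2.0 * exposure, exposure + 24.0))
        dose = compute_dose_summary(self.pk_params_, pulse)
        pA, pB, extrapolated = self.surfaces_.interpolate(dose)
        # an extrapolated capacity below the initial count would make the
        # logistic diverge; the capacity can never undercut an observed count
        if pA.theta < N_first:
            pA = ResponseParamsA(k_dA=pA.k_dA, theta=float(N_first))
        if pB.theta < N_first:
            pB = ResponseParamsB(k_dB=pB.k_dB, r=pB.r, theta=float(N_first))
        weights = predict_weight(self.weight_model_, dose, pA, pB)
        trajA = solve_population(N_first, self.growth_, "A", pA, times, t0=t_first)
        trajB = solve_population(N_first, self.growth_, "B", pB, times, t0=t_first)
        traj = averaged_prediction(trajA, trajB, weights)
        traj.dose = dose
        return PredictionResult(
            trajectory=traj,
            dose=dose,
            weights=weights,
            params_A=pA,
            params_B=pB,
            extrapolated=extrapolated,
        )


def predict_response(
    training: ResponseFitCollection,
    pk_params: PKParameters,
    concentration: float,
    exposure: float,
    N_first: float,
    t_first: float,
    times,
    span: float = 0.5,
) -> PredictionResult:
    predictor = TrajectoryPredictor(span=span).fit(training, pk_params)
    return predictor.predict(concentration, exposure, N_first, t_first, times)


def bootstrap_band(
    training_dose_data: Sequence[DoseData],
    replicate_counts: Sequence[np.ndarray],
    growth,
    pk_params: PKParameters,
    test_condition: tuple[float, float],
    N_first: float,
    t_first: float,
    times,
    B: int = 200,
    seed: int | None = 0,
    alpha: float = 0.1,
    span: float = 0.5,
    exposure: float | None = None,
) -> tuple[np.ndarray, np.ndarray, PredictionResult]:
    """Percentile bootstrap band for a predicted trajectory.

    Replicate residuals (ratios to the weighted best-fit curve) in the
    training experiment are resampled with replacement per dose and
    timepoint, the response surfaces and weight model are refit on the
    resampled replicate means, and the test-condition prediction is
    recomputed; the 2.5/97.5 percentiles across ``B`` resamples form the
    band (widened, if needed, to contain the point prediction).
    """
    if B < 2:
        raise ValidationError("bootstrap needs B >= 2")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if exposure is None:
        exposure = training_dose_data[0].dose.exposure

    base = fit_response_models(training_dose_data, growth, exposure, alpha=alpha)
    predictor = TrajectoryPredictor(span=span).fit(base, pk_params)
    point = predictor.predict(test_condition[0], test_condition[1], N_first, t_first, times)

    # fitted weighted curve per dose, on the dose's own grid
    fitted = []
    for k, dd in enumerate(training_dose_data):
        f = base.fits[k]
        trajA = solve_population(
            f.fit_A.extras["N0"], growth, "A", f.params_A, dd.times, t0=f.t0
        )
        trajB = solve_population(
            f.fit_B.extras["N0"], growth, "B", f.params_B, dd.times, t0=f.t0
        )
        fitted.append(averaged_prediction(trajA, trajB, f.weights).counts)

    ratios = [
        np.asarray(reps, dtype=float) / fit[None, :]
        for reps, fit in zip(replicate_counts, fitted)
    ]

    samples = np.empty((B, times.size))
    for b in range(B):
        boot_data = []
        for k, dd in enumerate(training_dose_data):
            R = ratios[k]
            n_rep, n_t = R.shape
            idx = rng.integers(0, n_rep, size=(n_rep, n_t))
            boot_mean = fitted[k] * R[idx, np.arange(n_t)[None, :]].mean(axis=0)
            boot_data.append(DoseData(dose=dd.dose, times=dd.times, counts=boot_mean))
        coll = fit_response_models(
            boot_data, growth, exposure, alpha=alpha, n_starts=1
        )
        pred = TrajectoryPredictor(span=span).fit(coll, pk_params).predict(
            test_condition[0], test_condition[1], N_first, t_first, times
        )
        samples[b] = pred.trajectory.counts

    lower = np.minimum(np.percentile(samples, 2.5, axis=0), point.trajectory.counts)
    upper = np.maximum(np.percentile(samples, 97.5, axis=0), point.trajectory.counts)
    point.band = (lower, upper)
    return lower, upper, point
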