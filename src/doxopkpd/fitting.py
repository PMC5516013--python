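"""Parameter estimation for the uptake and treatment-response models.

Three sklearn-style estimators cover the three fitting stages:

* :class:`CompartmentModelEstimator` — one shared set of transfer rates
  (k_EF, k_FE, k_FB) per cell line, fit jointly to the intracellular
  drug timecourses of all treatment conditions;
* :class:`LogisticGrowthEstimator` — the cell line's proliferation rate k_p
  and carrying capacity theta from pre-treatment and untreated-control
  counts;
* :class:`ResponseSurfaceEstimator` — per-dose response parameters for one
  exposure-time experiment, all doses fit simultaneously under a
  first-difference smoothness penalty across the concentration series.

All objectives use relative residuals (Y - Yhat)/Y, matching how errors are
reported (mean percent error), and trust-region reflective least squares
with non-negativity bounds and seeded multi-starts.  Confidence intervals
come from the linearized (Jacobian-based) covariance at the optimum.

Model comparison uses AIC = n ln(RSS/n) + 2p and Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .errors import ValidationError
from .growth import (
    GrowthParameters,
    ModelWeights,
    ResponseParamsA,
    ResponseParamsB,
    solve_population,
)
from .pk import DoseSummary, InputFunction, PKParameters, simulate_pk_forced

__all__ = [
    "FitResult",
    "PKCondition",
    "DoseData",
    "DoseResponseFit",
    "ResponseFitCollection",
    "CompartmentModelEstimator",
    "LogisticGrowthEstimator",
    "ResponseSurfaceEstimator",
    "compute_aic",
    "akaike_weights",
    "regularized_objective",
    "fit_pk_parameters",
    "fit_growth",
    "fit_response_surface",
    "fit_response_models",
]

_TINY = 1e-30


# ---------------------------------------------------------------------------
# information criteria


def compute_aic(n: int, rss: float, p: int) -> float:
    """AIC = n ln(RSS/n) + 2p for a least-squares fit."""
    if n <= 0:
        raise ValidationError("n must be > 0")
    if p < 0:
        raise ValidationError("p must be >= 0")
    if rss < 0:
        raise ValidationError("RSS must be >= 0")
    if rss == 0:
        raise ValidationError("RSS = 0 gives AIC = -inf; perfect fits are degenerate")
    return n * math.log(rss / n) + 2 * p


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Normalized model probabilities from a list of AIC values."""
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValidationError("need at least one AIC value")
    if not np.any(np.isfinite(aics)):
        raise ValidationError("need at least one finite AIC value")
    if np.any(np.isneginf(aics)):  # a perfect fit dominates
        w = np.where(np.isneginf(aics), 1.0, 0.0)
        return w / w.sum()
    delta = aics - np.min(aics[np.isfinite(aics)])
    w = np.exp(-0.5 * delta)
    w[~np.isfinite(aics)] = 0.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# result containers


@dataclass
class FitResult:
    """Point estimates with 95% CIs and fit diagnostics for one model."""

    params: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    rss: float
    n: int
    p: int
    aic: float | None
    converged: bool
    message: str = ""
    extras: dict = field(default_factory=dict)


@dataclass
class PKCondition:
    """Observed intracellular (free + bound) series for one treatment."""

    input_function: InputFunction
    times: np.ndarray
    intracellular_total: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intracellular_total = np.asarray(self.intracellular_total, dtype=float)
        if self.times.shape != self.intracellular_total.shape:
            raise ValidationError("times and observations must align")


@dataclass
class DoseData:
    """Replicate-mean post-treatment counts for one dose."""

    dose: DoseSummary
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValidationError("times and counts must align")
        if np.any(self.counts <= 0):
            raise ValidationError("counts must be > 0 (relative residuals)")


@dataclass
class DoseResponseFit:
    """Both response variants fit at one dose, with their Akaike weights."""

    dose: DoseSummary
    params_A: ResponseParamsA
    params_B: ResponseParamsB
    fit_A: FitResult
    fit_B: FitResult
    weights: ModelWeights
    N0: float
    t0: float


@dataclass
class ResponseFitCollection:
    """Per-dose fits for one exposure-time experiment."""

    growth: GrowthParameters
    fits: list[DoseResponseFit]
    exposure: float


# ---------------------------------------------------------------------------
# shared numerics


def _linearized_ci(jac: np.ndarray, residuals: np.ndarray, n_params: int, level: float = 0.95):
    """Standard errors and CIs from the Jacobian at the optimum."""
    n, p = residuals.size, n_params
    dof = max(n - p, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    # Equilibrate before pseudo-inverting: raw parameters can differ by many
    # orders of magnitude, which makes J^T J so ill-conditioned that pinv's
    # relative cutoff silently truncates genuine (sloppy) directions and
    # understates the variance along them.
    d = np.sqrt(np.diag(jtj))
    d = np.where(d > 0, d, 1.0)
    scaled = jtj / np.outer(d, d)
    cov = (np.linalg.pinv(scaled, hermitian=True) / np.outer(d, d)) * s2
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tq = stats.t.ppf(0.5 + level / 2.0, dof)
    return se, tq * se, cov


def _multistart_least_squares(fun, x0, bounds, starts, rng, **kw):
    """Run trust-region reflective least squares from several seeded starts."""
    best = None
    lo, hi = bounds
    for i in range(starts):
        if i == 0:
            xi = np.asarray(x0, dtype=float)
        else:
            factor = np.exp(rng.uniform(-1.5, 1.5, size=len(x0)))
            xi = np.clip(np.asarray(x0) * factor, lo, hi)
            xi = np.where(np.asarray(x0) == 0, rng.uniform(0, 1e-3, len(x0)), xi)
        try:
            res = optimize.least_squares(fun, xi, bounds=bounds, method="trf", **kw)
        except Exception:  # a bad start may make the model blow up
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValidationError("all optimizer starts failed")
    return best


# ---------------------------------------------------------------------------
# PK parameter estimation


class CompartmentModelEstimator(BaseEstimator):
    """Shared (k_EF, k_FE, k_FB) for a cell line from uptake timecourses.

    The fit target is the intracellular total C_F + C_B with relative
    residuals, pooled jointly across all supplied treatment conditions; the
    extracellular input function is prescribed, never fit.  Pre-drug
    timepoints with zero observed signal are excluded (their relative
    residual is undefined).

    Parameters
    ----------
    v_E, v_I : compartment volumes in uL (defaults: 250 uL media,
        10,000 cells x 2e-6 uL/cell).
    n_starts : seeded multi-starts for the trust-region optimizer.
    """

    def __init__(
        self,
        v_E: float = 250.0,
        v_I: float = 0.02,
        n_starts: int = 5,
        random_state: int | None = 0,
        ci_level: float = 0.95,
    ):
        self.v_E = v_E
        self.v_I = v_I
        self.n_starts = n_starts
        self.random_state = random_state
        self.ci_level = ci_level

    _BOUNDS = (np.array([0.0, 0.0, 0.0]), np.array([np.inf, np.inf, np.inf]))
    _X0 = np.array([1e-3, 0.2, 0.05])

    def fit(self, conditions: Sequence[PKCondition], y=None):
        if not conditions:
            raise ValidationError("need at least one treatment condition")
        masks = []
        for cond in conditions:
            mask = cond.intracellular_total > 0
            if mask.sum() == 0:
                raise ValidationError("a condition has no positive observations")
            masks.append(mask)
        if all(np.all(c.intracellular_total == 0) for c in conditions):
            raise ValidationError("all-zero data cannot constrain the PK model")

        def residuals(x):
            out = []
            for cond, mask in zip(conditions, masks):
                params = PKParameters(x[0], x[1], x[2], self.v_I, self.v_E)
                tc = simulate_pk_forced(params, cond.input_function, cond.times)
                model = tc.intracellular_total[mask]
                obs = cond.intracellular_total[mask]
                out.append((obs - model) / obs)
            return np.concatenate(out)

        rng = np.random.default_rng(self.random_state)
        res = _multistart_least_squares(
            residuals, self._X0, self._BOUNDS, self.n_starts, rng, xtol=1e-12, ftol=1e-12
        )

        names = ("k_EF", "k_FE", "k_FB")
        se, half, cov = _linearized_ci(res.jac, res.fun, 3, self.ci_level)
        self.k_EF_, self.k_FE_, self.k_FB_ = (float(v) for v in res.x)
        self.params_ = PKParameters(*res.x, v_I=self.v_I, v_E=self.v_E)
        self.conf_int_ = {
            nm: (float(res.x[i] - half[i]), float(res.x[i] + half[i]))
            for i, nm in enumerate(names)
        }
        self.cov_ = cov
        self.rss_ = float(res.fun @ res.fun)
        self.n_obs_ = int(res.fun.size)
        self.converged_ = bool(res.success)
        per_cond = []
        for cond, mask in zip(conditions, masks):
            tc = simulate_pk_forced(self.params_, cond.input_function, cond.times)
            err = np.abs(
                (cond.intracellular_total[mask] - tc.intracellular_total[mask])
                / cond.intracellular_total[mask]
            )
            per_cond.append(100.0 * float(err.mean()))
        self.mean_percent_error_ = float(np.mean(per_cond))
        self.result_ = FitResult(
            params={nm: float(res.x[i]) for i, nm in enumerate(names)},
            conf_int=self.conf_int_,
            rss=self.rss_,
            n=self.n_obs_,
            p=3,
            aic=compute_aic(self.n_obs_, self.rss_, 3) if self.rss_ > 0 else None,
            converged=self.converged_,
            message=res.message,
            extras={"mean_percent_error": self.mean_percent_error_},
        )
        return self

    def predict(self, input_function: InputFunction, times):
        return simulate_pk_forced(self.params_, input_function, times)


# ---------------------------------------------------------------------------
# control growth


class LogisticGrowthEstimator(BaseEstimator):
    """k_p and theta from pre-treatment plus untreated-control counts.

    Fits the logistic solution N(t) = theta / (1 + (theta/N0 - 1)
    exp(-k_p (t - t0))) with N0 free, on relative residuals.  theta is only
    identifiable if the data approach the plateau; the fit flags
    ``theta_identifiable_ = False`` when the largest observed count stays
    below half the estimated capacity or the CI on theta is unbounded.
    """

    def __init__(
        self, n_starts: int = 3, random_state: int | None = 0, ci_level: float = 0.95
    ):
        self.n_starts = n_starts
        self.random_state = random_state
        self.ci_level = ci_level

    def fit(self, times, counts):
        times = np.asarray(times, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if times.size != counts.size:
            raise ValidationError("times and counts must align")
        if times.size < 3:
            raise ValidationError("growth fit needs at least 3 timepoints")
        if np.any(counts <= 0):
            raise ValidationError("counts must be > 0")
        t0 = float(times[0])

        # initial guesses: early log-slope for k_p, plateau for theta
        span = max(times[-1] - times[0], 1.0)
        kp0 = max((np.log(counts[-1]) - np.log(counts[0])) / span, 1e-4)
        theta0 = 1.5 * float(counts.max())
        x0 = np.array([kp0, theta0, float(counts[0])])
        lo = np.array([0.0, float(counts.max()) * 0.5, _TINY])
        hi = np.array([1.0, 1e9, float(counts.max()) * 10])

        def residuals(x):
            kp, theta, n0 = x
            growth = GrowthParameters(k_p=kp, theta=theta)
            model = solve_population(n0, growth, None, None, times, t0=t0).counts
            return (counts - model) / counts

        rng = np.random.default_rng(self.random_state)
        res = _multistart_least_squares(
            residuals, x0, (lo, hi), self.n_starts, rng, xtol=1e-13, ftol=1e-13
        )
        se, half, cov = _linearized_ci(res.jac, res.fun, 3, self.ci_level)
        names = ("k_p", "theta", "N0")
        self.k_p_, self.theta_, self.N0_ = (float(v) for v in res.x)
        self.growth_ = GrowthParameters(k_p=self.k_p_, theta=self.theta_)
        self.conf_int_ = {
            nm: (float(res.x[i] - half[i]), float(res.x[i] + half[i]))
            for i, nm in enumerate(names)
        }
        self.rss_ = float(res.fun @ res.fun)
        self.converged_ = bool(res.success)
        rel_width = (self.conf_int_["theta"][1] - self.conf_int_["theta"][0]) / self.theta_
        self.theta_identifiable_ = bool(
            counts.max() >= 0.5 * self.theta_ and np.isfinite(rel_width) and rel_width < 5.0
        )
        if times.size < 5:
            self.theta_identifiable_ = False
        self.result_ = FitResult(
            params={nm: float(res.x[i]) for i, nm in enumerate(names)},
            conf_int=self.conf_int_,
            rss=self.rss_,
            n=int(times.size),
            p=3,
            aic=None,
            converged=self.converged_,
            message=res.message,
            extras={"theta_identifiable": self.theta_identifiable_},
        )
        return self

    def predict(self, times):
        return solve_population(
            self.N0_, self.growth_, None, None, np.asarray(times, dtype=float)
        ).counts


# ---------------------------------------------------------------------------
# regularized per-dose response fitting


def regularized_objective(
    param_matrix: np.ndarray, residuals_per_dose: Sequence[np.ndarray], alpha: float
) -> float:
    """G = sum over doses of relative SSE plus alpha x squared roughness.

    ``param_matrix`` holds one row per dose (ordered by concentration) and
    one column per response parameter.  Each column is scaled by its mean
    absolute value across doses before first differences between adjacent
    doses are taken, so parameters of different magnitudes contribute
    comparably to the penalty.
    """
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    P = np.asarray(param_matrix, dtype=float)
    if P.ndim != 2:
        raise ValidationError("param_matrix must be 2-D (doses x parameters)")
    sse = float(sum(np.asarray(r, dtype=float) @ np.asarray(r, dtype=float)
                    for r in residuals_per_dose))
    return sse + alpha * _roughness(P)


def _roughness(P: np.ndarray) -> float:
    if P.shape[0] < 2:
        return 0.0
    scale = np.maximum(np.mean(np.abs(P), axis=0), _TINY)
    diffs = np.diff(P / scale, axis=0)
    return float(np.sum(diffs**2))


class ResponseSurfaceEstimator(BaseEstimator):
    """Per-dose response parameters for one exposure-time experiment.

    All doses of the experiment are fit simultaneously: the objective is the
    pooled relative SSE plus ``alpha`` times the squared first difference of
    the (scaled) parameters between concentration-adjacent doses, which
    penalizes non-smooth variation of the response surface and stabilizes
    doses whose data alone cannot resolve their parameters.

    k_p is fixed to the control estimate.  Each dose's initial count N0 is
    a per-dose nuisance parameter started at the first post-treatment
    replicate-mean count; fitting it (rather than fixing it to the noisy
    observation) keeps the reported parameter confidence intervals honest,
    since an error in a fixed N0 would propagate into the kill rates
    without appearing in their covariance.  theta is a free parameter only
    where the population reaches at least ``theta_fix_fraction`` of the
    control capacity; in regressing populations it is not identifiable and
    is fixed to the control value.
    """

    def __init__(
        self,
        variant: str = "A",
        alpha: float = 0.1,
        theta_fix_fraction: float = 0.5,
        n_starts: int = 3,
        random_state: int | None = 0,
        ci_level: float = 0.95,
    ):
        self.variant = variant
        self.alpha = alpha
        self.theta_fix_fraction = theta_fix_fraction
        self.n_starts = n_starts
        self.random_state = random_state
        self.ci_level = ci_level

    def fit(self, dose_data: Sequence[DoseData], growth: GrowthParameters):
        if self.variant not in ("A", "B"):
            raise ValidationError("variant must be 'A' or 'B'")
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if not dose_data:
            raise ValidationError("need at least one dose")
        order = np.argsort([d.dose.concentration for d in dose_data])
        doses = [dose_data[i] for i in order]

        theta_free = [
            float(d.counts.max()) >= self.theta_fix_fraction * growth.theta for d in doses
        ]
        n0 = [float(d.counts[0]) for d in doses]
        t0 = [float(d.times[0]) for d in doses]

        # per-dose free-parameter layout (N0 is a nuisance parameter)
        per_dose_names: list[list[str]] = []
        for free in theta_free:
            names = ["k_dA"] if self.variant == "A" else ["k_dB", "r"]
            if free:
                names.append("theta")
            names.append("N0")
            per_dose_names.append(names)
        slices, pos = [], 0
        for names in per_dose_names:
            slices.append(slice(pos, pos + len(names)))
            pos += len(names)
        n_free = pos

        lo = np.zeros(n_free)
        hi = np.full(n_free, np.inf)
        x0 = np.empty(n_free)
        for d, names, sl, free in zip(doses, per_dose_names, slices, theta_free):
            g = (math.log(d.counts[-1]) - math.log(d.counts[0])) / max(
                d.times[-1] - d.times[0], 1.0
            )
            kd0 = float(np.clip(growth.k_p - g, 1e-4, 0.5))
            vals = [kd0] if self.variant == "A" else [kd0, 1.0 / (7 * 24.0)]
            bounds_lo = [0.0] if self.variant == "A" else [0.0, 1e-5]
            bounds_hi = [2.0] if self.variant == "A" else [2.0, 1.0]
            if free:
                vals.append(growth.theta)
                bounds_lo.append(max(1.0, d.counts.max() * 0.5))
                bounds_hi.append(1e9)
            first = float(d.counts[0])
            vals.append(first)
            bounds_lo.append(first * 0.2)
            bounds_hi.append(first * 5.0)
            x0[sl] = vals
            lo[sl] = bounds_lo
            hi[sl] = bounds_hi

        def unpack(x, k):
            vals = dict(zip(per_dose_names[k], x[slices[k]]))
            theta = vals.get("theta", growth.theta)
            if self.variant == "A":
                return ResponseParamsA(k_dA=max(vals["k_dA"], 0.0), theta=max(theta, _TINY))
            return ResponseParamsB(
                k_dB=max(vals["k_dB"], 0.0), r=max(vals["r"], 1e-12), theta=max(theta, _TINY)
            )

        def n0_of(x, k):
            return float(x[slices[k].start + per_dose_names[k].index("N0")])

        def param_matrix(x):
            cols = ["k_dA", "theta"] if self.variant == "A" else ["k_dB", "r", "theta"]
            P = np.empty((len(doses), len(cols)))
            for k in range(len(doses)):
                p = unpack(x, k)
                for j, c in enumerate(cols):
                    P[k, j] = getattr(p, c)
            return P

        sqrt_alpha = math.sqrt(self.alpha)

        def residuals(x):
            out = []
            for k, d in enumerate(doses):
                p = unpack(x, k)
                model = solve_population(
                    n0_of(x, k), growth, self.variant, p, d.times, t0=t0[k]
                ).counts
                out.append((d.counts - model) / d.counts)
            if sqrt_alpha > 0 and len(doses) > 1:
                P = param_matrix(x)
                scale = np.maximum(np.mean(np.abs(P), axis=0), _TINY)
                out.append(sqrt_alpha * np.diff(P / scale, axis=0).ravel())
            return np.concatenate(out)

        rng = np.random.default_rng(self.random_state)
        res = _multistart_least_squares(
            residuals, x0, (lo, hi), self.n_starts, rng, xtol=1e-12, ftol=1e-12
        )
        se, half, cov = _linearized_ci(res.jac, res.fun, n_free, self.ci_level)

        self.fits_: list[FitResult] = []
        self.params_ = []
        self.doses_ = [d.dose for d in doses]
        for k, d in enumerate(doses):
            p = unpack(res.x, k)
            self.params_.append(p)
            n0_hat = n0_of(res.x, k)
            model = solve_population(n0_hat, growth, self.variant, p, d.times, t0=t0[k]).counts
            r = (d.counts - model) / d.counts
            rss = float(r @ r)
            n_k = int(d.times.size)
            p_k = len(per_dose_names[k])
            ci = {}
            for j, nm in enumerate(per_dose_names[k]):
                i = slices[k].start + j
                ci[nm] = (float(res.x[i] - half[i]), float(res.x[i] + half[i]))
            if not theta_free[k]:
                ci["theta"] = (growth.theta, growth.theta)
            aic = compute_aic(n_k, rss, p_k) if rss > 0 else -math.inf
            self.fits_.append(
                FitResult(
                    params={
                        nm: float(res.x[slices[k].start + j])
                        for j, nm in enumerate(per_dose_names[k])
                    },
                    conf_int=ci,
                    rss=rss,
                    n=n_k,
                    p=p_k,
                    aic=aic,
                    converged=bool(res.success),
                    extras={
                        "theta_fixed": not theta_free[k],
                        "N0": n0_hat,
                        "N0_observed": n0[k],
                        "t0": t0[k],
                        "dose": d.dose,
                    },
                )
            )
        self.converged_ = bool(res.success)
        self.objective_ = 2.0 * float(res.cost)
        self.roughness_ = _roughness(
            np.array(
                [
                    (
                        [p.k_dA, p.theta]
                        if self.variant == "A"
                        else [p.k_dB, p.r, p.theta]
                    )
                    for p in self.params_
                ]
            )
        )
        self.growth_ = growth
        return self

    def predict(self, dose_index: int, times):
        fr = self.fits_[dose_index]
        return solve_population(
            fr.extras["N0"],
            self.growth_,
            self.variant,
            self.params_[dose_index],
            np.asarray(times, dtype=float),
            t0=fr.extras["t0"],
        ).counts


# ---------------------------------------------------------------------------
# functional wrappers


def fit_pk_parameters(
    conditions: Sequence[PKCondition], v_E: float = 250.0, v_I: float = 0.02, **kw
) -> CompartmentModelEstimator:
    return CompartmentModelEstimator(v_E=v_E, v_I=v_I, **kw).fit(conditions)


def fit_growth(times, counts, **kw) -> LogisticGrowthEstimator:
    return LogisticGrowthEstimator(**kw).fit(times, counts)


def fit_response_surface(
    dose_data: Sequence[DoseData], growth: GrowthParameters, variant: str = "A", **kw
) -> ResponseSurfaceEstimator:
    return ResponseSurfaceEstimator(variant=variant, **kw).fit(dose_data, growth)


def fit_response_models(
    dose_data: Sequence[DoseData],
    growth: GrowthParameters,
    exposure: float,
    alpha: float = 0.1,
    **kw,
) -> ResponseFitCollection:
    """Fit both response variants and combine them via Akaike weights."""
    est_A = ResponseSurfaceEstimator(variant="A", alpha=alpha, **kw).fit(dose_data, growth)
    est_B = ResponseSurfaceEstimator(variant="B", alpha=alpha, **kw).fit(dose_data, growth)
    fits = []
    for k in range(len(est_A.fits_)):
        fa, fb = est_A.fits_[k], est_B.fits_[k]
        w = akaike_weights([fa.aic, fb.aic])
        fits.append(
            DoseResponseFit(
                dose=fa.extras["dose"],
                params_A=est_A.params_[k],
                params_B=est_B.params_[k],
                fit_A=fa,
                fit_B=fb,
                weights=ModelWeights(w_A=float(w[0]), w_B=float(w[1])),
                N0=fa.extras["N0"],
                t0=fa.extras["t0"],
            )
        )
    return ResponseFitCollection(growth=growth, fits=fits, exposure=exposure)
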