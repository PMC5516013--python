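"""Logistic growth with time-dependent drug-induced death.

The population obeys

    dN/dt = (k_p - k_d(t, D)) N (1 - N / theta(D)),

where ``k_p`` is the pre-treatment proliferation rate, ``theta`` the
carrying capacity of the well and ``k_d`` one of two dose-specific death
profiles switched on at the moment of drug application (t = 0):

* variant A — an immediate, constant kill rate ``k_dA`` (apoptosis-like:
  the growth rate drops instantly to a stable post-treatment value);
* variant B — a smooth rise-and-decay kill ``k_dB * r * t * exp(1 - r t)``
  (mitotic-catastrophe-like: the effect builds over days, peaks at
  ``k_dB`` when t = 1/r, then fades so the population can regrow).

The substitution u = theta/N - 1 linearises the equation for any
time-varying net rate, giving the closed form

    N(t) = theta / (1 + (theta/N0 - 1) exp(-M(t))),
    M(t) = integral from t0 to t of (k_p - k_d(s)) ds,

which is what ``solve_population`` evaluates; the kill-rate integrals are
available analytically for both variants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import ValidationError
from .pk import DoseSummary

__all__ = [
    "GrowthParameters",
    "ResponseParamsA",
    "ResponseParamsB",
    "ModelWeights",
    "Trajectory",
    "death_rate",
    "death_rate_integral",
    "solve_population",
    "averaged_prediction",
]


@dataclass(frozen=True)
class GrowthParameters:
    """Cell-line proliferation rate (hr^-1) and carrying capacity (cells)."""

    k_p: float
    theta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.k_p) or self.k_p < 0:
            raise ValidationError("k_p must be finite and >= 0")
        if not math.isfinite(self.theta) or self.theta <= 0:
            raise ValidationError("theta must be finite and > 0")


@dataclass(frozen=True)
class ResponseParamsA:
    """Immediate-kill response: constant death rate k_dA after t = 0."""

    k_dA: float
    theta: float

    def __post_init__(self) -> None:
        if self.k_dA < 0:
            raise ValidationError("k_dA must be >= 0")
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")


@dataclass(frozen=True)
class ResponseParamsB:
    """Delayed-kill response: k_d(t) = k_dB * r * t * exp(1 - r t).

    The curve peaks at exactly ``k_dB`` at t = 1/r and decays to zero, so a
    treated population can decline transiently and then recover.
    """

    k_dB: float
    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.k_dB < 0:
            raise ValidationError("k_dB must be >= 0")
        if self.r <= 0:
            raise ValidationError("r must be > 0")
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")


@dataclass(frozen=True)
class ModelWeights:
    """Akaike weights of the two response variants; must sum to one."""

    w_A: float
    w_B: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_A <= 1.0 and 0.0 <= self.w_B <= 1.0):
            raise ValidationError("weights must lie in [0, 1]")
        if abs(self.w_A + self.w_B - 1.0) > 1e-9:
            raise ValidationError("weights must sum to 1")


@dataclass
class Trajectory:
    """Cell counts on a time grid; t = 0 is the moment of drug application."""

    times: np.ndarray
    counts: np.ndarray
    dose: DoseSummary | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times.shape != self.counts.shape:
            raise ValidationError("times and counts must have the same shape")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts <= 0):
            raise ValidationError("counts must be finite and > 0")


def _params_for(variant: str, params) -> None:
    if variant == "A":
        if not isinstance(params, ResponseParamsA):
            raise ValidationError("variant A requires ResponseParamsA")
    elif variant == "B":
        if not isinstance(params, ResponseParamsB):
            raise ValidationError("variant B requires ResponseParamsB")
    else:
        raise ValidationError(f"unknown variant {variant!r}")


def death_rate(t, variant: str, params) -> np.ndarray:
    """Kill rate k_d(t) for the given variant; zero before treatment."""
    _params_for(variant, params)
    t = np.asarray(t, dtype=float)
    if variant == "A":
        out = np.where(t >= 0, params.k_dA, 0.0)
    else:
        tt = np.clip(t, 0.0, None)
        out = np.where(t >= 0, params.k_dB * params.r * tt * np.exp(1.0 - params.r * tt), 0.0)
    return out


def death_rate_integral(t, variant: str, params) -> np.ndarray:
    """K(t) = integral of k_d from 0 to t (zero for t <= 0).

    Variant A: k_dA * t.  Variant B: (k_dB e / r) (1 - exp(-r t)(1 + r t)),
    the exact antiderivative of k_dB r s exp(1 - r s).
    """
    _params_for(variant, params)
    t = np.asarray(t, dtype=float)
    tt = np.clip(t, 0.0, None)
    if variant == "A":
        return params.k_dA * tt
    rt = params.r * tt
    return (params.k_dB * math.e / params.r) * (1.0 - np.exp(-rt) * (1.0 + rt))


def solve_population(
    N0: float,
    growth: GrowthParameters,
    variant: str | None,
    params,
    times: Sequence[float],
    t0: float | None = None,
) -> Trajectory:
    """Closed-form population trajectory from N(t0) = N0.

    ``variant=None`` gives untreated logistic growth with the carrying
    capacity of ``growth``; otherwise ``params.theta`` is used and the kill
    profile of the chosen variant is subtracted from the net rate.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValidationError("time grid must be non-empty and 1-D")
    if t0 is None:
        t0 = float(times[0])
    if np.any(times < t0 - 1e-12):
        raise ValidationError("grid must start at or after the initialization time")
    if N0 <= 0 or not math.isfinite(N0):
        raise ValidationError("N0 must be finite and > 0")

    if variant is None:
        theta = growth.theta
        M = growth.k_p * (times - t0)
    else:
        _params_for(variant, params)
        theta = params.theta
        K = death_rate_integral(times, variant, params) - death_rate_integral(
            t0, variant, params
        )
        M = growth.k_p * (times - t0) - K

    if N0 < theta:
        counts = theta * expit(logit(N0 / theta) + M)
        counts = np.maximum(counts, np.finfo(float).tiny)
    else:
        # above carrying capacity the sigmoid form is invalid; use the raw
        # closed form (well-behaved for the decaying regimes encountered)
        u0 = theta / N0 - 1.0
        counts = theta / (1.0 + u0 * np.exp(-M))
    return Trajectory(times=times, counts=counts)


def averaged_prediction(
    trajA: Trajectory, trajB: Trajectory, weights: ModelWeights
) -> Trajectory:
    """Pointwise Akaike-weighted average of the two variant trajectories."""
    if trajA.times.shape != trajB.times.shape or not np.allclose(
        trajA.times, trajB.times, rtol=0, atol=1e-9
    ):
        raise ValidationError("trajectories must share an identical time grid")
    counts = weights.w_A * trajA.counts + weights.w_B * trajB.counts
    return Trajectory(times=trajA.times.copy(), counts=counts, dose=trajA.dose or trajB.dose)
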