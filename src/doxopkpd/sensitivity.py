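"""Variance-based global sensitivity via the extended FAST method.

eFAST drives all parameters along space-filling search curves
x_k(s) = 0.5 + (1/pi) arcsin(sin(omega_k s + phi_k)), assigning a high
frequency to the parameter of interest and low frequencies to the
complementary set.  The Fourier spectrum of the model output along the
curve then apportions output variance by frequency: the total-order index

    S_Ti = 1 - V_complement / V_total

captures the parameter's full contribution including all interactions,
scaled to [0, 1].  Indices are averaged over ``resamples`` random phase
shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .fitting import ResponseFitCollection
from .growth import solve_population

__all__ = [
    "EfastSettings",
    "SensitivityResult",
    "efast_total_order",
    "response_sensitivity",
]


@dataclass(frozen=True)
class EfastSettings:
    """Sampling settings: conventional eFAST defaults (M=4, 5 resamples)."""

    samples_per_curve: int = 257
    interference: int = 4  # harmonics considered per frequency
    resamples: int = 5

    def __post_init__(self) -> None:
        if self.samples_per_curve < 4 * self.interference**2 + 1:
            raise ValidationError(
                "samples_per_curve must be >= 4*M^2 + 1 "
                f"({4 * self.interference ** 2 + 1} for M={self.interference})"
            )
        if self.resamples < 1:
            raise ValidationError("resamples must be >= 1")


@dataclass
class SensitivityResult:
    """Total-order indices per parameter plus the sampling settings used."""

    S_TI: dict[str, float]
    settings: EfastSettings
    seed: int | None = None
    extras: dict = field(default_factory=dict)


def _frequencies(n_params: int, Ns: int, M: int) -> tuple[int, np.ndarray]:
    """High frequency for the parameter of interest, low ones for the rest."""
    omega_hi = (Ns - 1) // (2 * M)
    m = max(omega_hi // (2 * M), 1)
    if n_params == 1:
        return omega_hi, np.array([], dtype=int)
    if m >= n_params - 1:
        others = np.floor(np.linspace(1, m, n_params - 1)).astype(int)
    else:
        others = 1 + (np.arange(n_params - 1) % m)
    return omega_hi, others


def efast_total_order(
    model: Callable[[np.ndarray], np.ndarray],
    ranges: Mapping[str, tuple[float, float]],
    settings: EfastSettings | None = None,
    seed: int | None = 0,
) -> SensitivityResult:
    """Total-order eFAST indices of ``model`` over uniform parameter ranges.

    ``model`` maps an (n_samples, n_params) array (column order = ``ranges``
    key order) to a 1-D output array.
    """
    settings = settings or EfastSettings()
    names = list(ranges.keys())
    n = len(names)
    if n < 2:
        raise ValidationError("eFAST needs at least 2 parameters")
    lo = np.array([ranges[k][0] for k in names], dtype=float)
    hi = np.array([ranges[k][1] for k in names], dtype=float)
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ValidationError("parameter ranges must be finite")
    if np.any(hi <= lo):
        raise ValidationError("degenerate parameter range (width <= 0)")

    Ns = settings.samples_per_curve
    M = settings.interference
    rng = np.random.default_rng(seed)
    s = (2.0 * math.pi / Ns) * np.arange(Ns)

    omega_hi, omega_lo = _frequencies(n, Ns, M)
    half = (Ns - 1) // 2
    cutoff = max(omega_hi // 2, 1)

    sti = np.zeros(n)
    for i in range(n):
        omega = np.empty(n)
        omega[i] = omega_hi
        omega[np.arange(n) != i] = omega_lo
        acc = 0.0
        for _ in range(settings.resamples):
            phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
            X01 = 0.5 + (1.0 / math.pi) * np.arcsin(
                np.sin(omega[None, :] * s[:, None] + phi[None, :])
            )
            X = lo + X01 * (hi - lo)
            y = np.asarray(model(X), dtype=float)
            if y.shape != (Ns,):
                raise ValidationError("model must return one output per sample")
            spec = np.abs(np.fft.fft(y)) ** 2 / Ns**2
            V = 2.0 * spec[1 : half + 1].sum()
            # a (numerically) constant output has no variance to apportion
            if V <= 1e-20 * max(1.0, float(np.mean(y)) ** 2):
                continue
            V_ci = 2.0 * spec[1 : cutoff + 1].sum()
            acc += 1.0 - V_ci / V
        sti[i] = acc / settings.resamples

    return SensitivityResult(
        S_TI={nm: float(np.clip(v, 0.0, 1.0)) for nm, v in zip(names, sti)},
        settings=settings,
        seed=seed,
    )


def response_sensitivity(
    training: ResponseFitCollection,
    horizon_hr: float,
    settings: EfastSettings | None = None,
    seed: int | None = 0,
    r_threshold: float = 0.3,
) -> list[dict]:
    """Per-dose total-order indices of the end-of-experiment count.

    For each dose and each response variant, parameter ranges are the
    fitted 95% CIs (clipped to the valid domain) and the model output is
    the predicted count at ``horizon_hr``.  Parameters whose CI collapses
    to a point contribute no variance and get S_TI = 0 without sampling.
    Doses where S_TI(r) <= ``r_threshold`` are flagged (the regime where
    the effect-induction rate barely moves the prediction).
    """
    growth = training.growth
    out = []
    for f in training.fits:
        record = {"dose": f.dose, "variants": {}}
        for variant, fit, order in (
            ("A", f.fit_A, ["k_dA", "theta"]),
            ("B", f.fit_B, ["k_dB", "r", "theta"]),
        ):
            floors = {"k_dA": 0.0, "k_dB": 0.0, "r": 1e-8, "theta": 1.0}
            ranges, fixed = {}, {}
            for nm in order:
                if nm not in fit.conf_int:
                    raise ValidationError(f"missing CI for parameter {nm}")
                lo, hi = fit.conf_int[nm]
                lo = max(lo, floors[nm])
                hi = max(hi, floors[nm])
                if hi - lo <= 0:
                    fixed[nm] = max(fit.params.get(nm, lo), floors[nm])
                else:
                    ranges[nm] = (lo, hi)
            center = {
                nm: max(fit.params.get(nm, growth.theta if nm == "theta" else 0.0),
                        floors[nm])
                for nm in order
            }
            if "theta" in fixed and "theta" not in fit.params:
                center["theta"] = fixed["theta"]

            def end_count(X, _names=list(ranges), _fixed=dict(fixed),
                          _variant=variant, _center=dict(center), _f=f):
                vals = dict(_center)
                ys = np.empty(X.shape[0])
                from .growth import ResponseParamsA, ResponseParamsB

                for row in range(X.shape[0]):
                    vals.update(dict(zip(_names, X[row])))
                    vals.update(_fixed)
                    if _variant == "A":
                        p = ResponseParamsA(k_dA=vals["k_dA"], theta=vals["theta"])
                    else:
                        p = ResponseParamsB(
                            k_dB=vals["k_dB"], r=vals["r"], theta=vals["theta"]
                        )
                    ys[row] = solve_population(
                        _f.N0, growth, _variant, p, np.array([horizon_hr]), t0=_f.t0
                    ).counts[0]
                return ys

            if len(ranges) >= 2:
                res = efast_total_order(end_count, ranges, settings, seed)
                sti = dict(res.S_TI)
            elif len(ranges) == 1:
                nm = next(iter(ranges))
                lo, hi = ranges[nm]
                probe = end_count(np.linspace(lo, hi, 16)[:, None])
                sti = {nm: 1.0 if float(np.ptp(probe)) > 0 else 0.0}
            else:
                sti = {}
            for nm in fixed:
                sti[nm] = 0.0
            entry = {"S_TI": {nm: sti[nm] for nm in order}}
            if variant == "B":
                entry["r_insensitive"] = bool(sti["r"] <= r_threshold)
            record["variants"][variant] = entry
        out.append(record)
    return out
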