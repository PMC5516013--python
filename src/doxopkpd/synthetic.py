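"""Synthetic datasets with the experimental design the analysis assumes.

No raw imaging data ships with this package, so every stage is exercised
against generated tables that copy the study design: a two-fold doxorubicin
dilution series (10-2500 nM response experiments; 312.5-2500 nM uptake
experiments) plus an untreated control, 6/12/24-hour exposures, ~15-minute
drug-uptake sampling over ~25 hours, daily nuclear counts from three days
before treatment to thirty days after, and six count replicates.

The ground truth is explicit: compartment-model rates for the uptake
timecourses, and response-parameter surfaces that are smooth saturating
functions of the bound-drug peak C_B,max — emulating the empirical
collapse of fitted parameters onto a single curve in C_B,max — with a
logistic switch of the model weight from the delayed-kill variant (low
dose) to the immediate-kill variant (high dose).  Noise is multiplicative
log-normal with a configurable CV.  Generators return tidy DataFrames plus
a truth record for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .growth import (
    GrowthParameters,
    ModelWeights,
    ResponseParamsA,
    ResponseParamsB,
    averaged_prediction,
    solve_population,
)
from .pk import (
    DoseSummary,
    PKParameters,
    compute_dose_summary,
    make_pulse_input,
    simulate_pk_forced,
)

__all__ = ["ExperimentDesign", "TruthSurfaces", "generate_pk_dataset",
           "generate_response_dataset"]

# printed response-design concentration series (nM); 0 is the control
_RESPONSE_CONCS = (0.0, 10.0, 20.0, 39.0, 78.0, 156.0, 312.0, 625.0, 1250.0, 2500.0)
# uptake design: exact two-fold series down from 2500 nM
_PK_CONCS = (312.5, 625.0, 1250.0, 2500.0)


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate design: concentrations, exposures, sampling and replication."""

    response_concentrations: tuple[float, ...] = _RESPONSE_CONCS
    response_exposures: tuple[float, ...] = (6.0, 12.0, 24.0)
    pk_concentrations: tuple[float, ...] = _PK_CONCS
    pk_exposures: tuple[float, ...] = (6.0, 12.0)
    pk_sampling_interval: float = 0.25  # hr
    pk_start: float = -1.0  # imaging begins 1 h before the bolus
    pk_end: float = 24.0
    pre_treatment_days: int = 3
    post_treatment_days: int = 30
    count_interval_hr: float = 24.0
    count_replicates: int = 6
    pk_replicates: int = 2
    n_cells_seeded_response: float = 2500.0
    n_cells_seeded_pk: float = 10000.0
    cell_volume_uL: float = 2e-6
    v_E_uL: float = 250.0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.response_concentrations):
            raise ValidationError("concentrations must be >= 0")
        if list(self.response_concentrations) != sorted(self.response_concentrations):
            raise ValidationError("concentrations must be sorted")
        if self.count_replicates < 1 or self.pk_replicates < 1:
            raise ValidationError("replicates must be >= 1")

    @property
    def v_I_uL(self) -> float:
        return self.n_cells_seeded_pk * self.cell_volume_uL

    def pk_times(self) -> np.ndarray:
        n = int(round((self.pk_end - self.pk_start) / self.pk_sampling_interval))
        return self.pk_start + self.pk_sampling_interval * np.arange(n + 1)

    def count_times(self) -> np.ndarray:
        start = -self.pre_treatment_days * 24.0
        end = self.post_treatment_days * 24.0
        n = int(round((end - start) / self.count_interval_hr))
        return start + self.count_interval_hr * np.arange(n + 1)


@dataclass(frozen=True)
class TruthSurfaces:
    """Ground-truth parameters and dose-response surfaces.

    Growth defaults follow the SUM-149PT-like profile (k_p = 2.69e-2 hr^-1,
    theta = 3.81e4 cells).  The kill-rate surfaces are Hill functions of
    C_B,max; the effect-induction rate r rises with dose; the carrying
    capacity declines mildly; and the weight of the delayed-kill variant
    w_B switches from ~1 to ~0 as C_B,max crosses ``w_switch_CBmax``.
    """

    pk: PKParameters = field(
        default_factory=lambda: PKParameters(
            k_EF=2e-3, k_FE=0.4, k_FB=0.1, v_I=0.02, v_E=250.0
        )
    )
    growth: GrowthParameters = field(
        default_factory=lambda: GrowthParameters(k_p=2.69e-2, theta=3.81e4)
    )
    k_dA_max: float = 4.5e-2
    k_dA_half: float = 2.0e4  # C_B,max (nM) at half-maximal immediate kill
    k_dB_max: float = 5.0e-2
    k_dB_half: float = 5.0e3
    hill: float = 2.0
    r_base: float = 2.0e-3
    r_max_increment: float = 2.8e-2
    r_half: float = 1.0e4
    theta_drop: float = 0.3
    theta_half: float = 5.0e4
    w_switch_CBmax: float = 6.0e4
    w_switch_slope: float = 4.0  # per decade of C_B,max
    noise_cv: float = 0.05
    # generate from a single response variant ("A" or "B") instead of the
    # weighted mixture; used for parameter-recovery studies
    force_variant: str | None = None

    def k_dA(self, cbmax: float) -> float:
        c = cbmax**self.hill
        return self.k_dA_max * c / (c + self.k_dA_half**self.hill)

    def k_dB(self, cbmax: float) -> float:
        c = cbmax**self.hill
        return self.k_dB_max * c / (c + self.k_dB_half**self.hill)

    def r(self, cbmax: float) -> float:
        return self.r_base + self.r_max_increment * cbmax / (cbmax + self.r_half)

    def theta(self, cbmax: float) -> float:
        return self.growth.theta * (1.0 - self.theta_drop * cbmax / (cbmax + self.theta_half))

    def w_B(self, cbmax: float) -> float:
        if self.force_variant == "A":
            return 0.0
        if self.force_variant == "B":
            return 1.0
        if cbmax <= 0:
            return 1.0
        x = math.log10(cbmax) - math.log10(self.w_switch_CBmax)
        return float(expit(-self.w_switch_slope * x))

    def params_at(self, cbmax: float):
        pA = ResponseParamsA(k_dA=self.k_dA(cbmax), theta=self.theta(cbmax))
        pB = ResponseParamsB(k_dB=self.k_dB(cbmax), r=self.r(cbmax), theta=self.theta(cbmax))
        return pA, pB, self.w_B(cbmax)


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative noise with the requested coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma**2)


def generate_pk_dataset(
    truth: TruthSurfaces, design: ExperimentDesign, seed: int | None = 0
) -> tuple[pd.DataFrame, dict]:
    """Uptake timecourse table: intracellular total per condition/replicate."""
    rng = np.random.default_rng(seed)
    times = design.pk_times()
    pk = PKParameters(
        k_EF=truth.pk.k_EF,
        k_FE=truth.pk.k_FE,
        k_FB=truth.pk.k_FB,
        v_I=design.v_I_uL,
        v_E=design.v_E_uL,
    )
    rows = []
    conditions = {}
    for exposure in design.pk_exposures:
        for conc in design.pk_concentrations:
            cid = f"c{conc:g}_e{exposure:g}"
            pulse = make_pulse_input(conc, exposure, design.pk_end)
            tc = simulate_pk_forced(pk, pulse, times)
            total = tc.intracellular_total
            conditions[cid] = {
                "concentration_nM": conc,
                "exposure_hr": exposure,
                "noiseless_intracellular_total": total.tolist(),
            }
            for rep in range(design.pk_replicates):
                noisy = total * _lognormal_factors(rng, truth.noise_cv, total.shape)
                for t, ce, v in zip(times, tc.C_E, noisy):
                    rows.append((t, cid, rep, "extracellular", ce, "concentration_nM"))
                    rows.append((t, cid, rep, "intracellular_total", v, "concentration_nM"))
    df = pd.DataFrame(
        rows,
        columns=["time_hr", "condition_id", "replicate", "compartment", "value",
                 "value_kind"],
    )
    record = {
        "pk": {"k_EF": pk.k_EF, "k_FE": pk.k_FE, "k_FB": pk.k_FB,
               "v_I": pk.v_I, "v_E": pk.v_E},
        "noise_cv": truth.noise_cv,
        "seed": seed,
        "conditions": conditions,
    }
    return df, record


def generate_response_dataset(
    truth: TruthSurfaces, design: ExperimentDesign, seed: int | None = 0
) -> tuple[pd.DataFrame, dict]:
    """Longitudinal count table over the full concentration x exposure grid.

    Counts follow the weighted response model: logistic pre-treatment
    growth from seeding, then the w_B-weighted mix of immediate-kill and
    delayed-kill trajectories evaluated at the truth surfaces for the
    condition's C_B,max.
    """
    rng = np.random.default_rng(seed)
    times = design.count_times()
    pre_mask = times <= 0
    post_mask = times >= 0
    pk = PKParameters(
        k_EF=truth.pk.k_EF,
        k_FE=truth.pk.k_FE,
        k_FB=truth.pk.k_FB,
        v_I=design.v_I_uL,
        v_E=design.v_E_uL,
    )
    rows = []
    conditions = {}
    for exposure in design.response_exposures:
        for conc in design.response_concentrations:
            if conc > 0:
                pulse = make_pulse_input(conc, exposure, max(2 * exposure, exposure + 24.0))
                dose = compute_dose_summary(pk, pulse)
            else:
                dose = DoseSummary(C_Bmax=0.0, AUC=0.0, concentration=0.0,
                                   exposure=exposure)
            pA, pB, wB = truth.params_at(dose.C_Bmax)
            weights = ModelWeights(w_A=1.0 - wB, w_B=wB)

            pre = solve_population(
                design.n_cells_seeded_response, truth.growth, None, None,
                times[pre_mask],
            )
            n_at_zero = pre.counts[-1]
            trajA = solve_population(n_at_zero, truth.growth, "A", pA, times[post_mask])
            trajB = solve_population(n_at_zero, truth.growth, "B", pB, times[post_mask])
            post = averaged_prediction(trajA, trajB, weights)
            # t = 0 appears in both windows; keep the single post-side value
            full = np.concatenate([pre.counts[:-1], post.counts])

            conditions[f"c{conc:g}_e{exposure:g}"] = {
                "concentration_nM": conc,
                "exposure_hr": exposure,
                "C_Bmax": dose.C_Bmax,
                "AUC": dose.AUC,
                "k_dA": pA.k_dA,
                "k_dB": pB.k_dB,
                "r": pB.r,
                "theta": pA.theta,
                "w_B": wB,
                "noiseless_counts": full.tolist(),
            }
            for rep in range(design.count_replicates):
                noisy = full * _lognormal_factors(rng, truth.noise_cv, full.shape)
                for t, v in zip(times, noisy):
                    rows.append((t, conc, exposure, rep, v))
    df = pd.DataFrame(
        rows, columns=["time_hr", "concentration_nM", "exposure_hr", "replicate", "count"]
    )
    record = {
        "growth": {"k_p": truth.growth.k_p, "theta": truth.growth.theta},
        "pk": {"k_EF": pk.k_EF, "k_FE": pk.k_FE, "k_FB": pk.k_FB,
               "v_I": pk.v_I, "v_E": pk.v_E},
        "noise_cv": truth.noise_cv,
        "seed": seed,
        "times_hr": times.tolist(),
        "conditions": conditions,
    }
    return df, record
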