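"""Stage orchestration: tables -> fits -> predictions -> artifacts.

These helpers connect the tidy tables (see :mod:`doxopkpd.io`) to the
estimators and are shared by the command-line interface, the test suite
and the reproduction script.  The full pipeline mirrors the study's
workflow: characterize drug uptake, estimate control growth, fit the
per-dose response surfaces for each exposure-time experiment, screen
parameter sensitivity, then train on one exposure time and predict the
others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .fitting import (
    CompartmentModelEstimator,
    DoseData,
    LogisticGrowthEstimator,
    PKCondition,
    ResponseFitCollection,
    fit_response_models,
)
from .growth import GrowthParameters
from .io import replicate_means, write_count_table, write_run_log, write_timecourse_table
from .pk import (
    Calibration,
    DoseSummary,
    PKParameters,
    compute_dose_summary,
    intensity_to_concentration,
    make_pulse_input,
)
from .predict import PredictionResult, TrajectoryPredictor, mean_percent_error
from .sensitivity import EfastSettings, response_sensitivity
from .synthetic import ExperimentDesign, TruthSurfaces, generate_pk_dataset, \
    generate_response_dataset

__all__ = [
    "pk_conditions_from_table",
    "fit_growth_from_counts",
    "dose_data_for_exposure",
    "train_and_predict",
    "run_pipeline",
]


def pk_conditions_from_table(
    df: pd.DataFrame,
    conditions: dict[str, tuple[float, float]],
    horizon: float,
    calibration: Calibration | None = None,
) -> list[PKCondition]:
    """Build PK fit inputs from a timecourse table.

    ``conditions`` maps each condition_id to its (concentration nM,
    exposure hr) pulse.  Replicates are averaged; intensity readings are
    converted to concentration when a calibration is supplied.
    """
    out = []
    for cid, (conc, exposure) in conditions.items():
        sub = df[(df["condition_id"] == cid) & (df["compartment"] == "intracellular_total")]
        if sub.empty:
            raise ValidationError(f"no intracellular_total rows for condition {cid}")
        if sub["value_kind"].eq("intensity_au").any():
            if calibration is None:
                raise ValidationError(f"condition {cid} has intensities but no calibration")
            sub = sub.assign(
                value=intensity_to_concentration(sub["value"].to_numpy(), calibration)
            )
        mean = sub.groupby("time_hr", as_index=False)["value"].mean()
        out.append(
            PKCondition(
                input_function=make_pulse_input(conc, exposure, horizon),
                times=mean["time_hr"].to_numpy(),
                intracellular_total=mean["value"].to_numpy(),
            )
        )
    return out


def fit_growth_from_counts(count_df: pd.DataFrame) -> LogisticGrowthEstimator:
    """k_p and theta from pre-treatment (all wells) plus control counts."""
    means = replicate_means(count_df)
    pre = means[means["time_hr"] <= 0]
    pre = pre.groupby("time_hr", as_index=False)["count"].mean()
    ctrl = means[(means["concentration_nM"] == 0) & (means["time_hr"] > 0)]
    ctrl = ctrl.groupby("time_hr", as_index=False)["count"].mean()
    data = pd.concat([pre, ctrl]).sort_values("time_hr")
    return LogisticGrowthEstimator().fit(data["time_hr"].to_numpy(), data["count"].to_numpy())


def dose_data_for_exposure(
    count_df: pd.DataFrame,
    exposure: float,
    pk_params: PKParameters,
    include_control: bool = True,
) -> list[DoseData]:
    """Post-treatment replicate-mean counts with dose summaries, one exposure."""
    means = replicate_means(count_df)
    sub = means[(means["exposure_hr"] == exposure) & (means["time_hr"] >= 0)]
    if sub.empty:
        raise ValidationError(f"no counts for exposure {exposure}")
    out = []
    for conc, g in sub.groupby("concentration_nM"):
        if conc == 0 and not include_control:
            continue
        if conc > 0:
            pulse = make_pulse_input(conc, exposure, max(2 * exposure, exposure + 24.0))
            dose = compute_dose_summary(pk_params, pulse)
        else:
            dose = DoseSummary(C_Bmax=0.0, AUC=0.0, concentration=0.0, exposure=exposure)
        g = g.sort_values("time_hr")
        out.append(DoseData(dose=dose, times=g["time_hr"].to_numpy(),
                            counts=g["count"].to_numpy()))
    return out


@dataclass
class PredictionOutcome:
    concentration: float
    exposure: float
    result: PredictionResult
    observed_times: np.ndarray
    observed_counts: np.ndarray


def train_and_predict(
    count_df: pd.DataFrame,
    train_exposure: float,
    test_exposures: list[float],
    pk_params: PKParameters,
    growth: GrowthParameters | None = None,
    alpha: float = 0.1,
    span: float = 0.5,
    **fit_kw,
) -> tuple[ResponseFitCollection, list[PredictionOutcome]]:
    """Train on one exposure-time experiment; predict the others.

    Each test condition's prediction is initialized at its first
    post-treatment replicate-mean count and scored against the observed
    replicate means (mean percent error over all timepoints and at the end
    of the experiment).
    """
    if growth is None:
        growth = fit_growth_from_counts(count_df).growth_
    train_data = dose_data_for_exposure(count_df, train_exposure, pk_params)
    training = fit_response_models(train_data, growth, train_exposure, alpha=alpha, **fit_kw)
    predictor = TrajectoryPredictor(span=span).fit(training, pk_params)

    means = replicate_means(count_df)
    outcomes = []
    for exposure in test_exposures:
        sub = means[(means["exposure_hr"] == exposure) & (means["time_hr"] >= 0)]
        for conc, g in sub.groupby("concentration_nM"):
            if conc <= 0:
                continue
            g = g.sort_values("time_hr")
            times = g["time_hr"].to_numpy()
            obs = g["count"].to_numpy()
            res = predictor.predict(conc, exposure, obs[0], times[0], times)
            res.score(obs)
            outcomes.append(
                PredictionOutcome(
                    concentration=float(conc),
                    exposure=float(exposure),
                    result=res,
                    observed_times=times,
                    observed_counts=obs,
                )
            )
    return training, outcomes


def run_pipeline(config: dict, seed: int, outdir) -> dict:
    """Full synthetic pipeline: generate, fit, screen, predict, log.

    ``config`` keys (all optional): ``design`` (ExperimentDesign overrides),
    ``truth`` (TruthSurfaces overrides), ``alpha``, ``span``,
    ``train_exposure``, ``test_exposures``, ``sensitivity_samples``.
    Deterministic for a fixed seed: all stage seeds derive from ``seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design_cfg = dict(config.get("design", {}))
    truth_cfg = dict(config.get("truth", {}))
    for key, cls in (("design", ExperimentDesign), ("truth", TruthSurfaces)):
        cfg = design_cfg if key == "design" else truth_cfg
        unknown = set(cfg) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown {key} config keys: {sorted(unknown)}")
    if "pk" in truth_cfg:
        truth_cfg["pk"] = PKParameters(**truth_cfg["pk"])
    if "growth" in truth_cfg:
        truth_cfg["growth"] = GrowthParameters(**truth_cfg["growth"])
    design = ExperimentDesign(**design_cfg)
    if "response_exposures" in design_cfg:
        design_cfg["response_exposures"] = tuple(design_cfg["response_exposures"])
    truth = TruthSurfaces(**truth_cfg)

    train_exposure = float(config.get("train_exposure", 12.0))
    test_exposures = [
        float(e) for e in config.get(
            "test_exposures",
            [e for e in design.response_exposures if e != train_exposure],
        )
    ]
    if not list(design.response_exposures):
        raise ValidationError("design must define at least one exposure time")
    if train_exposure not in design.response_exposures:
        raise ValidationError("train_exposure must be one of the design exposures")
    alpha = float(config.get("alpha", 0.1))
    span = float(config.get("span", 0.5))

    rng = np.random.default_rng(seed)
    sub_seeds = {
        "pk_data": int(rng.integers(2**31 - 1)),
        "response_data": int(rng.integers(2**31 - 1)),
        "sensitivity": int(rng.integers(2**31 - 1)),
    }
    diagnostics: dict = {}

    # synth
    pk_df, pk_truth = generate_pk_dataset(truth, design, seed=sub_seeds["pk_data"])
    count_df, resp_truth = generate_response_dataset(
        truth, design, seed=sub_seeds["response_data"]
    )
    write_timecourse_table(pk_df, outdir / "pk_timecourses.csv")
    write_count_table(count_df, outdir / "counts.csv")
    (outdir / "truth.json").write_text(
        json.dumps({"pk": pk_truth, "response": resp_truth}, indent=2, default=str)
    )

    # fit-pk
    conditions = {
        cid: (rec["concentration_nM"], rec["exposure_hr"])
        for cid, rec in pk_truth["conditions"].items()
    }
    pk_fit = CompartmentModelEstimator(v_E=design.v_E_uL, v_I=design.v_I_uL).fit(
        pk_conditions_from_table(pk_df, conditions, design.pk_end)
    )
    diagnostics["fit_pk"] = {
        "params": pk_fit.result_.params,
        "mean_percent_error": pk_fit.mean_percent_error_,
        "converged": pk_fit.converged_,
    }

    # fit-growth
    growth_fit = fit_growth_from_counts(count_df)
    diagnostics["fit_growth"] = growth_fit.result_.params

    # fit-response on the training exposure
    training, outcomes = train_and_predict(
        count_df,
        train_exposure,
        test_exposures,
        pk_fit.params_,
        growth=growth_fit.growth_,
        alpha=alpha,
        span=span,
    )
    fit_rows = []
    for f in training.fits:
        fit_rows.append(
            {
                "concentration_nM": f.dose.concentration,
                "exposure_hr": f.dose.exposure,
                "C_Bmax": f.dose.C_Bmax,
                "AUC": f.dose.AUC,
                "k_dA": f.params_A.k_dA,
                "theta_A": f.params_A.theta,
                "k_dB": f.params_B.k_dB,
                "r": f.params_B.r,
                "theta_B": f.params_B.theta,
                "w_A": f.weights.w_A,
                "w_B": f.weights.w_B,
                "AIC_A": f.fit_A.aic,
                "AIC_B": f.fit_B.aic,
            }
        )
    pd.DataFrame(fit_rows).to_csv(outdir / "response_fits.csv", index=False)

    # sensitivity on the training fits
    horizon = design.post_treatment_days * 24.0
    settings = EfastSettings(
        samples_per_curve=int(config.get("sensitivity_samples", 257))
    )
    sens = response_sensitivity(
        training, horizon, settings=settings, seed=sub_seeds["sensitivity"]
    )
    sens_rows = []
    for rec in sens:
        for variant, entry in rec["variants"].items():
            for nm, val in entry["S_TI"].items():
                sens_rows.append(
                    {
                        "concentration_nM": rec["dose"].concentration,
                        "C_Bmax": rec["dose"].C_Bmax,
                        "variant": variant,
                        "parameter": nm,
                        "S_TI": val,
                    }
                )
    pd.DataFrame(sens_rows).to_csv(outdir / "sensitivity.csv", index=False)

    # predictions + error summary (Table-1-style layout)
    pred_rows, err_rows = [], []
    for oc in outcomes:
        cid = f"c{oc.concentration:g}_e{oc.exposure:g}"
        for t, c in zip(oc.result.trajectory.times, oc.result.trajectory.counts):
            pred_rows.append(
                {"time_hr": t, "condition_id": cid, "count": c, "source": "model"}
            )
        err_rows.append(
            {
                "concentration_nM": oc.concentration,
                "exposure_hr": oc.exposure,
                "predicted_mean_percent_error": oc.result.mean_percent_error,
                "predicted_eoe_percent_error": oc.result.eoe_percent_error,
                "extrapolated": oc.result.extrapolated,
            }
        )
    pd.DataFrame(pred_rows).to_csv(outdir / "predicted_trajectories.csv", index=False)
    pd.DataFrame(err_rows).to_csv(outdir / "prediction_errors.csv", index=False)
    diagnostics["prediction"] = {
        "n_conditions": len(outcomes),
        "mean_percent_error": float(
            np.mean([oc.result.mean_percent_error for oc in outcomes])
        )
        if outcomes
        else None,
    }

    write_run_log(
        outdir / "run_log.json",
        command="run",
        config=config,
        seeds={"top_level": seed, **sub_seeds},
        diagnostics=diagnostics,
    )
    return {
        "pk_fit": pk_fit,
        "growth_fit": growth_fit,
        "training": training,
        "outcomes": outcomes,
        "sensitivity": sens,
        "outdir": outdir,
    }
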