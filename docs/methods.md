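# Methods

This note records the models, assumptions, numerical choices and known
limitations of `doxopkpd`.  Quantitative claims about accuracy are made only
where the test suite (`tests/`) or the acceptance script
(`scripts/acceptance.py`) computes them.

## 1. Drug-uptake model (`doxopkpd.pk`)

Three well-mixed compartments: extracellular drug `C_E` (volume `v_E`), free
intracellular drug `C_F` and DNA-bound intracellular drug `C_B` (both in the
pooled cell volume `v_I`).  All concentrations in nM, time in hours.

```
dC_F/dt = k_EF (v_E / v_I) C_E − (k_FE + k_FB) C_F
dC_B/dt = k_FB C_F
```

Binding to DNA is treated as irreversible (`C_B` never decreases), cells
neither grow nor die on the uptake timescale (≤ 24 h), and uptake kinetics
are linear in concentration.

Two simulation modes:

* **Forced**: `C_E(t)` is an exogenous rectangular pulse — constant
  concentration during the exposure window, exactly zero after washout.  The
  system is then linear with piecewise-constant forcing and is solved exactly
  on each segment (homogeneous + particular solution; the `k_FE + k_FB = 0`
  degenerate case is handled by its polynomial limit).
* **Closed**: `C_E` depletes as cells absorb drug.  The full 3×3 linear
  system is advanced with `scipy.linalg.expm`.  Total drug mass
  `v_E C_E + v_I (C_F + C_B)` is conserved by construction; the acceptance
  suite checks conservation to 1e-8 (observed ~5e-15) and agreement of both
  modes with an adaptive LSODA integration to a relative error of 1e-6
  (observed ~3e-11) over random parameter draws spanning three decades.

Each condition is summarised (`DoseSummary`) by `C_Bmax`, the peak bound
concentration over a horizon long enough for the free pool to drain, and the
nominal exposure `AUC = concentration × exposure time`.  The AUC identity is
exact for rectangular pulses and is asserted exactly at the design extremes
(60, 480, 1 875, 30 000, 60 000 nM·hr).

`Calibration` maps fluorescence intensity to concentration affinely; it is
kept separate from the kinetic model so image-derived data can be fed in
without touching the fitting code.

## 2. Cell-response model (`doxopkpd.growth`)

Logistic growth with a time-dependent drug-induced death rate:

```
dN/dt = (k_p − k_d(t)) N (1 − N/θ)
```

with treatment applied at `t0` (death rate is zero before `t0`).  Two
variants:

* **A** — constant death: `k_d(t) = k_dA`.
* **B** — delayed, transient death: `k_d(t) = k_dB · r s e^(1 − r s)` with
  `s = t − t0`; the rate peaks at value `k_dB` at `s = 1/r`, then decays, so
  populations can regrow.

Because `k_d` depends on time only, the ODE is separable and solved in
closed form: with `M(t) = ∫ (k_p − k_d) dt`,
`N(t) = θ · expit(logit(N0/θ) + M(t))`, using the exact kill integral
`∫ k_d ds = (k_dB e / r)(1 − e^{−rs}(1 + rs))` for variant B.  Writing the
solution through `logit`/`expit` keeps it valid above capacity (`N0 > θ`) and
numerically stable near saturation.  Agreement with adaptive integration is
checked to 1e-6 relative error; timepoints where the *oracle* has decayed
below 1e-6 × N0 are excluded, since there the adaptive integrator's absolute
tolerance, not the closed form, limits accuracy.

Assumptions: death acts multiplicatively on the logistic term (as a growth-
rate modifier, not a separate first-order loss), drug effect is fully
summarised by the per-dose parameters (no explicit intracellular
concentration driving `k_d`), and wells are independent.

## 3. Fitting (`doxopkpd.fitting`)

All estimators are sklearn-style (`fit`/`predict`, `get_params`/`set_params`,
fitted attributes with trailing underscores); `fit_pk_parameters`,
`fit_growth`, `fit_response_surface`, `fit_response_models` are thin
functional wrappers.

* **CompartmentModelEstimator** fits shared `(k_EF, k_FE, k_FB)` across all
  uptake conditions by relative least squares on total intracellular signal
  `C_F + C_B`.  Pre-drug timepoints with exactly zero signal are dropped
  (relative residuals undefined there).
* **LogisticGrowthEstimator** fits `(k_p, θ, N0)` to untreated controls.  If
  the data never approach capacity, θ is flagged non-identifiable
  (`theta_identifiable_`) rather than reported with a meaningless interval.
* **ResponseSurfaceEstimator** fits all doses of one exposure time jointly:
  pooled relative SSE plus `α ×` squared first differences of the
  (mean-|·|-scaled) parameters between concentration-adjacent doses
  (default `α = 0.1`), implemented as `√α` penalty rows so the whole problem
  stays a least-squares problem.  Per dose, the free parameters are the
  variant parameters (`k_dA` or `k_dB, r`), θ — free only where the dose
  reaches ≥ 50 % of the control capacity, otherwise fixed to the control
  value — and the initial count `N0` as a nuisance parameter.  Fitting `N0`
  (rather than pinning it to the first noisy observation) matters for
  calibration: a fixed-but-wrong `N0` pushes its error into the kill rates
  outside their reported covariance.

Optimization uses `scipy.optimize.least_squares` (trust-region reflective,
non-negativity bounds) with a few seeded multistarts.  Confidence intervals
are the standard linearization at the optimum:
`cov = s² (JᵀJ)⁻¹`, `s² = RSS/(n − p)`, t-quantile half-widths.  `JᵀJ` is
first equilibrated to correlation form (divided by its diagonal scale) before
the pseudo-inverse: raw parameters differ by up to six orders of magnitude,
and without equilibration the pseudo-inverse's relative cutoff can silently
truncate genuinely sloppy directions (e.g. the `k_d`–θ ridge) and understate
their variance.  Coverage at the pipeline's noise level (5 % lognormal CV,
replicate means of 2 uptake / 6 count wells) is measured by the acceptance
suite: ≥ 8/10 over seeded repeats for every reported parameter.

Model comparison uses `AIC = n ln(RSS/n) + 2p` on relative residuals and
Akaike weights `w_i ∝ exp(−Δ_i/2)`; the analytic cases (equal AICs → ½/½,
Δ = 2 → 0.731/0.269) are asserted to 1e-9.

## 4. Prediction (`doxopkpd.predict`)

Fitted per-dose parameters are regressed on standardized
`(log10 C_Bmax, log10 AUC)` with local-linear (LOESS-style) surfaces:
tricube weights over the `span`-nearest training points (default span 0.5,
minimum 3 points), degree-1 fit per query, falling back to the weighted mean
when the local system is singular.  Queries outside the training hull are
flagged (`is_extrapolated`), not refused.

The A-vs-B balance is carried across doses by a binomial GLM of the Akaike
weight `w_B` on the same features.  Each dose's fractional label enters with
sample weight `|AIC_A − AIC_B|` capped at 50: where both variants fit equally
well the label is ≈ 0.5 regardless of the generating model and carries no
information, so it should not drag confident doses toward indifference; the
cap stops one decisive dose from dominating.  If the weighted GLM fails to
converge or returns unbounded coefficients (separation), a ridge-stabilized
fit (`λ = 1e-2`) takes over and is recorded (`used_ridge_fallback_`).

`TrajectoryPredictor.predict(concentration, exposure, N_first, t_first, times)`
computes the condition's `DoseSummary`, interpolates parameters and weight,
and integrates both variants forward from the *first measured count* of the
target condition, returning the weight-averaged trajectory with the two
variant trajectories and extrapolation flags attached.  Accuracy is
quantified as mean percent error against noiseless truth; the acceptance
suite requires < 20 % at sub-lethal doses (immediate kill rate below `k_p`)
and within 10 percentage points of the error of a fit given full access to
the test data.  Supra-lethal doses are outside the accuracy claim: once the
population crashes to near zero, percent errors are dominated by noise.

Uncertainty bands use a residual-ratio bootstrap: multiplicative residuals
(observed/fitted, pooled per training dose) are resampled onto the fitted
curves, the whole pipeline (response fits → surfaces → weight model →
prediction) is refit per resample, and pointwise 2.5/97.5 percentiles are
reported.

## 5. Sensitivity analysis (`doxopkpd.sensitivity`)

Hand-rolled extended FAST (eFAST) total-order indices (no SALib in the
environment).  Each parameter in turn is assigned the high frequency
`ω = (Ns − 1)/(2M)` with `M = 4` interference harmonics; complementary
parameters get low frequencies ≤ `ω/(2M)`.  The search curve
`x_i = ½ + (1/π) asin(sin(ω_i s + φ_i))` is evaluated at `Ns` points
(default 257 per curve, 5 random-phase resamples averaged; settings validated
against `Ns ≥ 4M² + 1`).  `S_TI = 1 − V_complementary/V`, with variance read
off the Fourier power spectrum.  A numerically constant output
(`V ≤ 1e-20 · max(1, mean²)`) returns zero indices instead of amplifying
roundoff.  Accuracy is benchmarked on the Ishigami function against its
analytic variance decomposition: within 0.05 at 1 001 samples per curve
(observed ~0.027).

`response_sensitivity` applies this to the fitted pipeline, reporting
total-order indices of the predicted final count with respect to the response
parameters per variant.

## 6. Synthetic data generator (`doxopkpd.synthetic`)

The generator's defaults are the study conditions; they were fixed before
the acceptance outcomes were inspected and are not tuned to them.

* **Design** (`ExperimentDesign`): response doses 0, 10, 20, 39, 78, 156,
  312, 625, 1 250, 2 500 nM × 6/12/24 h exposures, counts every 24 h from
  3 days pre-treatment to 30 days post (6 replicate wells, 2 500 cells
  seeded); uptake study 312.5–2 500 nM (2-fold) × 6/12 h, sampled every
  0.25 h from −1 to 24 h (2 replicates, 10 000 cells).
* **Truth** (`TruthSurfaces`): Hill-shaped kill-rate surfaces in `C_Bmax`
  (`k_dA`: max 0.045/hr, half-point 2e4 nM, Hill 2; `k_dB`: max 0.05/hr,
  half-point 5e3 nM), rising delay rate `r`, a mild capacity drop at extreme
  doses, and a logistic A→B variant switch centred at `C_Bmax = 6e4` nM.
  Per-condition data are generated from a single variant drawn with
  probability `w_B` (`force_variant` overrides this for recovery studies).
* **Noise**: mean-one lognormal, CV 5 %, independent per well and timepoint.

Scope: the generator produces plausible in-vitro count and uptake tables for
exercising the pipeline; it is not a calibrated digital twin of any cell
line, and its truth record (noiseless counts, per-condition parameters,
seeds) exists so tests can score estimates against ground truth.

## 7. I/O and CLI (`doxopkpd.io`, `doxopkpd.cli`)

Long-format CSV tables with validated schemas (missing columns, unknown
categories, negative values, unsorted times → `SchemaError` naming the
offending column/row), YAML/JSON configs validated against known keys, and
JSON run logs carrying the command, config hash, seeds, software version and
convergence diagnostics.  The `doxopkpd` CLI exposes the pipeline
(`synth`, `fit-pk`, `fit-growth`, `fit-response`, `sensitivity`, `predict`,
`run`); every stochastic command takes `--seed` and derives all internal
seeds from it.

## 8. Numerical choices (summary)

* Closed-form solutions everywhere the models admit them; `expm` for the
  closed uptake mode; LSODA at `rtol 1e-11` only as an *oracle* in tests.
* Relative (not absolute) residuals throughout, matching multiplicative
  measurement noise.
* Trust-region-reflective least squares with bounds and seeded multistarts;
  `xtol/ftol 1e-12` where recovery to 1e-3 is asserted.
* Equilibrated (correlation-form) pseudo-inverse for linearized covariances.
* Regularization `α = 0.1` (first-difference roughness across adjacent
  doses); LOESS span 0.5; eFAST `M = 4`, 5 resamples; evidence cap 50 on
  weight-model labels; bootstrap percentile bands at 95 %.

## 9. Limitations

* Linearized confidence intervals are first-order; for strongly curved
  ridges (e.g. `k_d`–θ near capacity) they are approximate.  Coverage is
  verified empirically at the study's noise level only.
* The AUC summary uses the nominal rectangular pulse, not the realized
  intracellular exposure; conditions with equal `concentration × time` are
  identical to the surface model even though their `C_Bmax` differs.
* Parameter surfaces are local-linear in two features; with few training
  doses, extrapolation beyond the training hull is flagged but inevitably
  unreliable.
* The weight model assumes the A-vs-B balance varies smoothly (logistically)
  in the dose features; abrupt mechanism changes between adjacent doses
  would be smoothed over.
* The variance-based sensitivity indices inherit eFAST's assumptions
  (independent inputs sampled over finite ranges).
* Supra-lethal doses, where populations collapse to near zero, are excluded
  from percent-error accuracy claims; relative error is ill-conditioned
  there.
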