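# Methods

## Structural model

Unbound daptomycin follows linear two-compartment kinetics with zero-order
infusion input into the central compartment:

    dA1/dt = in(t) − (CL + Q)·A1/V1 + Q·A2/V2
    dA2/dt =          Q·A1/V1 − Q·A2/V2,      C_free = A1/V1

with elimination clearance `CL` (L/h), unbound central and peripheral
volumes `V1`, `V2` (L), and inter-compartmental clearance `Q` (L/h). The
profile is evaluated in closed form (bi-exponential infusion solution with
hybrid constants α, β; β is computed as `k10·k21/α` to avoid cancellation)
and superposed over dose events; a piecewise LSODA integration of the same
ODEs serves as an independent oracle and the two agree to ≤ 1e-6 relative.

Observed *total* serum concentrations are an instantaneous transform of the
free concentration — for the final model the single-site saturable form
`C_tot = C_f + B_max·C_f/(K_D + C_f)` with `B_max = 160 mg/L`,
`K_D = 3.56 mg/L`. The transform acts on the observation only; the
disposition dynamics stay linear in the free drug. Under this reading the
free-drug system and the printed parameter values (V1 = 0.95 L together
with CL = 6.98 L/h) are mutually coherent. The alternative reading — a
mass-balance model with an explicit bound pool whose binding alters the
dynamics — is not implemented; see Limitations.

All concentrations are mg/L and times are hours; no molar conversion.

## Population model

* `CL_i = CL · (CLCR_i / 92.8)^0.19 · exp(η_CL)`, `η_CL ~ N(0, ω_CL²)`,
  ω_CL = 0.32 (reported as 32%).
* `V2_i = V2 · exp(η_V2)`, ω_V2 = 0.47. V1 and Q carry no random effects;
  the random effects are independent (diagonal Ω).
* Residual error is additive on log concentration, σ = 0.22: observed
  `ln DV = ln Ĉ_tot + ε`, `ε ~ N(0, σ²)` — equivalently a proportional
  error of ~22% on the natural scale.
* Body weight has deliberately **no** structural effect: it enters only
  through the mg/kg dose, which is what produces the weight trends in the
  dose-selection tables.
* Creatinine clearance can be estimated from age/weight/serum creatinine by
  Cockcroft-Gault (×0.85 for women); values are used as returned, without
  body-surface renormalisation. Renal classes split at 30/60/90
  mL/min/1.73 m², boundaries assigned to the more impaired class.

## Estimation

The marginal likelihood per subject integrates the conditional log-normal
observation likelihood over the 2-D random effect. Two deterministic
approximations are provided:

* **Laplace** (default): damped Newton search for the per-subject posterior
  mode of `F(η) = −2 ln p(y|η) + η'Ω⁻¹η` (finite-difference curvature,
  step 1e-4, eigenvalue-floored damping, step cap, vectorised across
  subjects), then `OFV_i = F(η̂) + ln|Ω| + ln|H_F(η̂)/2|`.
* **Adaptive Gauss-Hermite** (cross-check): the same mode and curvature
  recentre and rescale a tensor Gauss-Hermite rule (default 5 nodes/dim).

On three-subject toy sets both agree with a dense 81×81 brute-force
quadrature of the integral (Laplace within 0.5, AGH within 0.05 — checked
in the test suite). When an ω is zero that dimension is dropped exactly, so
the Ω→0 limit reproduces the η=0 likelihood.

The outer problem maximises the summed marginal likelihood over
log-transformed parameters (the covariate exponent stays on the natural
scale) with L-BFGS-B, forward-difference gradients (step 1e-5), and a
relative-OFV-change stopping rule of 1e-6; the default is three
log-normally jittered starts (SD 0.2) keeping the best OFV. A central
difference scheme (`fd_scheme="3-point"`) is available for stiff,
nearly-noise-free problems. Standard errors come from the central
finite-difference Hessian of the OFV (covariance `2 H⁻¹`); %RSE of a
log-estimated parameter is 100·SE(log). Eta-shrinkage is
`100·(1 − SD(EBE)/ω)` over subjects with observations. Nested models are
compared by ΔOFV against the conventional two-decimal χ² cutoffs (3.84 at
df = 1). The nonparametric bootstrap resamples subjects with replacement,
refits with independent per-replicate seed substreams, and reports
2.5/50/97.5 percentiles of converged replicates. Observations below the
0.027 mg/L limit of detection are excluded from the likelihood and flagged
`MDV=1` in datasets (all TDM concentrations sit orders of magnitude above
the limit, so no censored-data machinery is warranted).

### Identifiability of the binding parameters

With only total concentrations observed, the parameter family
`(c·CL, c·V1, c·Q, c·V2, B_max, K_D/c)` changes predictions solely through
the unbound share of the total — 2–5% at the fitted parameters — and a
joint adjustment of `B_max`/`K_D` absorbs most of the remainder. The profile
likelihood of `K_D` is flat to ~2 OFV units across a 30-fold range, i.e.
the free-concentration *scale* is practically non-identified at a 22%
residual error. Consequences:

* Point estimates of CL, V1, Q, V2, B_max and especially K_D from a single
  46-patient study scatter far beyond their nominal standard errors; ratios
  and shapes (the saturation knee in *observed* units, the covariate
  exponent, the ω's and σ) are well identified.
* On a flat profile every stopping rule retains starting-value information;
  a more aggressive optimiser travels further along the ridge while
  improving the OFV negligibly. The package reports the plain maximum of
  the approximated likelihood and does not regularise.
* The recovery checks therefore use the median estimate across replicate
  simulated studies, and the binding dissociation constant is the least
  reproducible quantity of the analysis.

## Synthetic study generator

The generator emulates a 46-patient adult TDM cohort: log-normal weight
(median 75 kg, IQR 65–85) and CLCR (median 93, IQR 50–136, truncated
≥ 15 mL/min/1.73 m²), truncated-normal age (median 68, IQR 59–81, bounds
18–100) and albumin (median 2.9, IQR 2.4–3.4 g/dL), 93% male, statin
co-administration 30% (a round prevalence typical of such cohorts; the
source table does not report one), log-normal mg/kg dose (median 9.1, IQR
7.5–10.0, clipped to 4–12). Log-normal/normal parameters are back-solved
from the target median and IQR. Marginals are independent; a weight-CLCR
correlation hook exists but defaults to zero. Height and serum creatinine
are generated for completeness and carried through the dataset files but
unused by the model.

Each subject receives four q24h 30-minute infusions (steady state by
explicit superposition, not a steady-state shortcut) and five scheduled
samples in the fourth interval: pre-dose at 72 h, 0.5 h after the infusion
ends, one draw uniform in each of the 1–2 h and 4–10 h post-infusion
windows, and a trough at 96 h. Independent per-sample retention of 157/230
makes the expected observation count 157. Observed values are the model
totals times `exp(ε)`, censored below 0.027 mg/L, and rounded to 6
significant digits (the file-format precision), so regeneration under the
same seed is byte-identical.

What the generator does **not** emulate: correlated covariates, dose
adjustments during therapy, occasion-to-occasion variability, dropout that
depends on the patient, assay-specific error structure, or pathogen/MIC
distributions. Passing tests demonstrate the machinery is correct under
the stated statistical model, not that real data behave this way.

## Monte Carlo dose optimisation

Exposure metrics are computed on model-predicted concentrations without
residual error (the standard PTA convention): unbound AUC over 0–24 h after
the first dose by exact term-wise integration of the bi-exponential
solution; total AUC over the same window by composite trapezoid (step
0.05 h, ten-fold refined across infusion ramps — refining to 0.01 h moves
the result by ~0.01%); troughs as total concentrations at 24 h and at the
end of the first dosing interval. The dose-selection default uses the
end-of-interval trough (the literal "trough"); the 24-h convention is
available as a switch. For q48h regimens the AUC window remains 0–24 h
after the first dose; the efficacy targets are fAUC ≥ 59 (bacteriostatic)
and ≥ 107.5 mg·h/L (bactericidal) — fixed constants; the package does not
re-derive them from the total-AUC references 465/666/761 mg·h/L, though
`auc_fauc_curve` exposes the mapping as a diagnostic.

Scenario simulations draw η pairs per virtual subject at a fixed CLCR and
weight; all scenarios of a grid reuse the same random stream (common random
numbers), which makes PTA exactly non-decreasing in dose and non-increasing
in MIC, and the trough-safety probability exactly non-decreasing in dose
and non-increasing in CLCR, at any Monte Carlo size. The published design
uses n = 10,000 per scenario; package defaults use n = 2,000 for dose
selection and the tests use n = 500, sizes chosen to keep the checks quick
while leaving the binomial error of a 90% PTA estimate near one percentage
point. `select_dose` returns the minimal grid dose with PTA ≥ 90% and
trough risk ≤ 20%; if none attains, the best-PTA dose under the safety cap,
flagged as not attained.

## Diagnostics

* **GOF residuals**: PRED at η = 0, IPRED at the empirical Bayes η̂;
  residuals and weighted residuals on the log scale (matching the error
  model).
* **pc-VPC**: quantile bins (default 6) on time-after-dose; observed and
  simulated values are corrected by the bin-median population prediction —
  multiplicative on the concentration scale, additive on the log scale.
  Bands are the 2.5–97.5 percentile envelope of each percentile across
  simulated replicates of the observed design. With ~25 observations per
  bin the median-in-band coverage of a correctly specified model is ~93%
  (discreteness of small-sample percentiles), reaching the nominal 95% at
  larger cohorts; the calibration test pools bins over replicate studies
  accordingly.
* **NPDE**: per subject, simulated replicate vectors are decorrelated (log
  scale) with the simulated mean and Cholesky factor (ridge 1e-8 on
  degenerate covariances); observed coordinates are ranked among simulated
  ones, ties broken by seeded uniform jitter, extreme ranks clipped by half
  a rank, then inverse-normal transformed.

## Numerical and degenerate-input conventions

Quadratic inverse of the single-site transform uses the
cancellation-stable root form; multi-site inversion brackets on [0, C_tot]
(Brent, rtol 1e-12). Zero-dose or pre-first-dose predictions are exactly
zero; a non-positive prediction at an observation renders that parameter
point's likelihood infinite rather than raising during a search. Dose
events with zero padding rates contribute nothing, letting ragged cohorts
share one padded array. Optimizer exploration is clamped (`exp` arguments
capped) so overflow cannot poison a fit. Every stochastic routine takes an
explicit seed; bootstrap replicates use `SeedSequence(seed, spawn_key=rep)`.

## Limitations

* The free-concentration scale (hence K_D and the absolute magnitudes of
  CL, V1, Q, V2) is practically non-identified from total-only data, as
  quantified above; fitted values should be read jointly, not singly.
* The mass-balance binding variant, covariates on V1/Q/binding, correlated
  random effects, between-occasion variability, dialysis, and non-IV routes
  are out of scope.
* The pc-VPC offers no covariate stratification; bands use the
  percentile-of-percentiles approach only.
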