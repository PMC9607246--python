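# daptopk

Population pharmacokinetic/pharmacodynamic modelling and dose optimisation of
**daptomycin**, for pharmacometricians and infectious-disease modellers who
need to pick safe, effective dosing regimens across renal function and body
weight.

Daptomycin is a concentration-dependent lipopeptide antibiotic against
Gram-positive organisms (including MRSA) whose efficacy tracks the unbound
exposure-to-potency ratio fAUC/MIC and whose muscle toxicity (CPK elevation)
tracks trough concentrations. It is ~90% bound to plasma proteins, and the
binding **saturates** at therapeutic concentrations, so unbound exposure grows
more than proportionally with dose. This package implements the full analysis
chain around that fact:

* **Binding models** — linear (`C_tot = C_f (1 + K_b)`), single-site saturable
  (`C_tot = C_f + B_max C_f / (K_D + C_f)`), and multi-site, with exact
  inverses.
* **Free-drug two-compartment kinetics** — closed-form bi-exponential infusion
  solution (parameters CL, V1, Q, V2 of the unbound drug) superposed over
  arbitrary infusion schedules, with an independent ODE evaluator; observed
  total serum concentrations are the binding transform of the free profile.
* **Population model** — log-normal inter-individual variability on CL and V2,
  a power covariate of creatinine clearance on clearance
  (`CL_i = CL (CLCR_i / 92.8)^0.19 e^eta`), additive residual error on log
  concentration.
* **Estimation** — nonlinear mixed-effects by per-subject Laplace
  approximation (adaptive Gauss–Hermite as a cross-check), OFV-based
  likelihood-ratio model comparison (3.84 at df = 1), covariate scanning,
  nonparametric bootstrap, standard errors and eta-shrinkage.
* **Diagnostics** — goodness-of-fit residuals, prediction-corrected visual
  predictive checks, normalised prediction distribution errors.
* **Monte Carlo dose optimisation** — probability of target attainment
  (fAUC/MIC ≥ 59 bacteriostatic / ≥ 107.5 bactericidal), trough-safety
  probability (total C_min ≥ 24.3 mg/L), and minimal-dose selection
  (PTA ≥ 90% with ≤ 20% trough risk) over CLCR × weight × regimen grids
  (5–12 mg/kg q12h/q24h, 10–17 mg/kg q48h).
* **Synthetic data** — a generator that emulates the 46-patient steady-state
  TDM study design (5 samples in the fourth dosing interval, ~157
  observations), so the whole pipeline is testable without clinical data.

## Worked example

```python
import daptopk as d

pm = d.final_model()          # published population estimates

# first-dose exposure of the typical 75 kg patient on 9 mg/kg q24h
m = d.exposure_metrics(pm.typical, pm.binding, d.Regimen(9.0, 24.0), 75.0)
print(m.auc_total_0_24, m.fauc_0_24, m.cmin_trough)

# minimal safe q48h dose for a 100 kg patient with normal renal function
# against an MRSA strain with MIC 1 mg/L (bactericidal target)
sel = d.select_dose(pm, clcr=90.0, weight=100.0, regimen_family="q48h",
                    mic=1.0, n=2000, seed=1)
print(sel)
```

prints

```
typical 75 kg patient, 9 mg/kg q24h (first dose):
  total AUC(0-24) = 834.4 mg.h/L
  unbound AUC(0-24) = 92.9 mg.h/L
  trough (24 h)     = 11.89 mg/L
q48h, 100 kg, CLCR 90, MIC 1 mg/L -> 12 mg/kg (PTA 92.5%, trough-risk 1.8%, attained=True)
```

The unbound AUC is ~11% of the total here, and that fraction *rises* with
dose — the saturable-binding effect that makes total-exposure dose selection
misleading. The 12 mg/kg q48h recommendation says: with that dose, ≥ 90% of
simulated 100 kg patients with CLCR 90 reach a bactericidal unbound exposure
against an MIC 1 mg/L strain, while fewer than 2% ever cross the 24.3 mg/L
trough level linked to CPK elevation.

A command-line interface mirrors the library:

```sh
daptopk generate --n 46 --seed 1 --out study.csv
daptopk fit --data study.csv --out fit
daptopk vpc --data study.csv --out vpc.csv --plot vpc.svg
daptopk simulate --n 10000 --out pta_grid.csv
daptopk select-dose --family q48h --mic 1 --out doses.csv
```

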