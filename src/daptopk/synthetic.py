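"""Synthetic cohort and TDM dataset generation.

Emulates a 46-patient adult cohort on daptomycin therapeutic drug
monitoring: mostly male, median weight 75 kg, wide renal-function range
(median CLCR 93 mL/min/1.73 m2, down to severe impairment), doses 4-12
mg/kg as 30-min q24h infusions, and a sparse 5-sample steady-state sampling
day (pre-dose, 0.5 h post infusion end, one sample in each of the 1-2 h and
4-10 h post-infusion windows, and a final pre-next-dose trough).  Random
per-sample retention thins the schedule so the expected number of
observations matches the ~157 seen in such a study.

Continuous covariates are drawn from log-normal (or truncated normal)
distributions whose parameters are back-solved from target medians and
interquartile ranges; covariate marginals are independent (an optional
weight-CLCR correlation hook exists but defaults to zero).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .dataio import Observation, StudyDataset, SubjectRecord
from .pk import DoseEvent
from .population import PopulationModel, SubjectCovariates
from .reference import LLOQ

__all__ = ["CohortSpec", "DesignSpec", "generate_cohort", "generate_dataset"]

_Z75 = 0.6744897501960817   # standard normal 75th percentile


def _lognormal_from_median_iqr(median: float, q1: float, q3: float) -> Tuple[float, float]:
    """(mu, sigma) of a log-normal with the requested median and IQR."""
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * _Z75)
    return mu, sigma


def _normal_from_median_iqr(median: float, q1: float, q3: float) -> Tuple[float, float]:
    return median, (q3 - q1) / (2.0 * _Z75)


@dataclass(frozen=True)
class CohortSpec:
    """Target marginal distributions for the virtual cohort.

    Medians and interquartile ranges follow the study population the
    generator emulates; truncation bounds keep draws physiological.
    """

    n_subjects: int = 46
    weight_median: float = 75.0
    weight_iqr: Tuple[float, float] = (65.0, 85.0)
    clcr_median: float = 93.0
    clcr_iqr: Tuple[float, float] = (50.0, 136.0)
    clcr_min: float = 15.0
    age_median: float = 68.0
    age_iqr: Tuple[float, float] = (59.0, 81.0)
    age_bounds: Tuple[float, float] = (18.0, 100.0)
    albumin_median: float = 2.9
    albumin_iqr: Tuple[float, float] = (2.4, 3.4)
    height_median: float = 1.7
    height_iqr: Tuple[float, float] = (1.6, 1.7)
    scr_median: float = 0.9
    scr_iqr: Tuple[float, float] = (0.6, 1.3)
    p_male: float = 0.93
    p_statin: float = 0.30
    dose_per_kg_median: float = 9.1
    dose_per_kg_iqr: Tuple[float, float] = (7.5, 10.0)
    dose_per_kg_bounds: Tuple[float, float] = (4.0, 12.0)
    weight_clcr_corr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        if not -1.0 < self.weight_clcr_corr < 1.0:
            raise ValueError("weight_clcr_corr must be in (-1, 1)")


@dataclass(frozen=True)
class DesignSpec:
    """Dosing and sampling design of the TDM day.

    Four q24h doses are simulated explicitly (steady state is reached by
    superposition, not by a steady-state shortcut) and the five samples sit
    in the fourth dosing interval: pre-dose at 72 h, 0.5 h after the
    infusion ends, one draw uniform in each of the 1-2 h and 4-10 h
    post-infusion windows, and a trough just before the next dose at 96 h.
    ``retention`` thins each scheduled sample independently; the default
    157/230 makes the expected total observation count 157 for 46 subjects.
    """

    interval: float = 24.0
    n_doses: int = 4
    infusion_duration: float = 0.5
    window_1_2: Tuple[float, float] = (1.0, 2.0)
    window_4_10: Tuple[float, float] = (4.0, 10.0)
    retention: float = 157.0 / 230.0

    def __post_init__(self) -> None:
        if not 0 < self.retention <= 1:
            raise ValueError("retention must be in (0, 1]")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def sampling_interval_start(self) -> float:
        return (self.n_doses - 1) * self.interval


def _truncated(draw, lo: float, hi: float, rng: np.random.Generator,
               max_tries: int = 1000) -> float:
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    raise RuntimeError("unsatisfiable truncation bounds")


def generate_cohort(spec: CohortSpec) -> List[SubjectCovariates]:
    """Draw a virtual cohort; reproducible for the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    mu_wt, sd_wt = _lognormal_from_median_iqr(spec.weight_median, *spec.weight_iqr)
    mu_cr, sd_cr = _lognormal_from_median_iqr(spec.clcr_median, *spec.clcr_iqr)
    mu_age, sd_age = _normal_from_median_iqr(spec.age_median, *spec.age_iqr)
    mu_alb, sd_alb = _normal_from_median_iqr(spec.albumin_median, *spec.albumin_iqr)
    mu_ht, sd_ht = _normal_from_median_iqr(spec.height_median, *spec.height_iqr)
    mu_scr, sd_scr = _lognormal_from_median_iqr(spec.scr_median, *spec.scr_iqr)
    rho = spec.weight_clcr_corr

    cohort = []
    for _ in range(spec.n_subjects):
        z_wt = rng.standard_normal()
        z_cr = rho * z_wt + math.sqrt(1 - rho ** 2) * rng.standard_normal()
        weight = math.exp(mu_wt + sd_wt * z_wt)
        clcr = math.exp(mu_cr + sd_cr * z_cr)
        if clcr < spec.clcr_min:   # truncate by redraw, keeping the correlation hook
            clcr = _truncated(lambda r: math.exp(mu_cr + sd_cr * r.standard_normal()),
                              spec.clcr_min, math.inf, rng)
        age = _truncated(lambda r: mu_age + sd_age * r.standard_normal(),
                         *spec.age_bounds, rng)
        albumin = _truncated(lambda r: mu_alb + sd_alb * r.standard_normal(),
                             1e-6, math.inf, rng)
        cohort.append(SubjectCovariates(
            weight=weight,
            clcr=clcr,
            age=age,
            albumin=albumin,
            sex="M" if rng.random() < spec.p_male else "F",
            statin=bool(rng.random() < spec.p_statin),
            height=mu_ht + sd_ht * rng.standard_normal(),
            serum_creatinine=math.exp(mu_scr + sd_scr * rng.standard_normal()),
        ))
    return cohort


def generate_dataset(
    cohort: List[SubjectCovariates],
    design: DesignSpec,
    pm: PopulationModel,
    seed: int = 0,
    dose_per_kg: np.ndarray | None = None,
    spec: CohortSpec | None = None,
) -> StudyDataset:
    """Simulate a TDM dataset for a cohort under a population model.

    Per subject: draw the mg/kg dose (log-normal, clipped to the allowed
    range), the random effects, simulate total concentrations at the
    sampled design times, multiply by log-normal residual error, censor
    below the 0.027 mg/L limit of detection, and round the recorded values
    to 6 significant digits (the written-file precision).  Byte-identical
    datasets result from identical seeds.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(seed)
    mu_d, sd_d = _lognormal_from_median_iqr(spec.dose_per_kg_median,
                                            *spec.dose_per_kg_iqr)
    t0_sample = design.sampling_interval_start
    t_inf_end = t0_sample + design.infusion_duration
    subjects = []
    for i, cov in enumerate(cohort):
        if dose_per_kg is not None:
            dpk = float(dose_per_kg[i])
        else:
            dpk = float(np.clip(math.exp(mu_d + sd_d * rng.standard_normal()),
                                *spec.dose_per_kg_bounds))
        amount = dpk * cov.weight
        doses = tuple(
            DoseEvent(k * design.interval, amount, design.infusion_duration)
            for k in range(design.n_doses)
        )
        sched = [
            t0_sample,                                       # pre-dose trough
            t_inf_end + 0.5,                                 # 0.5 h post infusion
            t_inf_end + rng.uniform(*design.window_1_2),
            t_inf_end + rng.uniform(*design.window_4_10),
            t0_sample + design.interval,                     # pre-next-dose
        ]
        keep = rng.random(len(sched)) < design.retention
        times = sorted(t for t, k in zip(sched, keep) if k)

        eta_cl = rng.normal(0.0, pm.omega_cl)
        eta_v2 = rng.normal(0.0, pm.omega_v2)
        obs = []
        if times:
            from .population import individual_params
            from .pk import total_profile

            sp = individual_params(pm, cov, eta_cl, eta_v2)
            pred = total_profile(sp, pm.binding, list(doses), np.asarray(times))
            eps = rng.normal(0.0, pm.sigma, size=len(times))
            dv = pred * np.exp(eps)
            for t, v in zip(times, dv):
                if v < LLOQ:
                    obs.append(Observation(time=float(t), dv=0.0, below_lloq=True))
                else:
                    obs.append(Observation(time=float(t),
                                           dv=float(f"{v:.6g}")))
        subjects.append(SubjectRecord(
            id=str(i + 1), covariates=cov, doses=doses, observations=tuple(obs),
        ))
    provenance = json.dumps({"generator": "daptopk.synthetic",
                             "seed": seed,
                             "n_subjects": len(cohort)}, sort_keys=True)
    return StudyDataset(subjects=tuple(subjects), provenance=provenance)
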