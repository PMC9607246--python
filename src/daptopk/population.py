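"""Population model: typical values, covariates and random effects.

The population model maps typical structural parameters plus a subject's
covariates and log-normal random effects onto individual disposition
parameters.  In the final daptomycin model:

* clearance scales with renal function through a power function of
  creatinine clearance centered at the cohort reference
  (``CL_i = CL * (CLCR_i / 92.8)**0.19 * exp(eta_CL)``),
* the peripheral volume carries the second random effect
  (``V2_i = V2 * exp(eta_V2)``),
* V1 and Q stay at their typical values, and
* body weight has no structural effect — it enters only through the
  mg/kg dose.

Residual variability is additive on the log-concentration scale
(equivalently, proportional on the natural scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binding import BindingParameters
from .pk import StructuralParameters

__all__ = [
    "PopulationModel",
    "SubjectCovariates",
    "individual_params",
    "sample_etas",
    "cockcroft_gault",
    "renal_category",
]


@dataclass(frozen=True)
class PopulationModel:
    """Population-level parameters of the free-drug daptomycin model.

    ``omega_cl`` / ``omega_v2`` are standard deviations of the log-normal
    random effects (the conventional "%CV" report is 100x these values for
    small omega); ``sigma`` is the additive residual SD on log
    concentration.
    """

    typical: StructuralParameters
    binding: BindingParameters
    clcr_exponent: float = 0.19
    clcr_reference: float = 92.8
    omega_cl: float = 0.0
    omega_v2: float = 0.0
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_v2 < 0:
            raise ValueError("omega values must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.clcr_reference <= 0:
            raise ValueError("clcr_reference must be > 0")


@dataclass(frozen=True)
class SubjectCovariates:
    """Covariates of one subject; weight (kg) and CLCR (mL/min/1.73 m2) are
    the ones the final model uses."""

    weight: float
    clcr: float
    age: float = 68.0
    albumin: float = 2.9
    sex: str = "M"
    statin: bool = False
    height: Optional[float] = None
    serum_creatinine: Optional[float] = None

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.clcr <= 0:
            raise ValueError("clcr must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


def clcr_multiplier(pm: PopulationModel, clcr: float) -> float:
    """Power-function covariate multiplier on clearance; 1 at the reference."""
    if clcr <= 0:
        raise ValueError("clcr must be > 0")
    return float((clcr / pm.clcr_reference) ** pm.clcr_exponent)


def individual_params(
    pm: PopulationModel,
    cov: SubjectCovariates,
    eta_cl: float = 0.0,
    eta_v2: float = 0.0,
) -> StructuralParameters:
    """Individual structural parameters given covariates and random effects."""
    mult = clcr_multiplier(pm, cov.clcr)
    return StructuralParameters(
        CL=pm.typical.CL * mult * float(np.exp(eta_cl)),
        V1=pm.typical.V1,
        Q=pm.typical.Q,
        V2=pm.typical.V2 * float(np.exp(eta_v2)),
    )


def sample_etas(pm: PopulationModel, n: int, seed) -> np.ndarray:
    """Draw ``n`` independent (eta_CL, eta_V2) pairs, shape (n, 2).

    Zero-mean normals with SDs (omega_cl, omega_v2) and diagonal covariance;
    bitwise reproducible for a given seed (or an already-constructed
    ``numpy.random.Generator``).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    etas = rng.standard_normal((n, 2))
    etas[:, 0] *= pm.omega_cl
    etas[:, 1] *= pm.omega_v2
    return etas


def cockcroft_gault(age: float, weight: float, serum_creatinine: float, sex: str) -> float:
    """Cockcroft-Gault creatinine clearance estimate, mL/min.

    ``((140 - age) * weight) / (72 * Scr)``, times 0.85 for females.  No
    body-surface normalization is applied.  Age 140 gives the formula zero;
    ages beyond that are rejected.
    """
    if age > 140:
        raise ValueError("age must be <= 140 years")
    if age < 0 or weight <= 0 or serum_creatinine <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    clcr = (140.0 - age) * weight / (72.0 * serum_creatinine)
    if sex == "F":
        clcr *= 0.85
    elif sex != "M":
        raise ValueError("sex must be 'M' or 'F'")
    return clcr


def renal_category(clcr: float) -> str:
    """Renal-function class from CLCR with thresholds at 30/60/90.

    Boundary values go to the lower-impairment class: 90 -> 'mild',
    60 -> 'moderate', 30 -> 'severe'.
    """
    if clcr < 0:
        raise ValueError("clcr must be >= 0")
    if clcr > 90:
        return "normal"
    if clcr > 60:
        return "mild"
    if clcr > 30:
        return "moderate"
    return "severe"
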