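"""Plasma protein binding transforms for daptomycin.

Daptomycin is highly (~90%) bound to plasma proteins, mainly albumin.  At
therapeutic concentrations the binding sites begin to saturate, so the
relationship between unbound ("free") and total serum concentration is
nonlinear.  This module provides the forward map (free -> total) and its
inverse for three binding models:

``linear``
    ``Ctotal = Cfree * (1 + Kb)`` — bound concentration proportional to free;
    no saturation.
``single_site``
    ``Ctotal = Cfree + Bmax * Cfree / (KD + Cfree)`` — one saturable site
    class with capacity ``Bmax`` (mg/L) and dissociation constant ``KD``
    (mg/L).
``multi_site``
    ``Ctotal = Cfree + sum_i Bmax_i * Cfree / (KD_i + Cfree)`` — several
    independent saturable site classes.

All concentrations are in mg/L (mass units throughout; no molar conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "BindingKind",
    "BindingParameters",
    "total_from_free",
    "free_from_total",
    "unbound_fraction",
]


class BindingKind(str, Enum):
    """Kind of protein-binding model."""

    LINEAR = "linear"
    SINGLE_SITE = "single_site"
    MULTI_SITE = "multi_site"


@dataclass(frozen=True)
class BindingParameters:
    """Parameters of a plasma protein binding model.

    Parameters
    ----------
    kind : BindingKind
        Which binding model the parameters describe.
    Kb : float
        Dimensionless binding proportionality constant (``linear`` only).
    sites : tuple of (Bmax, KD) pairs
        Saturable site classes, mg/L each.  ``single_site`` has exactly one
        entry; ``multi_site`` at least two.
    """

    kind: BindingKind
    Kb: float = 0.0
    sites: Tuple[Tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        kind = BindingKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "sites", tuple(tuple(s) for s in self.sites))
        if self.Kb < 0:
            raise ValueError("Kb must be >= 0")
        for bmax, kd in self.sites:
            if bmax <= 0 or kd <= 0:
                raise ValueError("all Bmax_i and KD_i must be > 0")
        if kind is BindingKind.LINEAR and self.sites:
            raise ValueError("linear binding takes no saturable sites")
        if kind is BindingKind.SINGLE_SITE and len(self.sites) != 1:
            raise ValueError("single_site binding requires exactly one site")
        if kind is BindingKind.MULTI_SITE and len(self.sites) < 2:
            raise ValueError("multi_site binding requires at least two sites")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def linear(cls, Kb: float) -> "BindingParameters":
        return cls(kind=BindingKind.LINEAR, Kb=Kb)

    @classmethod
    def single_site(cls, bmax: float, kd: float) -> "BindingParameters":
        return cls(kind=BindingKind.SINGLE_SITE, sites=((bmax, kd),))

    @classmethod
    def multi_site(cls, sites: Sequence[Tuple[float, float]]) -> "BindingParameters":
        return cls(kind=BindingKind.MULTI_SITE, sites=tuple(sites))

    @property
    def total_capacity(self) -> float:
        """Sum of Bmax over all saturable sites (mg/L); 0 for linear."""
        return float(sum(b for b, _ in self.sites))


def total_from_free(cfree, bp: BindingParameters):
    """Total serum concentration for a given unbound concentration.

    Accepts scalars or arrays; strictly increasing in ``cfree``.  The bound
    fraction never exceeds the total capacity ``sum(Bmax_i)``.
    """
    cfree_arr = np.asarray(cfree, dtype=float)
    if np.any(cfree_arr < 0):
        raise ValueError("cfree must be >= 0")
    if bp.kind is BindingKind.LINEAR:
        total = cfree_arr * (1.0 + bp.Kb)
    else:
        bound = np.zeros_like(cfree_arr)
        for bmax, kd in bp.sites:
            bound = bound + bmax * cfree_arr / (kd + cfree_arr)
        total = cfree_arr + bound
    if np.isscalar(cfree) or np.ndim(cfree) == 0:
        return float(total)
    return total


def _free_single_site(ctotal: np.ndarray, bmax: float, kd: float) -> np.ndarray:
    # Positive root of Cf^2 + (KD + Bmax - Ct) Cf - KD Ct = 0, written in the
    # numerically stable form that avoids cancellation when b > 0.
    b = kd + bmax - ctotal
    disc = np.sqrt(b * b + 4.0 * kd * ctotal)
    with np.errstate(divide="ignore", invalid="ignore"):
        stable = np.where(b > 0, 2.0 * kd * ctotal / (b + disc), (disc - b) / 2.0)
    return np.where(ctotal == 0.0, 0.0, stable)


def free_from_total(ctotal, bp: BindingParameters):
    """Unbound concentration given a total concentration (inverse transform).

    The single-site inverse is closed-form (positive quadratic root); the
    multi-site inverse is found by bracketed root finding on the monotone
    forward map to 1e-12 relative tolerance.  Round-trips with
    :func:`total_from_free`.
    """
    ctotal_arr = np.asarray(ctotal, dtype=float)
    if np.any(ctotal_arr < 0):
        raise ValueError("ctotal must be >= 0")
    if bp.kind is BindingKind.LINEAR:
        free = ctotal_arr / (1.0 + bp.Kb)
    elif bp.kind is BindingKind.SINGLE_SITE:
        (bmax, kd), = bp.sites
        free = _free_single_site(ctotal_arr, bmax, kd)
    else:
        def solve_one(ct: float) -> float:
            if ct == 0.0:
                return 0.0
            f = lambda x: total_from_free(x, bp) - ct
            # free <= total always, so [0, ct] brackets the root
            return brentq(f, 0.0, ct, rtol=1e-12, xtol=1e-300)

        free = np.vectorize(solve_one, otypes=[float])(ctotal_arr)
    if np.isscalar(ctotal) or np.ndim(ctotal) == 0:
        return float(free)
    return free


def unbound_fraction(cfree, bp: BindingParameters):
    """Unbound fraction Cfree / Ctotal at a given free concentration.

    Constant (``1/(1+Kb)``) for linear binding; strictly increasing in
    ``cfree`` for saturable models, approaching 1 as binding saturates.
    """
    cfree_arr = np.asarray(cfree, dtype=float)
    if np.any(cfree_arr <= 0):
        raise ValueError("cfree must be > 0")
    frac = cfree_arr / total_from_free(cfree_arr, bp)
    if np.isscalar(cfree) or np.ndim(cfree) == 0:
        return float(frac)
    return frac
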