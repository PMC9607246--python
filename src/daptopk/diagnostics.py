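"""Model diagnostics: goodness-of-fit residuals, pc-VPC and NPDE.

All simulation-based diagnostics replay the observed design (same subjects,
doses, covariates and sampling times) under the candidate population model:
random effects and residual error are redrawn per replicate, so the observed
data can be compared with what the model says data like these should look
like.

The prediction-corrected VPC normalises each observation (and each
simulated value) by the ratio of the bin-median population prediction to
that observation's own population prediction — multiplicative on the
concentration scale, i.e. additive on the log scale, matching the
log-additive error model.  This removes the spread caused by different
mg/kg doses and covariates, which would otherwise blur the percentile
bands of a TDM dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import StudyDataset
from .estimation import FitResult, _CohortEngine, _model_to_params
from .population import PopulationModel

__all__ = ["VpcBin", "VpcResult", "gof_residuals", "pc_vpc", "npde"]


def _flat_engine(ds: StudyDataset, pm: PopulationModel):
    """Engine plus flattened views of the quantifiable observations."""
    engine = _CohortEngine(ds, pm.clcr_reference)
    mask = engine.obs_mask
    subj_idx, obs_idx = np.nonzero(mask)
    times = engine.obs_time[mask]
    lndv = engine.lndv[mask]
    # time after the most recent dose at or before the sample
    tad = np.empty_like(times)
    for k, (i, t) in enumerate(zip(subj_idx, times)):
        starts = engine.dose_start[i][engine.dose_rate[i] > 0]
        prior = starts[starts <= t]
        tad[k] = t - prior.max() if prior.size else t
    return engine, subj_idx, times, tad, lndv


def _simulate_lnobs(engine, p, pm: PopulationModel, n_sim: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Simulated log total concentrations, shape (n_sim, S, O)."""
    S = engine.S
    etas = rng.standard_normal((n_sim, S, 2))
    etas[..., 0] *= pm.omega_cl
    etas[..., 1] *= pm.omega_v2
    lnpred = engine._ln_total(p, etas)
    eps = rng.standard_normal(lnpred.shape) * pm.sigma
    return lnpred + eps


def gof_residuals(ds: StudyDataset, fit: FitResult) -> pd.DataFrame:
    """Per-observation goodness-of-fit table.

    PRED is the population prediction (random effects at zero), IPRED the
    individual prediction at the empirical Bayes etas; residuals and
    weighted residuals are on the log scale, consistent with the additive
    log-scale error model.
    """
    pm = fit.estimates
    p = _model_to_params(pm)
    if fit.cov_coef is not None:
        p["cov_coef"] = fit.cov_coef
    engine, subj_idx, times, tad, lndv = _flat_engine(ds, pm)
    zeros = np.zeros((engine.S, 2))
    ln_pred = engine._ln_total(p, zeros)
    eta = np.array([fit.ebe[sid] for sid in engine.ids])
    ln_ipred = engine._ln_total(p, eta)
    sigma = pm.sigma
    pred = np.exp(ln_pred[engine.obs_mask])
    ipred = np.exp(ln_ipred[engine.obs_mask])
    resid = lndv - np.log(pred)
    iresid = lndv - np.log(ipred)
    return pd.DataFrame({
        "id": [engine.ids[i] for i in subj_idx],
        "time": times,
        "tad": tad,
        "dv": np.exp(lndv),
        "pred": pred,
        "ipred": ipred,
        "residual": resid,
        "wres": resid / sigma,
        "iwres": iresid / sigma,
    })


@dataclass(frozen=True)
class VpcBin:
    """One time bin of a VPC: observed percentiles and simulated bands."""

    t_lo: float
    t_hi: float
    n_obs: int
    observed: Tuple[float, float, float]          # 2.5 / 50 / 97.5 percentiles
    band_lo: Tuple[float, float, float]           # lower edge of 95% PI per percentile
    band_hi: Tuple[float, float, float]


@dataclass(frozen=True)
class VpcResult:
    bins: Tuple[VpcBin, ...]
    n_sim: int
    prediction_corrected: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in self.bins:
            for pct, o, lo, hi in zip((2.5, 50.0, 97.5), b.observed,
                                      b.band_lo, b.band_hi):
                rows.append({"t_lo": b.t_lo, "t_hi": b.t_hi, "n_obs": b.n_obs,
                             "percentile": pct, "observed": o,
                             "band_lo": lo, "band_hi": hi})
        return pd.DataFrame(rows)

    def median_coverage(self) -> float:
        """Fraction of bins whose observed median lies inside the simulated
        95% interval for the median."""
        ok = [b.band_lo[1] <= b.observed[1] <= b.band_hi[1] for b in self.bins]
        return float(np.mean(ok))


def pc_vpc(
    ds: StudyDataset,
    pm: PopulationModel,
    n_sim: int = 1000,
    bins: int | Sequence[float] = 6,
    seed: int = 0,
    prediction_corrected: bool = True,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Bins observations by time after dose (quantile bins by default, or
    explicit edges), corrects observed and simulated values by the
    bin-median population prediction, and overlays observed 2.5/50/97.5
    percentiles on the simulated 95% prediction interval of each
    percentile.  Reproducible for a given seed.
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    p = _model_to_params(pm)
    engine, subj_idx, times, tad, lndv = _flat_engine(ds, pm)
    rng = np.random.default_rng(seed)

    if np.isscalar(bins):
        qs = np.linspace(0, 1, int(bins) + 1)
        edges = np.unique(np.quantile(tad, qs))
        if len(edges) < 2:
            edges = np.array([tad.min(), tad.max() + 1e-9])
    else:
        edges = np.asarray(bins, dtype=float)
    edges = edges.copy()
    edges[-1] += 1e-9
    which = np.clip(np.digitize(tad, edges) - 1, 0, len(edges) - 2)

    ln_pred_flat = engine._ln_total(p, np.zeros((engine.S, 2)))[engine.obs_mask]
    ln_sim = _simulate_lnobs(engine, p, pm, n_sim, rng)[:, engine.obs_mask]

    if prediction_corrected:
        correction = np.empty_like(ln_pred_flat)
        for b in range(len(edges) - 1):
            m = which == b
            if np.any(m):
                correction[m] = np.median(ln_pred_flat[m]) - ln_pred_flat[m]
    else:
        correction = np.zeros_like(ln_pred_flat)
    obs_c = lndv + correction
    sim_c = ln_sim + correction[None, :]

    pcts = (2.5, 50.0, 97.5)
    out_bins: List[VpcBin] = []
    for b in range(len(edges) - 1):
        m = which == b
        if not np.any(m):
            continue  # with quantile bins this cannot happen; explicit edges may
        obs_p = np.percentile(np.exp(obs_c[m]), pcts)
        sim_p = np.percentile(np.exp(sim_c[:, m]), pcts, axis=1)   # (3, n_sim)
        lo = np.percentile(sim_p, 2.5, axis=1)
        hi = np.percentile(sim_p, 97.5, axis=1)
        out_bins.append(VpcBin(
            t_lo=float(edges[b]), t_hi=float(edges[b + 1]),
            n_obs=int(m.sum()),
            observed=tuple(obs_p), band_lo=tuple(lo), band_hi=tuple(hi),
        ))
    return VpcResult(bins=tuple(out_bins), n_sim=n_sim,
                     prediction_corrected=prediction_corrected)


def npde(
    ds: StudyDataset,
    pm: PopulationModel,
    n_sim: int = 1000,
    seed: int = 0,
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Normalised prediction distribution errors.

    Per subject: simulate ``n_sim`` replicate observation vectors,
    decorrelate observed and simulated vectors with the simulated mean and
    Cholesky factor of the simulated covariance (on the log scale), rank
    the observed against the simulated values coordinate-wise, and apply
    the inverse-normal transform.  Ties are broken with seeded uniform
    jitter; ranks of 0 or n_sim are clipped to half a rank.  Under a
    correct model the NPDE are approximately iid standard normal.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    p = _model_to_params(pm)
    engine, subj_idx, times, tad, lndv = _flat_engine(ds, pm)
    rng = np.random.default_rng(seed)
    ln_sim = _simulate_lnobs(engine, p, pm, n_sim, rng)   # (n_sim, S, O)

    rows = []
    for i in range(engine.S):
        m = engine.obs_mask[i]
        if not np.any(m):
            continue
        y = engine.lndv[i, m]
        sims = ln_sim[:, i, :][:, m]                      # (n_sim, O_i)
        mu = sims.mean(axis=0)
        if n_sim > 1:
            cov = np.cov(sims, rowvar=False, ddof=1)
            cov = np.atleast_2d(cov)
        else:
            cov = np.eye(y.size)
        cov = cov + ridge * np.eye(y.size)
        try:
            L = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = cov + 1e-6 * np.trace(cov) / y.size * np.eye(y.size)
            L = np.linalg.cholesky(cov)
        y_star = np.linalg.solve(L, y - mu)
        sim_star = np.linalg.solve(L, (sims - mu).T).T    # (n_sim, O_i)
        below = (sim_star < y_star).sum(axis=0).astype(float)
        ties = (sim_star == y_star).sum(axis=0)
        below += rng.uniform(0.0, 1.0, size=below.shape) * ties
        pde = np.clip(below / n_sim, 1.0 / (2 * n_sim), 1.0 - 1.0 / (2 * n_sim))
        z = stats.norm.ppf(pde)
        for j, oj in enumerate(np.nonzero(m)[0]):
            rows.append({"id": engine.ids[i], "time": engine.obs_time[i, oj],
                         "npde": z[j]})
    return pd.DataFrame(rows)
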