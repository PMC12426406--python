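"""Model qualification: prediction-corrected VPC, nonparametric bootstrap,
and external-prediction metrics.

The pcVPC compares observed concentration percentiles (5th/50th/95th) with
simulation-based confidence bands after normalizing observations and
simulations by the bin-median population prediction, which removes the
spread induced by covariates and banded dosing.  The bootstrap resamples
subjects with replacement and refits each replicate.  Prediction metrics
(MDPE, MAPE, F20, F30) summarize a priori predictability of external data
on population predictions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_core as mc
from .data_io import Dataset, STUDY_OCCASION_BOUNDS
from .estimation import FitResult, ModelSpec, _as_subjects, _tad, fit, _pack

__all__ = ["VpcResult", "BootstrapResult", "PredictionMetrics", "pcvpc",
           "bootstrap", "prediction_metrics", "population_predictions",
           "gof_tables"]


@dataclass
class VpcResult:
    """Binned pcVPC summary: observed percentiles and simulated 95% bands."""

    table: pd.DataFrame
    n_sim: int
    seed: int

    def coverage(self) -> float:
        """Fraction of observed percentile points inside their bands."""
        t = self.table
        inside = 0
        total = 0
        for p in ("p5", "p50", "p95"):
            total += len(t)
            inside += int(((t[f"obs_{p}"] >= t[f"lo_{p}"])
                           & (t[f"obs_{p}"] <= t[f"hi_{p}"])).sum())
        return inside / total


def _sim_observations(model, subjects, params, pop, rng):
    """One replicate dataset simulated from the population model."""
    sims = []
    for subj in subjects:
        om = model.omegas(params)
        eta = rng.standard_normal(model.n_eta) * om
        n_k = model.n_kappa(params, subj)
        kappa = rng.standard_normal(n_k) * model.pi(params) if n_k else \
            np.zeros(0)
        f = model.predict(params, subj, eta, kappa)
        y = mc.apply_residual(f, pop.sigma_prop, pop.sigma_add, rng)
        sims.append(y)
    return np.concatenate(sims)


def pcvpc(
    dataset,
    fit_result: FitResult,
    n_sim: int = 2000,
    n_bins: int = 8,
    seed: int = 0,
    dt: float = 0.1,
    occasion_bounds=STUDY_OCCASION_BOUNDS,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Bins are equal-count quantiles of time-after-dose.  Observations and
    simulations are scaled by median(PRED in bin)/PRED_i; bands are the
    2.5-97.5 percentile envelope of each binned percentile over ``n_sim``
    simulated replicates (observed covariates and design are reused).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    subjects = _as_subjects(dataset, dt, occasion_bounds)
    model = fit_result.model
    params = fit_result.params
    pop = fit_result.estimates
    pred = np.concatenate([model.predict(params, s, np.zeros(model.n_eta),
                                         np.zeros(model.n_kappa(params, s)))
                           for s in subjects])
    obs = np.concatenate([s.y for s in subjects])
    tad = np.concatenate([_tad(s) for s in subjects])
    ok = pred > 1e-12
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} observations with zero population "
                      "prediction excluded from pcVPC")
    edges = np.unique(np.quantile(tad[ok], np.linspace(0, 1, n_bins + 1)))
    bin_idx = np.clip(np.searchsorted(edges, tad, side="right") - 1,
                      0, len(edges) - 2)
    pc_factor = np.empty(len(obs))
    for b in range(len(edges) - 1):
        m = ok & (bin_idx == b)
        pc_factor[m] = np.median(pred[m]) / pred[m] if m.any() else np.nan
    obs_pc = obs * pc_factor

    rng = np.random.default_rng(seed)
    qs = (5.0, 50.0, 95.0)
    n_b = len(edges) - 1
    sim_stats = np.empty((n_sim, n_b, 3))
    for r in range(n_sim):
        y = _sim_observations(model, subjects, params, pop, rng) * pc_factor
        for b in range(n_b):
            m = ok & (bin_idx == b)
            sim_stats[r, b] = np.percentile(y[m], qs) if m.any() else np.nan
    rows = []
    for b in range(n_b):
        m = ok & (bin_idx == b)
        if not m.any():
            continue
        row = {"bin": b, "t_lo": edges[b], "t_hi": edges[b + 1],
               "t_mid": 0.5 * (edges[b] + edges[b + 1]),
               "n_obs": int(m.sum())}
        op = np.percentile(obs_pc[m], qs)
        for k, p in enumerate(("p5", "p50", "p95")):
            row[f"obs_{p}"] = op[k]
            row[f"sim_{p}"] = float(np.median(sim_stats[:, b, k]))
            row[f"lo_{p}"] = float(np.percentile(sim_stats[:, b, k], 2.5))
            row[f"hi_{p}"] = float(np.percentile(sim_stats[:, b, k], 97.5))
        rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim, seed=seed)


@dataclass
class BootstrapResult:
    """Per-parameter medians and percentile CIs over converged replicates."""

    summary: pd.DataFrame          # parameter, median, lo2_5, hi97_5
    replicates: pd.DataFrame
    convergence_fraction: float
    reliable: bool = True


def bootstrap(
    dataset,
    spec: ModelSpec,
    init: mc.PopulationParameters,
    n_boot: int = 500,
    seed: int = 0,
    dt: float = 0.1,
    occasion_bounds=STUDY_OCCASION_BOUNDS,
    **fit_kw,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects with replacement, refit
    each replicate, summarize converged replicates by median and 2.5/97.5
    percentiles.  Flagged unreliable if < 50% of replicates converge."""
    subjects = _as_subjects(dataset, dt, occasion_bounds)
    if len(subjects) < 2:
        raise ValueError("bootstrap needs >= 2 subjects")
    fit_kw.setdefault("compute_se", False)
    rng = np.random.default_rng(seed)
    names = list(spec.estimated) + [e.label() for e in spec.covariate_effects]
    rows = []
    n_conv = 0
    for b in range(n_boot):
        pick = rng.integers(0, len(subjects), size=len(subjects))
        boot_subjects = [subjects[k] for k in pick]
        try:
            f = fit(boot_subjects, spec, init, **fit_kw)
        except (ValueError, RuntimeError):
            continue
        if not (f.converged and np.isfinite(f.ofv)):
            continue
        n_conv += 1
        row = {"replicate": b, "ofv": f.ofv}
        vals = _pack(f.estimates, f.betas, spec)
        for k, name in enumerate(names):
            row[name] = math.exp(vals[k]) if k < len(spec.estimated) \
                else vals[k]
        rows.append(row)
    reps = pd.DataFrame(rows)
    frac = n_conv / n_boot if n_boot else 0.0
    summ_rows = []
    for name in names:
        if len(reps):
            v = reps[name].to_numpy()
            summ_rows.append({"parameter": name,
                              "median": float(np.median(v)),
                              "lo2_5": float(np.percentile(v, 2.5)),
                              "hi97_5": float(np.percentile(v, 97.5))})
        else:
            summ_rows.append({"parameter": name, "median": math.nan,
                              "lo2_5": math.nan, "hi97_5": math.nan})
    return BootstrapResult(summary=pd.DataFrame(summ_rows), replicates=reps,
                           convergence_fraction=frac, reliable=frac >= 0.5)


@dataclass(frozen=True)
class PredictionMetrics:
    """MDPE/MAPE (%) and F20/F30 (%) of prediction errors PE% =
    100·(pred − obs)/obs."""

    mdpe: float
    mape: float
    f20: float
    f30: float


def prediction_metrics(obs, pred) -> PredictionMetrics:
    """Median prediction error, median absolute prediction error, and the
    percentage of |PE%| within 20% / 30%.  Zero observations are excluded
    with a warning."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    ok = obs > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} non-positive observations excluded")
    pe = 100.0 * (pred[ok] - obs[ok]) / obs[ok]
    ape = np.abs(pe)
    return PredictionMetrics(
        mdpe=float(np.median(pe)), mape=float(np.median(ape)),
        f20=float(100.0 * np.mean(ape <= 20.0)),
        f30=float(100.0 * np.mean(ape <= 30.0)))


def population_predictions(dataset, fit_result: FitResult, dt: float = 0.1,
                           occasion_bounds=STUDY_OCCASION_BOUNDS):
    """(obs, pred) arrays of population (eta = 0) predictions for each
    observation row, in row order."""
    subjects = _as_subjects(dataset, dt, occasion_bounds)
    model = fit_result.model
    params = fit_result.params
    obs, pred = [], []
    for s in subjects:
        obs.append(s.y)
        pred.append(model.predict(params, s, np.zeros(model.n_eta),
                                  np.zeros(model.n_kappa(params, s))))
    return np.concatenate(obs), np.concatenate(pred)


def gof_tables(fit_result: FitResult) -> pd.DataFrame:
    """Tabular goodness-of-fit data: one row per observation with DV, PRED,
    IPRED, IWRES and CWRES versus time and time-after-dose."""
    if fit_result.gof is None:
        return pd.DataFrame(columns=["ID", "TIME", "TAD", "OCC", "DV",
                                     "PRED", "IPRED", "IWRES", "CWRES"])
    return fit_result.gof
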