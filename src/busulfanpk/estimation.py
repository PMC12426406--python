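"""Nonlinear mixed-effects estimation by FOCE with interaction.

The marginal likelihood of each subject's data is approximated by a Laplace
expansion around the conditional mode of the random effects (eta: BSV on
CL, Vc, Vp; kappa: occasion-wise IOV on CL), with the residual variance
evaluated at the conditional prediction (the eta-epsilon "interaction").
Per subject,

    -2 log p(y, u) = sum_j [ log(2 pi v_j) + (y_j - f_j(u))^2 / v_j ]
                     + d log(2 pi) + log|Omega| + u' Omega^{-1} u

with v_j = f_j^2 sigma_prop^2 + sigma_add^2, and

    OFV_i = -2 log p(y, u_hat) - d log(2 pi) + log det H,
    H     = sum_j F_j F_j' (1/v_j + 2 f_j^2 sigma_prop^4 / v_j^2) + Omega^{-1}

(the Fisher/Gauss-Newton curvature of the joint density, F_j = df_j/du at
the mode).  OFV = sum_i OFV_i is minimized over log-transformed population
parameters with a quasi-Newton outer optimizer and finite-difference
gradients.  Standard errors come from the inverse numerical Hessian of the
OFV; the condition number is the extreme-eigenvalue ratio of the estimate
correlation matrix.

The engine is structural-model agnostic (any `FoceModel`); `BusulfanFoce`
binds it to the semi-mechanistic GSH-depletion model in `model_core`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from . import model_core as mc
from ._kernel import integrate_grid
from .data_io import Dataset, SubjectData, STUDY_OCCASION_BOUNDS, \
    subjects_from_dataframe

__all__ = [
    "CovariateEffect", "ModelSpec", "FitResult", "FoceModel", "BusulfanFoce",
    "individual_joint_density", "foce_objective", "fit", "covariate_step",
    "continuous_candidates", "shrinkage", "cwres", "DEFAULT_ESTIMATED",
]

_BIG = 1e12
_LOG2PI = math.log(2.0 * math.pi)

DEFAULT_ESTIMATED = (
    "theta_cl", "theta_vc", "theta_q", "theta_vp",
    "omega_cl", "omega_vc", "omega_vp", "pi_cl",
    "sigma_prop", "sigma_add",
)


@dataclass(frozen=True)
class CovariateEffect:
    """One candidate covariate-parameter relation (multiplier on CL or Vc)."""

    parameter: str        # "cl" | "vc"
    covariate: str        # SubjectCovariates attribute ("gst", "wt", ...)
    form: str             # "linear" | "exponential" | "power" | "fractional"
    reference: float = 1.0

    def multiplier(self, value: float, beta: float) -> float:
        if self.form == "linear":
            return max(1.0 + beta * (value - self.reference), 1e-6)
        if self.form == "exponential":
            return math.exp(beta * (value - self.reference))
        if self.form == "power":
            if value <= 0:
                raise ValueError("power form needs a positive covariate")
            return (value / self.reference) ** beta
        if self.form == "fractional":   # categorical 0/1 flags
            return max(1.0 + beta * value, 1e-6)
        raise ValueError(f"unknown covariate form: {self.form!r}")

    def label(self) -> str:
        return f"{self.covariate}-{self.form}-on-{self.parameter}"


def continuous_candidates(parameter: str, covariate: str,
                          reference: float) -> list[CovariateEffect]:
    """The three standard functional forms tested for a continuous covariate."""
    return [CovariateEffect(parameter, covariate, form, reference)
            for form in ("linear", "exponential", "power")]


@dataclass(frozen=True)
class ModelSpec:
    """What to estimate and which structural components are switched on."""

    size_metric: str = "NFM"               # WT | BSA | FFM | NFM
    maturation: bool = True
    gst_covariate: bool = True
    iov: bool = True
    eta_params: tuple = ("cl", "vc", "vp")
    estimated: tuple = DEFAULT_ESTIMATED
    covariate_effects: tuple = ()          # tuple[CovariateEffect, ...]

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=tuple(
            e for e in self.covariate_effects if e != effect))


_OMEGA_BY_ETA = {"cl": "omega_cl", "vc": "omega_vc", "vp": "omega_vp"}


class FoceModel:
    """Structural-model interface consumed by the FOCE engine.

    ``params`` is an opaque bundle; for the busulfan model it is
    (PopulationParameters, betas) where betas align with
    spec.covariate_effects.
    """

    n_eta: int = 0

    def predict(self, params, subj, eta: np.ndarray,
                kappa: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def omegas(self, params) -> np.ndarray:
        raise NotImplementedError

    def pi(self, params) -> float:
        return 0.0

    def sigmas(self, params) -> tuple[float, float]:
        raise NotImplementedError

    def n_kappa(self, params, subj) -> int:
        return 0


class BusulfanFoce(FoceModel):
    """Semi-mechanistic busulfan model bound to the FOCE engine."""

    def __init__(self, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.n_eta = len(self.spec.eta_params)
        self._eta_slot = {name: i for i, name in
                          enumerate(self.spec.eta_params)}

    def individual(self, params, cov: mc.SubjectCovariates,
                   eta: np.ndarray) -> mc.IndividualParameters:
        pop, betas = params
        spec = self.spec
        full = np.zeros(3)
        for name, i in self._eta_slot.items():
            full[("cl", "vc", "vp").index(name)] = eta[i]
        ind = mc.individual_parameters(
            pop, cov, eta=full, size_metric=spec.size_metric,
            maturation=spec.maturation, gst_covariate=spec.gst_covariate)
        if spec.covariate_effects:
            m_cl = m_vc = 1.0
            for eff, beta in zip(spec.covariate_effects, betas):
                value = getattr(cov, eff.covariate)
                if eff.form == "fractional":
                    value = 1.0 if eff.covariate in cov.comedication_flags \
                        else 0.0
                m = eff.multiplier(float(value), beta)
                if eff.parameter == "cl":
                    m_cl *= m
                elif eff.parameter == "vc":
                    m_vc *= m
                else:
                    raise ValueError(f"unsupported parameter {eff.parameter!r}")
            ind = mc.IndividualParameters(
                cl=ind.cl * m_cl, vc=ind.vc * m_vc, q=ind.q,
                vp=ind.vp, s_gsh=ind.s_gsh, eta=ind.eta, kappa=ind.kappa)
        return ind

    def predict(self, params, subj: SubjectData, eta, kappa) -> np.ndarray:
        pop, _ = params
        ind = self.individual(params, subj.covs, np.asarray(eta, dtype=float))
        kap = np.asarray(kappa, dtype=float)
        clmult = subj.grid.clmult(kap if kap.size else None)
        conc, _, _ = integrate_grid(
            subj.grid.times, subj.grid.rates, clmult,
            ind.cl, ind.vc, ind.q, ind.vp, ind.s_gsh, pop.k_gsh)
        return conc[subj.grid.obs_idx]

    def omegas(self, params) -> np.ndarray:
        pop, _ = params
        return np.array([getattr(pop, _OMEGA_BY_ETA[n])
                         for n in self.spec.eta_params])

    def pi(self, params) -> float:
        pop, _ = params
        return pop.pi_cl if self.spec.iov else 0.0

    def sigmas(self, params):
        pop, _ = params
        return pop.sigma_prop, pop.sigma_add

    def n_kappa(self, params, subj) -> int:
        if not self.spec.iov or self.pi(params) <= 0:
            return 0
        return subj.grid.n_occasions


# ---------------------------------------------------------------------------
# engine

def _layout(model, params, subj):
    """Active random-effect layout: indices of etas with omega > 0 and the
    number of kappas."""
    om = model.omegas(params)
    active = np.flatnonzero(om > 0)
    n_k = model.n_kappa(params, subj)
    pi = model.pi(params)
    if pi <= 0:
        n_k = 0
    return active, om, n_k, pi


def _expand(u, active, n_eta, n_k):
    eta = np.zeros(n_eta)
    eta[active] = u[:len(active)]
    kappa = u[len(active):len(active) + n_k]
    return eta, kappa


def _neg2_joint(model, subj, params, u, active, om, n_k, pi):
    eta, kappa = _expand(u, active, model.n_eta, n_k)
    try:
        f = model.predict(params, subj, eta, kappa)
    except (ValueError, RuntimeError, FloatingPointError):
        return _BIG
    if not np.all(np.isfinite(f)):
        return _BIG
    sp, sa = model.sigmas(params)
    v = (f * sp) ** 2 + sa ** 2
    if np.any(v <= 0):
        return _BIG
    r = subj.y - f
    val = float(np.sum(np.log(2.0 * np.pi * v) + r * r / v))
    d = len(active) + n_k
    if d:
        val += d * _LOG2PI
        if len(active):
            oa = om[active]
            val += float(2.0 * np.sum(np.log(oa))
                         + np.sum((u[:len(active)] / oa) ** 2))
        if n_k:
            val += float(2.0 * n_k * math.log(pi)
                         + np.sum((u[len(active):len(active) + n_k] / pi) ** 2))
    return val


def individual_joint_density(model: FoceModel, subj: SubjectData, params,
                             eta, kappa) -> float:
    """-2 log of the joint density of one subject's data and random effects."""
    active, om, n_k, pi = _layout(model, params, subj)
    eta = np.asarray(eta, dtype=float)
    kappa = np.asarray(kappa, dtype=float)[:n_k]
    u = np.concatenate([eta[active], kappa])
    return _neg2_joint(model, subj, params, u, active, om, n_k, pi)


def _pred_jacobian(model, subj, params, u, f0, active, n_k, step=1e-4):
    """d f / d u at u (forward differences from f0), shape (n_obs, d)."""
    d = len(u)
    F = np.empty((subj.n_obs, d))
    for i in range(d):
        e = np.zeros(d)
        e[i] = step
        ep, km = _expand(u + e, active, model.n_eta, n_k)
        F[:, i] = (model.predict(params, subj, ep, km) - f0) / step
    return F


def _subject_ofv(model, subj, params, u0=None, inner_gtol=1e-8,
                 return_detail=False, max_iter=60):
    """Laplace/FOCE-I contribution of one subject.

    The conditional mode of u = (eta_active, kappa) is found by damped
    Newton iteration on the joint -2 log density, using the Gauss-Newton
    (Fisher) curvature; the same curvature supplies the Laplace
    determinant.
    """
    active, om, n_k, pi = _layout(model, params, subj)
    d = len(active) + n_k
    if d == 0:
        val = _neg2_joint(model, subj, params, np.empty(0), active, om, n_k, pi)
        if return_detail:
            return val, np.empty(0), (active, n_k)
        return val, np.empty(0)
    if u0 is None or len(u0) != d:
        u0 = np.zeros(d)
    sp, sa = model.sigmas(params)
    prec = np.concatenate([
        1.0 / om[active] ** 2,
        np.full(n_k, 1.0 / pi ** 2) if n_k else np.empty(0)])
    y = subj.y

    def fh(u):
        eta, kappa = _expand(u, active, model.n_eta, n_k)
        return model.predict(params, subj, eta, kappa)

    def qval(f, u):
        # joint -2 log density up to u-independent constants, halved
        v = (f * sp) ** 2 + sa ** 2
        if np.any(v <= 0) or not np.all(np.isfinite(f)):
            return np.inf
        r = y - f
        return 0.5 * (np.sum(np.log(v) + r * r / v) + u @ (prec * u))

    def _fail():
        return (np.inf, u0, (active, n_k)) if return_detail \
            else (np.inf, u0)

    u = np.asarray(u0, dtype=float).copy()
    try:
        f = fh(u)
    except (ValueError, RuntimeError):
        return _fail()
    q = qval(f, u)
    if not np.isfinite(q):
        u = np.zeros(d)
        f = fh(u)
        q = qval(f, u)
        if not np.isfinite(q):
            return _fail()
    F = v = w = None
    for _ in range(max_iter):
        F = _pred_jacobian(model, subj, params, u, f, active, n_k)
        v = (f * sp) ** 2 + sa ** 2
        r = y - f
        dv = 2.0 * f * sp ** 2                       # dv/df
        grad = F.T @ (0.5 * (-2.0 * r / v + (1.0 / v - r * r / v ** 2) * dv)) \
            + prec * u
        if np.max(np.abs(grad)) < inner_gtol:
            break
        w = 1.0 / v + 2.0 * (f ** 2) * sp ** 4 / v ** 2
        H = (F * w[:, None]).T @ F + np.diag(prec)
        try:
            step_dir = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return _fail()
        t = 1.0
        improved = False
        for _ls in range(12):
            u_new = u + t * step_dir
            f_new = fh(u_new)
            q_new = qval(f_new, u_new)
            if q_new < q - 1e-12:
                u, f, q = u_new, f_new, q_new
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    else:
        F = _pred_jacobian(model, subj, params, u, f, active, n_k)
        v = (f * sp) ** 2 + sa ** 2
    if F is None:
        F = _pred_jacobian(model, subj, params, u, f, active, n_k)
    v = (f * sp) ** 2 + sa ** 2
    r = y - f
    g_hat = float(np.sum(np.log(2.0 * np.pi * v) + r * r / v)
                  + u @ (prec * u)) + d * _LOG2PI \
        + float(2.0 * np.sum(np.log(om[active]))) \
        + (2.0 * n_k * math.log(pi) if n_k else 0.0)
    w = 1.0 / v + 2.0 * (f ** 2) * sp ** 4 / v ** 2
    H = (F * w[:, None]).T @ F + np.diag(prec)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0 or not np.isfinite(g_hat):
        return _fail()
    ofv = g_hat - d * _LOG2PI + logdet
    if return_detail:
        return ofv, u, (active, n_k, f, v, F, om, pi)
    return ofv, u


def foce_objective(model: FoceModel, subjects, params, cache: dict | None = None,
                   inner_gtol: float = 1e-8) -> float:
    """FOCE-I objective function value (sum of subject contributions)."""
    total = 0.0
    for i, subj in enumerate(subjects):
        u0 = cache.get(i) if cache is not None else None
        ofv_i, u_hat = _subject_ofv(model, subj, params, u0,
                                    inner_gtol=inner_gtol)
        if not np.isfinite(ofv_i):
            return _BIG
        if cache is not None:
            cache[i] = u_hat
        total += ofv_i
    return total


# ---------------------------------------------------------------------------
# packing of the outer parameter vector

def _bfgs_outer(objective, x0, bounds, maxiter=150, gtol=0.2,
                ftol_abs=1e-6, grad_step=1e-3, max_step=1.5):
    """Projected BFGS with Armijo backtracking for the outer OFV problem.

    Uses forward-difference gradients with a step large enough to dominate
    the (tiny) warm-start noise of the nested optimizations, caps the trial
    step in log-parameter space, and treats the failure plateau of the
    objective as simple non-improvement, which plain backtracking handles
    robustly.
    """
    lo, hi = bounds[:, 0], bounds[:, 1]

    def proj(x):
        return np.clip(x, lo, hi)

    def grad_at(x, f0):
        g = np.empty(len(x))
        for i in range(len(x)):
            e = np.zeros(len(x))
            e[i] = grad_step
            g[i] = (objective(x + e) - f0) / grad_step
        return g

    x = proj(np.asarray(x0, dtype=float))
    f = objective(x)
    if not np.isfinite(f) or f >= _BIG:
        return x, f, False, "objective not finite at the initial estimates"
    g = grad_at(x, f)
    H = np.eye(len(x)) / max(np.linalg.norm(g), 1.0)
    stall = 0
    message = "maximum outer iterations reached"
    converged = False
    for _ in range(maxiter):
        if np.max(np.abs(g)) < gtol:
            converged, message = True, "gradient tolerance reached"
            break
        d = -H @ g
        if d @ g > -1e-12:            # not a descent direction: reset
            H = np.eye(len(x)) / max(np.linalg.norm(g), 1.0)
            d = -H @ g
        nd = np.linalg.norm(d)
        t = min(1.0, max_step / nd) if nd > 0 else 0.0
        accepted = False
        for _ls in range(25):
            x_new = proj(x + t * d)
            f_new = objective(x_new)
            if f_new < f - 1e-10:   # simple decrease; robust on plateaus
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged, message = True, "no further improvement (line search)"
            break
        g_new = grad_at(x_new, f_new)
        s = x_new - x
        yv = g_new - g
        sy = s @ yv
        if sy > 1e-10:
            rho = 1.0 / sy
            I = np.eye(len(x))
            H = (I - rho * np.outer(s, yv)) @ H @ (I - rho * np.outer(yv, s)) \
                + rho * np.outer(s, s)
        if f - f_new < ftol_abs:
            stall += 1
            if stall >= 3:
                x, f, g = x_new, f_new, g_new
                converged, message = True, "objective change below tolerance"
                break
        else:
            stall = 0
        x, f, g = x_new, f_new, g_new
    return x, f, converged, message


def _pack(pop: mc.PopulationParameters, betas, spec: ModelSpec) -> np.ndarray:
    x = [math.log(getattr(pop, n)) for n in spec.estimated]
    x.extend(betas)
    return np.array(x)


def _unpack(x, base_pop: mc.PopulationParameters, spec: ModelSpec):
    n = len(spec.estimated)
    upd = {name: math.exp(min(xi, 50.0))
           for name, xi in zip(spec.estimated, x[:n])}
    return base_pop.replace(**upd), tuple(x[n:])


@dataclass
class FitResult:
    """Estimates, uncertainty and diagnostics of one FOCE-I fit."""

    estimates: mc.PopulationParameters
    betas: tuple = ()
    spec: ModelSpec = field(default_factory=ModelSpec)
    se: dict = field(default_factory=dict)
    rse: dict = field(default_factory=dict)
    ofv: float = math.nan
    aic: float = math.nan
    bic: float = math.nan
    condition_number: float = math.nan
    eta_shrinkage: dict = field(default_factory=dict)   # % per eta
    kappa_shrinkage: float = math.nan                   # % on IOV
    eps_shrinkage: float = math.nan                     # %
    ebes: dict = field(default_factory=dict)            # id -> (eta, kappa)
    gof: pd.DataFrame | None = field(default=None, repr=False)
    converged: bool = False
    message: str = ""
    n_obs: int = 0
    n_params: int = 0
    subjects: list = field(default=None, repr=False)    # type: ignore
    model: FoceModel = field(default=None, repr=False)  # type: ignore

    @classmethod
    def from_parameters(cls, pop: mc.PopulationParameters,
                        spec: ModelSpec | None = None,
                        betas: tuple = ()) -> "FitResult":
        """Minimal result wrapping known parameters (for simulation-based
        diagnostics without an actual fit)."""
        spec = spec or ModelSpec()
        return cls(estimates=pop, betas=betas, spec=spec, converged=True,
                   model=BusulfanFoce(spec))

    @property
    def params(self):
        return (self.estimates, self.betas)


def _as_subjects(dataset, dt, occasion_bounds):
    if isinstance(dataset, Dataset):
        return subjects_from_dataframe(dataset.df, dt=dt,
                                       occasion_bounds=occasion_bounds)
    if isinstance(dataset, pd.DataFrame):
        return subjects_from_dataframe(dataset, dt=dt,
                                       occasion_bounds=occasion_bounds)
    return list(dataset)


def _tad(subj: SubjectData) -> np.ndarray:
    starts = np.array([d.start_time for d in subj.doses])
    out = np.empty(subj.n_obs)
    for j, t in enumerate(subj.obs_times):
        prior = starts[starts <= t + 1e-9]
        out[j] = t - (prior.max() if prior.size else 0.0)
    return out


def fit(
    dataset,
    spec: ModelSpec | None = None,
    init: mc.PopulationParameters | None = None,
    init_betas: tuple | None = None,
    *,
    dt: float = 0.1,
    occasion_bounds=STUDY_OCCASION_BOUNDS,
    compute_se: bool = True,
    outer_maxfun: int = 150,
    inner_gtol: float = 1e-8,
    hess_step: float = 1e-3,
) -> FitResult:
    """Estimate population parameters by FOCE-I.

    ``dataset`` may be a Dataset, an event-record DataFrame or a prepared
    list of SubjectData.  Non-convergence is reported in the result status,
    not raised.
    """
    spec = spec or ModelSpec()
    init = init or mc.PopulationParameters()
    if init_betas is None:
        init_betas = tuple(0.0 for _ in spec.covariate_effects)
    subjects = _as_subjects(dataset, dt, occasion_bounds)
    if not subjects:
        raise ValueError("dataset has no subjects")
    for s in subjects:
        if s.n_obs == 0:
            raise ValueError(f"subject {s.id} has no observations")
    model = BusulfanFoce(spec)
    cache: dict = {}
    x0 = _pack(init, init_betas, spec)
    n_log = len(spec.estimated)

    def objective(x):
        pop, betas = _unpack(x, init, spec)
        try:
            return foce_objective(model, subjects, (pop, betas), cache,
                                  inner_gtol=inner_gtol)
        except (ValueError, RuntimeError):
            return _BIG

    bounds = np.array([(xi - 4.0, xi + 4.0) for xi in x0[:n_log]]
                      + [(-10.0, 10.0)] * (len(x0) - n_log))
    x_hat, ofv, converged, message = _bfgs_outer(
        objective, x0, bounds, maxiter=outer_maxfun)
    pop_hat, betas_hat = _unpack(x_hat, init, spec)
    n_obs = sum(s.n_obs for s in subjects)
    p = len(x_hat)
    result = FitResult(
        estimates=pop_hat, betas=betas_hat, spec=spec,
        ofv=ofv, aic=ofv + 2 * p, bic=ofv + p * math.log(n_obs),
        converged=converged, message=message, n_obs=n_obs, n_params=p,
        subjects=subjects, model=model)

    if compute_se and np.isfinite(ofv) and ofv < _BIG:
        _fill_uncertainty(result, objective, x_hat, spec, hess_step)
    _fill_diagnostics(result, inner_gtol)
    return result


def _fill_uncertainty(result, objective, x_hat, spec, h):
    p = len(x_hat)
    f0 = objective(x_hat)
    H = np.empty((p, p))
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h
        fp[i] = objective(x_hat + e)
        fm[i] = objective(x_hat - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            fpp = objective(x_hat + ei + ej)
            fmm = objective(x_hat - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                 - fm[i] - fm[j] + fmm) / (2.0 * h ** 2)
    names = list(spec.estimated) + [e.label() for e in spec.covariate_effects]
    try:
        cov = 2.0 * np.linalg.inv(H)
        var = np.diag(cov)
        if np.any(var <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
        sd = np.sqrt(var)
        corr = cov / np.outer(sd, sd)
        eig = np.linalg.eigvalsh(corr)
        result.condition_number = float(abs(eig[-1]) / max(abs(eig[0]), 1e-300))
        n_log = len(spec.estimated)
        for k, name in enumerate(names):
            if k < n_log:
                est = math.exp(x_hat[k])
                se = sd[k] * est          # delta method from log scale
            else:
                est = x_hat[k]
                se = sd[k]
            result.se[name] = float(se)
            result.rse[name] = float(100.0 * se / abs(est)) if est else math.nan
    except np.linalg.LinAlgError:
        result.message += " | Hessian not positive definite"
        result.condition_number = math.inf


def _fill_diagnostics(result, inner_gtol):
    """Final conditional pass: EBEs, shrinkage, IWRES/CWRES, GOF table."""
    model, subjects = result.model, result.subjects
    if model is None or subjects is None:
        return
    params = result.params
    pop = result.estimates
    rows = []
    etas, kappas, iwres_all = [], [], []
    for subj in subjects:
        ofv_i, u_hat, detail = _subject_ofv(model, subj, params,
                                            inner_gtol=inner_gtol,
                                            return_detail=True)
        if len(detail) == 2:     # no random effects in the model
            active, n_k = detail
            f = model.predict(params, subj, np.zeros(model.n_eta),
                              np.zeros(0))
            sp, sa = model.sigmas(params)
            v = (f * sp) ** 2 + sa ** 2
            F = np.zeros((subj.n_obs, 0))
            om = model.omegas(params); pi = model.pi(params)
        else:
            active, n_k, f, v, F, om, pi = detail
        eta, kappa = _expand(u_hat, active, model.n_eta, n_k)
        etas.append(eta)
        kappas.append(kappa)
        ipred = f
        iwres = (subj.y - ipred) / np.sqrt(v)
        iwres_all.append(iwres)
        pred = model.predict(params, subj, np.zeros(model.n_eta),
                             np.zeros(n_k))
        # FOCE-linearized conditional weighted residuals
        d = len(u_hat)
        if d:
            omega_u = np.concatenate([om[active] ** 2,
                                      np.full(n_k, pi ** 2)])
            V = (F * omega_u) @ F.T + np.diag(v)
            e = subj.y - ipred + F @ u_hat
        else:
            V = np.diag(v)
            e = subj.y - ipred
        try:
            L = np.linalg.cholesky(V)
            cw = linalg.solve_triangular(L, e, lower=True)
        except np.linalg.LinAlgError:
            cw = np.full(subj.n_obs, np.nan)
        tad = _tad(subj)
        for j in range(subj.n_obs):
            rows.append({"ID": subj.id, "TIME": subj.obs_times[j],
                         "TAD": tad[j], "OCC": int(subj.obs_occ[j]),
                         "DV": subj.y[j], "PRED": pred[j],
                         "IPRED": ipred[j], "IWRES": iwres[j],
                         "CWRES": cw[j]})
        result.ebes[subj.id] = (eta, kappa)
    result.gof = pd.DataFrame(rows, columns=["ID", "TIME", "TAD", "OCC", "DV",
                                             "PRED", "IPRED", "IWRES",
                                             "CWRES"])
    # shrinkage
    etas_m = np.array(etas)
    om_full = model.omegas(params)
    for i, name in enumerate(getattr(model, "spec", ModelSpec()).eta_params
                             if hasattr(model, "spec") else
                             [f"eta{i}" for i in range(model.n_eta)]):
        w = om_full[i]
        if w > 0 and len(etas_m):
            sd = etas_m[:, i].std(ddof=1) if len(etas_m) > 1 else 0.0
            result.eta_shrinkage[name] = float(100.0 * (1.0 - sd / w))
        else:
            result.eta_shrinkage[name] = math.nan
    pi = model.pi(params)
    kap_flat = np.concatenate([k for k in kappas]) if kappas else np.array([])
    if pi > 0 and kap_flat.size > 1:
        result.kappa_shrinkage = float(
            100.0 * (1.0 - kap_flat.std(ddof=1) / pi))
    iw = np.concatenate(iwres_all)
    if iw.size > 1:
        result.eps_shrinkage = float(100.0 * (1.0 - iw.std(ddof=1)))


def shrinkage(result: FitResult) -> tuple[dict, float]:
    """(eta-shrinkage % per effect, epsilon-shrinkage %)."""
    return result.eta_shrinkage, result.eps_shrinkage


def cwres(result: FitResult) -> np.ndarray:
    """Conditional weighted residuals, one per observation row."""
    if result.gof is None:
        raise ValueError("fit has no diagnostics")
    return result.gof["CWRES"].to_numpy()


def covariate_step(
    dataset,
    base_spec: ModelSpec,
    candidates,
    init: mc.PopulationParameters | None = None,
    *,
    forward_dofv: float = 3.84,
    backward_dofv: float = 10.83,
    **fit_kw,
):
    """Stepwise covariate search: forward inclusion at dOFV > 3.84
    (p < 0.05, df 1), backward elimination keeps an effect only if its
    removal raises the OFV by > 10.83 (p < 0.001).

    Returns (selected ModelSpec, step log).  Candidate effects must be
    nested extensions of the current model.
    """
    fit_kw.setdefault("compute_se", False)
    log: list[dict] = []
    current = base_spec
    current_fit = fit(dataset, current, init, **fit_kw)
    remaining = list(candidates)
    added: list = []
    while remaining:
        trials = []
        for eff in remaining:
            f_c = fit(dataset, current.with_effect(eff), init, **fit_kw)
            dofv = current_fit.ofv - f_c.ofv
            trials.append((dofv, eff, f_c))
            log.append({"step": "forward", "effect": eff.label(),
                        "dofv": dofv, "included": False})
        dofv, eff, f_best = max(trials, key=lambda t: t[0])
        if dofv <= forward_dofv:
            break
        current = current.with_effect(eff)
        current_fit = f_best
        added.append(eff)
        remaining = [e for e in remaining if e != eff]
        log[-len(trials) + [t[1] for t in trials].index(eff)]["included"] = True
    for eff in added:
        f_wo = fit(dataset, current.without_effect(eff), init, **fit_kw)
        rise = f_wo.ofv - current_fit.ofv
        keep = rise > backward_dofv
        log.append({"step": "backward", "effect": eff.label(),
                    "dofv": rise, "included": keep})
        if not keep:
            current = current.without_effect(eff)
            current_fit = f_wo
    return current, log
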