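"""Core semi-mechanistic model of intravenous busulfan disposition in children.

Busulfan is eliminated almost exclusively by glutathione (GSH) conjugation,
catalysed by glutathione S-transferases (GST).  The model is a two-compartment
disposition system with zero-order (infusion) input in which the elimination
clearance is modulated by a normalized, depletable GSH pool:

    dA1/dt    = rate_in - (CL·A_GSH/Vc)·A1 - (Q/Vc)·A1 + (Q/Vp)·A2
    dA2/dt    = (Q/Vc)·A1 - (Q/Vp)·A2
    dA_GSH/dt = k_GSH·(1 - A_GSH) - (S_GSH/Vc)·A_GSH·k10·A1,   k10 = CL/Vc
    dAUC/dt   = A1/Vc

A_GSH starts at 1 (baseline pool); each milligram of busulfan metabolized
consumes a fraction S_GSH of the remaining pool (scaled to a 1-L central
volume), and the pool is resynthesized toward baseline with first-order rate
k_GSH, whose zero-order synthesis equivalent matches elimination at
equilibrium.  Covariates enter through

* allometric normal-fat-mass (NFM) scaling of CL, Q (exponent 0.75) and
  Vc, Vp (exponent 1), referenced to a 70-kg, 176-cm adult male;
* a sigmoid post-menstrual-age (PMA) maturation fraction on CL;
* an exponential effect of measured GST activity on S_GSH.

Between-subject variability is log-normal on CL, Vc and Vp; inter-occasion
variability is log-normal on CL.  Residual error combines proportional and
additive components.  All concentrations are mg/L, amounts mg, times h.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._kernel import Grid, build_grid, integrate_grid

__all__ = [
    "WEEKS_PER_YEAR", "LLOQ", "STD_WT", "STD_HT", "STD_SEX", "STD_FFM",
    "SubjectCovariates", "PopulationParameters", "IndividualParameters",
    "DosingEvent", "PKState", "ConcentrationProfile",
    "compute_ffm", "compute_bsa", "compute_nfm", "maturation_fraction",
    "gst_multiplier", "allometric_factors", "individual_parameters",
    "pk_rhs", "simulate_profile", "apply_residual",
]

WEEKS_PER_YEAR = 52.1775
#: assay lower limit of quantification, mg/L (10 ng/mL)
LLOQ = 0.010

# reference (standard) subject for allometric scaling
STD_WT = 70.0
STD_HT = 176.0
STD_SEX = "male"


def compute_ffm(wt: float, ht: float, sex: str) -> float:
    """Fat-free mass (kg) from the Janmahasatian height/weight equations.

    wt in kg, ht in cm.  Males: 9.27e3·W/(6.68e3+216·BMI) in its
    height-weight form 42.92·H²·W/(30.93·H²+W); females use the
    corresponding 37.99/35.98 coefficients (H in metres).
    """
    if wt <= 0 or ht <= 0:
        raise ValueError("wt and ht must be positive")
    h = ht / 100.0
    if sex == "male":
        ffm = 42.92 * h * h * wt / (30.93 * h * h + wt)
    elif sex == "female":
        ffm = 37.99 * h * h * wt / (35.98 * h * h + wt)
    else:
        raise ValueError(f"unknown sex: {sex!r}")
    # the adult-derived equation can exceed WT in underweight children;
    # fat-free mass is bounded by total weight
    return min(ffm, wt)


def compute_bsa(wt: float, ht: float) -> float:
    """Body surface area (m²), Mosteller formula."""
    if wt <= 0 or ht <= 0:
        raise ValueError("wt and ht must be positive")
    return math.sqrt(wt * ht / 3600.0)


STD_FFM = compute_ffm(STD_WT, STD_HT, STD_SEX)
STD_BSA = compute_bsa(STD_WT, STD_HT)


def compute_nfm(ffm: float, wt: float, ffat: float) -> float:
    """Normal fat mass: NFM = FFM + Ffat·(WT − FFM).

    Ffat is the parameter-specific fraction of fat mass that contributes to
    the size descriptor (0 → FFM, 1 → total WT).
    """
    if not 0 < ffm <= wt:
        raise ValueError("require 0 < ffm <= wt")
    if ffat < 0:
        raise ValueError("ffat must be >= 0")
    return ffm + ffat * (wt - ffm)


def maturation_fraction(pma: float, tm50: float, hill: float) -> float:
    """Sigmoid maturation of clearance: F = 1/(1 + (PMA/TM50)^(−Hill)).

    PMA and TM50 in weeks.  F(TM50) = 1/2 and F → 1 as PMA → ∞.
    """
    if pma <= 0 or tm50 <= 0 or hill <= 0:
        raise ValueError("pma, tm50 and hill must be positive")
    return 1.0 / (1.0 + (pma / tm50) ** (-hill))


def gst_multiplier(gst: float, theta_gst: float, gst_ref: float) -> float:
    """Exponential GST-activity effect on S_GSH, centered at the cohort
    median activity: exp(theta_gst·(GST/GST_ref − 1))."""
    if gst_ref <= 0:
        raise ValueError("gst_ref must be positive")
    if gst < 0:
        raise ValueError("gst must be >= 0")
    return math.exp(theta_gst * (gst / gst_ref - 1.0))


@dataclass(frozen=True)
class SubjectCovariates:
    """Demographics and GST activity of one (real or virtual) subject."""

    id: str
    sex: str = "male"
    postnatal_age: float = 1.4          # years
    gestational_age: float = 38.5       # weeks
    wt: float = 9.9                     # kg
    ht: float | None = None             # cm
    ffm: float | None = None            # kg; computed from wt/ht/sex if None
    gst: float = 9.2                    # nmol/min/mL
    comedication_flags: frozenset = frozenset()

    def __post_init__(self):
        if self.wt <= 0:
            raise ValueError("wt must be positive")
        if self.postnatal_age < 0:
            raise ValueError("postnatal_age must be >= 0")
        if self.gestational_age <= 0:
            raise ValueError("gestational_age must be positive")
        if self.gst < 0:
            raise ValueError("gst must be >= 0")
        if self.ffm is None:
            if self.ht is None:
                raise ValueError("need ffm or ht to determine fat-free mass")
            object.__setattr__(self, "ffm", compute_ffm(self.wt, self.ht, self.sex))
        if not 0 < self.ffm <= self.wt + 1e-9:
            raise ValueError("require 0 < ffm <= wt")

    @property
    def pma(self) -> float:
        """Post-menstrual age in weeks."""
        return self.gestational_age + self.postnatal_age * WEEKS_PER_YEAR


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variance components and structural constants.

    Defaults are the final estimates of the pediatric intravenous-busulfan
    population analysis that this package reimplements (typical values
    standardized to a 70-kg adult): CL 9.57 L/h, Vc 28.2 L, Q 8.16 L/h,
    Vp 16.1 L; fat-mass fractions 0.905 (CL/Q) and 0.687 (Vc/Vp); TM50 45
    weeks, Hill 1.11; S_GSH fixed at 0.00259 h/mg with an exponential GST
    slope of 0.28 centered at 9.2 nmol/min/mL.  Variability: BSV 23.2 %
    (CL), 15.6 % (Vc), 40.0 % (Vp); IOV on CL 10.7 %; residual 11.1 %
    proportional + 0.0166 mg/L additive.  k_gsh (GSH turnover, h⁻¹) is a
    configuration constant, not an estimate.
    """

    theta_cl: float = 9.57       # L/h at standard adult size
    theta_vc: float = 28.2       # L
    theta_q: float = 8.16        # L/h
    theta_vp: float = 16.1       # L
    ffat_cl: float = 0.905
    ffat_vc: float = 0.687
    tm50: float = 45.0           # weeks PMA
    hill: float = 1.11
    s_gsh: float = 0.00259       # h/mg, scaled to 1-L central volume
    theta_gst: float = 0.28
    gst_ref: float = 9.2         # nmol/min/mL
    k_gsh: float = 0.1           # 1/h GSH turnover
    omega_cl: float = 0.232      # SD of log-scale BSV
    omega_vc: float = 0.156
    omega_vp: float = 0.400
    pi_cl: float = 0.107         # SD of log-scale IOV on CL
    sigma_prop: float = 0.111    # proportional residual SD (fraction)
    sigma_add: float = 0.0166    # additive residual SD (mg/L)

    def __post_init__(self):
        for name in ("theta_cl", "theta_vc", "theta_q", "theta_vp",
                     "tm50", "hill", "gst_ref", "k_gsh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("ffat_cl", "ffat_vc", "s_gsh", "omega_cl", "omega_vc",
                     "omega_vp", "pi_cl", "sigma_prop", "sigma_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def replace(self, **kw) -> "PopulationParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class IndividualParameters:
    """Realized PK parameters of one subject (one set of random effects)."""

    cl: float                    # L/h
    vc: float                    # L
    q: float                     # L/h
    vp: float                    # L
    s_gsh: float                 # h/mg
    eta: tuple = (0.0, 0.0, 0.0)
    kappa: tuple = ()

    def __post_init__(self):
        if min(self.cl, self.vc, self.q, self.vp) <= 0:
            raise ValueError("realized PK parameters must be positive")
        if self.s_gsh < 0:
            raise ValueError("s_gsh must be >= 0")


@dataclass(frozen=True)
class DosingEvent:
    start_time: float            # h
    amount: float                # mg
    infusion_duration: float = 2.0

    def __post_init__(self):
        if self.amount < 0:
            raise ValueError("amount must be >= 0")
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be positive")


@dataclass
class PKState:
    """Instantaneous model state (amounts mg, normalized GSH pool, mg·h/L)."""

    a_central: float = 0.0
    a_periph: float = 0.0
    a_gsh: float = 1.0
    auc: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.a_central, self.a_periph, self.a_gsh, self.auc])


@dataclass
class ConcentrationProfile:
    """Simulated concentration-time curve with regimen exposure summaries."""

    times: np.ndarray            # requested observation times, h
    conc: np.ndarray             # mg/L at `times`
    cauc: float                  # cumulative AUC to the horizon, mg·h/L
    cmax: float                  # max concentration on the dense grid, mg/L
    dense_times: np.ndarray = field(default=None, repr=False)  # type: ignore
    dense_conc: np.ndarray = field(default=None, repr=False)   # type: ignore
    gsh: np.ndarray = field(default=None, repr=False)          # type: ignore


def allometric_factors(cov: SubjectCovariates, pop: PopulationParameters,
                       size_metric: str = "NFM") -> tuple[float, float]:
    """(clearance-side, volume-side) allometric scaling factors.

    Clearance-like parameters scale with exponent 0.75 and volume-like with
    exponent 1 of the chosen size metric relative to the standard adult.
    For NFM the standard subject's NFM uses the same estimated Ffat, so the
    factor is exactly 1 for the standard subject.
    """
    if size_metric == "NFM":
        nfm_cl = compute_nfm(cov.ffm, cov.wt, pop.ffat_cl)
        nfm_v = compute_nfm(cov.ffm, cov.wt, pop.ffat_vc)
        std_cl = compute_nfm(STD_FFM, STD_WT, pop.ffat_cl)
        std_v = compute_nfm(STD_FFM, STD_WT, pop.ffat_vc)
        return (nfm_cl / std_cl) ** 0.75, nfm_v / std_v
    if size_metric == "FFM":
        r = cov.ffm / STD_FFM
        return r ** 0.75, r
    if size_metric == "WT":
        r = cov.wt / STD_WT
        return r ** 0.75, r
    if size_metric == "BSA":
        if cov.ht is None:
            raise ValueError("BSA size metric requires height")
        r = compute_bsa(cov.wt, cov.ht) / STD_BSA
        return r ** 0.75, r
    raise ValueError(f"unknown size metric: {size_metric!r}")


def individual_parameters(
    pop: PopulationParameters,
    cov: SubjectCovariates,
    eta: Sequence[float] = (0.0, 0.0, 0.0),
    kappa_occ: float = 0.0,
    size_metric: str = "NFM",
    maturation: bool = True,
    gst_covariate: bool = True,
) -> IndividualParameters:
    """Realize individual PK parameters from covariates and random effects.

    eta = (eta_cl, eta_vc, eta_vp) log-scale deviations; kappa_occ is a
    single log-scale inter-occasion deviation applied to CL (for regimens
    spanning several occasions, occasion-wise kappas are applied during
    simulation instead).  With all random effects zero this returns the
    typical subject.
    """
    e = np.asarray(eta, dtype=float)
    if e.shape != (3,) or not np.all(np.isfinite(e)):
        raise ValueError("eta must be 3 finite values (cl, vc, vp)")
    f_cl, f_v = allometric_factors(cov, pop, size_metric)
    fmat = maturation_fraction(cov.pma, pop.tm50, pop.hill) if maturation else 1.0
    cl = pop.theta_cl * f_cl * fmat * math.exp(e[0] + kappa_occ)
    vc = pop.theta_vc * f_v * math.exp(e[1])
    q = pop.theta_q * f_cl
    vp = pop.theta_vp * f_v * math.exp(e[2])
    s = pop.s_gsh
    if gst_covariate:
        s *= gst_multiplier(cov.gst, pop.theta_gst, pop.gst_ref)
    return IndividualParameters(cl=cl, vc=vc, q=q, vp=vp, s_gsh=s,
                                eta=tuple(e), kappa=(kappa_occ,))


def pk_rhs(t: float, state: np.ndarray, ind: IndividualParameters,
           infusion_rate: float, k_gsh: float) -> np.ndarray:
    """Right-hand side of the ODE system; state = [A1, A2, A_GSH, AUC]."""
    a1, a2, g = state[0], state[1], state[2]
    k10 = ind.cl / ind.vc
    da1 = (infusion_rate - k10 * g * a1
           - (ind.q / ind.vc) * a1 + (ind.q / ind.vp) * a2)
    da2 = (ind.q / ind.vc) * a1 - (ind.q / ind.vp) * a2
    dg = k_gsh * (1.0 - g) - (ind.s_gsh / ind.vc) * g * k10 * a1
    dauc = a1 / ind.vc
    return np.array([da1, da2, dg, dauc])


def simulate_profile(
    ind: IndividualParameters,
    regimen: Sequence[DosingEvent],
    obs_times: Sequence[float] | np.ndarray = (),
    k_gsh: float = 0.1,
    dt: float = 0.05,
    horizon: float | None = None,
    kappa_by_occasion: Sequence[float] | None = None,
    occasion_bounds: Sequence[float] = (),
    grid: Grid | None = None,
) -> ConcentrationProfile:
    """Simulate a noise-free concentration profile for one regimen.

    cAUC is the AUC state integrated to ``horizon`` (default: end of the
    last infusion + 72 h, by which the residual tail is negligible at
    typical half-lives); Cmax is the maximum on the dense grid (step
    ``dt``).  ``kappa_by_occasion`` applies occasion-wise log-scale IOV
    deviations to CL over the windows delimited by ``occasion_bounds``.
    """
    regimen = sorted(regimen, key=lambda d: d.start_time)
    if grid is None:
        if horizon is None and regimen:
            horizon = max(d.start_time + d.infusion_duration for d in regimen) + 72.0
        grid = build_grid(regimen, obs_times, horizon=horizon, dt=dt,
                          occasion_bounds=occasion_bounds)
    clmult = grid.clmult(None if kappa_by_occasion is None
                         else np.asarray(kappa_by_occasion, dtype=float))
    conc, gsh, auc = integrate_grid(grid.times, grid.rates, clmult,
                                    ind.cl, ind.vc, ind.q, ind.vp,
                                    ind.s_gsh, k_gsh)
    if not np.all(np.isfinite(conc)):
        raise RuntimeError("integration produced non-finite concentrations")
    return ConcentrationProfile(
        times=np.asarray(obs_times, dtype=float),
        conc=conc[grid.obs_idx],
        cauc=float(auc[-1]),
        cmax=float(np.max(conc)),
        dense_times=grid.times,
        dense_conc=conc,
        gsh=gsh,
    )


def apply_residual(conc, sigma_prop: float, sigma_add: float,
                   rng: np.random.Generator):
    """Combined proportional + additive residual model:
    y = c·(1 + eps_p) + eps_a with independent zero-mean Gaussians."""
    if sigma_prop < 0 or sigma_add < 0:
        raise ValueError("residual SDs must be >= 0")
    c = np.asarray(conc, dtype=float)
    y = c * (1.0 + sigma_prop * rng.standard_normal(c.shape)) \
        + sigma_add * rng.standard_normal(c.shape)
    return y if c.shape else float(y)
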