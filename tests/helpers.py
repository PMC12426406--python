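"""Independent oracles and tiny toy models used across the test suite.

Everything here is deliberately implemented without touching the package's
integration/estimation code paths: the linear two-compartment solution uses
piecewise matrix exponentials, and the toy marginal likelihood uses
Gauss-Hermite quadrature.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from busulfanpk.estimation import FoceModel


def linear_two_compartment(cl, vc, q, vp, doses, times):
    """Exact concentration and AUC of the linear (no GSH depletion)
    two-compartment multiple-infusion model.

    Propagates the affine system z' = M z (z = [A1, A2, AUC, 1]) exactly
    across the piecewise-constant infusion schedule with matrix
    exponentials.  ``doses``: iterable of (start, amount, duration).
    Returns (conc, auc) arrays at ``times``.
    """
    times = np.asarray(times, dtype=float)
    knots = {0.0}
    for s, a, d in doses:
        knots.add(float(s))
        knots.add(float(s + d))
    knots.update(times.tolist())
    knots = np.array(sorted(knots))
    A = np.array([[-(cl + q) / vc, q / vp],
                  [q / vc, -q / vp]])
    z = np.zeros(4)
    z[3] = 1.0
    out_c = {}
    out_a = {}
    if 0.0 in times:
        pass
    out_c[0.0] = 0.0
    out_a[0.0] = 0.0
    for lo, hi in zip(knots[:-1], knots[1:]):
        rate = sum(a / d for s, a, d in doses if s <= lo + 1e-12 < s + d - 1e-12)
        M = np.zeros((4, 4))
        M[:2, :2] = A
        M[0, 3] = rate
        M[2, 0] = 1.0 / vc
        z = expm(M * (hi - lo)) @ z
        out_c[float(hi)] = z[0] / vc
        out_a[float(hi)] = z[2]
    conc = np.array([out_c[float(t)] for t in times])
    auc = np.array([out_a[float(t)] for t in times])
    return conc, auc


@dataclass
class ToyPop:
    """One-compartment IV-bolus population with a single eta on CL."""

    cl: float = 2.0
    v: float = 10.0
    omega: float = 0.3
    sigma_prop: float = 0.0
    sigma_add: float = 0.1


@dataclass
class ToySubject:
    id: str
    dose: float
    obs_times: np.ndarray
    y: np.ndarray

    @property
    def n_obs(self):
        return len(self.y)


class ToyBolusModel(FoceModel):
    """f(t) = (D/V) exp(-CL e^eta t / V); analytic, no ODE."""

    n_eta = 1

    def predict(self, params, subj, eta, kappa):
        pop = params[0]
        k = pop.cl * math.exp(float(np.asarray(eta)[0])) / pop.v
        return (subj.dose / pop.v) * np.exp(-k * subj.obs_times)

    def omegas(self, params):
        return np.array([params[0].omega])

    def sigmas(self, params):
        return params[0].sigma_prop, params[0].sigma_add


def simulate_estimation_subjects(spec, betas, pop, n=18, seed=0,
                                 n_doses=4, comed_prevalence=0.0):
    """Simulate subjects directly through the estimation model (short
    4-dose design) so covariate effects on CL can be switched on in truth.
    Returns a list of prepared SubjectData."""
    from busulfanpk import model_core as mc
    from busulfanpk import estimation as est
    from busulfanpk.data_io import SubjectData
    from busulfanpk.synthetic_data import DemographicsSpec, StudyDesign, \
        generate_population
    from busulfanpk.virtual_trial import wt_band_dose

    rng = np.random.default_rng(seed)
    design = StudyDesign(n_doses=n_doses, dose1_samples=(2.0, 4.0),
                         trough_before_doses=(n_doses,),
                         final_samples_group_a=(2.0, 6.0),
                         final_samples_group_b=(2.0, 6.0))
    covs = generate_population(
        DemographicsSpec(n_subjects=n, comed_prevalence=comed_prevalence),
        seed)
    model = est.BusulfanFoce(spec)
    subjects = []
    for cov in covs:
        dose_mg = wt_band_dose(cov.wt) * cov.wt
        doses = [mc.DosingEvent(6.0 * k, dose_mg, 2.0)
                 for k in range(n_doses)]
        times = design.observation_times("A")
        s = SubjectData(id=cov.id, covs=cov, doses=doses, obs_times=times,
                        y=np.zeros(len(times)),
                        obs_occ=np.ones(len(times), dtype=int))
        s.build_grid(dt=0.1)
        eta = np.zeros(len(spec.eta_params))
        eta[0] = rng.normal(0, pop.omega_cl)
        f = model.predict((pop, betas), s, eta, np.zeros(0))
        s.y = mc.apply_residual(f, pop.sigma_prop, pop.sigma_add, rng)
        subjects.append(s)
    return subjects


def toy_neg2ll_quadrature(model, subj, params, n_nodes=96):
    """-2 log of the exact marginal likelihood of a one-eta toy subject via
    Gauss-Hermite quadrature (the FOCE oracle)."""
    pop = params[0]
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    total = 0.0
    for z, w in zip(nodes, weights):
        eta = math.sqrt(2.0) * pop.omega * z
        f = model.predict(params, subj, np.array([eta]), np.zeros(0))
        v = (f * pop.sigma_prop) ** 2 + pop.sigma_add ** 2
        loglik = -0.5 * np.sum(np.log(2.0 * np.pi * v)
                               + (subj.y - f) ** 2 / v)
        total += w / math.sqrt(math.pi) * math.exp(loglik)
    return -2.0 * math.log(total)
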