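# Methods

## The model

`busulfanpk` implements a semi-mechanistic population-pharmacokinetic model
of intravenous busulfan in pediatric hematopoietic-cell-transplant (HCT)
recipients.  Busulfan is cleared almost entirely by conjugation with
glutathione (GSH), mostly catalysed by glutathione S-transferases (GST).
Because each conjugation event consumes a GSH molecule, sustained q6h dosing
can deplete the cofactor pool and slow elimination over the course of
conditioning.  The structural model is a two-compartment disposition system
with zero-order (infusion) drug input whose elimination clearance is scaled
by a normalized, depletable GSH pool A_GSH ∈ (0, 1]:

    dA1/dt    = rate_in(t) − (CL·A_GSH/Vc)·A1 − (Q/Vc)·A1 + (Q/Vp)·A2
    dA2/dt    = (Q/Vc)·A1 − (Q/Vp)·A2
    dA_GSH/dt = k_GSH·(1 − A_GSH) − (S_GSH/Vc)·A_GSH·k10·A1,   k10 = CL/Vc
    dAUC/dt   = A1/Vc

A_GSH(0) = 1.  The depletion term removes a fraction S_GSH of the remaining
pool per milligram of busulfan metabolized (scaled to a 1-L central volume);
the pool is resynthesized toward baseline with first-order rate k_GSH, whose
implied zero-order synthesis rate equals elimination at equilibrium.  The
depletion term enters with a negative sign (conjugation consumes GSH).

Covariates:

* **Body size** — normal fat mass, NFM = FFM + Ffat·(WT − FFM), with a
  parameter-class-specific fat fraction Ffat (0.905 for clearances, 0.687
  for volumes).  CL and Q scale as (NFM/NFM_std)^0.75; Vc and Vp as
  (NFM/NFM_std)^1.  The standard subject is a 70-kg, 176-cm adult male
  (FFM_std 56.1 kg by the Janmahasatian height-weight equations); NFM_std
  uses the same Ffat as the individual, so the scaling factor is exactly 1
  for the standard subject.  FFM is clamped at WT because the adult-derived
  equation can exceed total weight in underweight children.
* **Maturation** — a sigmoid fraction of adult clearance driven by
  post-menstrual age (PMA = gestational age + postnatal age, 52.1775
  weeks/year): F_mat = 1/(1 + (PMA/TM50)^(−Hill)), TM50 = 45 wk,
  Hill = 1.11.  F_mat applies to CL only.
* **GST activity** — an exponential multiplier on the depletion factor,
  S_GSH,i = S_GSH · exp(θ_GST·(GST/9.2 − 1)), centered at the cohort median
  activity of 9.2 nmol·min⁻¹·mL⁻¹ with slope θ_GST = 0.28.  Higher measured
  GST activity means faster conjugation and hence faster GSH depletion.

Random effects: log-normal between-subject variability (BSV) on CL, Vc and
Vp (none on Q), log-normal inter-occasion variability (IOV) on CL with a
variance shared across occasions, and combined proportional + additive
residual error, y = c·(1 + ε_p) + ε_a.

### Default parameter values

The defaults in `PopulationParameters` are the final estimates of the
published pediatric analysis this package reimplements: CL 9.57 L/h,
Vc 28.2 L, Q 8.16 L/h, Vp 16.1 L (70-kg standardized), Ffat_CL 0.905,
Ffat_Vc 0.687, TM50 45 wk, Hill 1.11, S_GSH 0.00259 h/mg (fixed, i.e. a
0.26 %/h pool reduction per mg metabolized at 1 L central volume), θ_GST
0.28; BSV 23.2/15.6/40.0 % (CL/Vc/Vp), IOV-CL 10.7 %, residual 11.1 %
proportional + 0.0166 mg/L additive.  Variability percentages are treated
as SDs of the log-scale effects.  Two printed-unit ambiguities in the
source material are resolved on physiological grounds and carried through
consistently: the additive residual SD is 0.0166 mg/L (16.6 µg/L — an
additive error of 16.6 mg/L would exceed every observed concentration
tenfold), and the Cmax safety limit is 1.88 mg/L.  The GSH turnover rate
k_GSH is not identifiable from published information and is a
configuration constant, default 0.1 h⁻¹; at that value the pool dips only
~1-2 % during conditioning, so exposure is only mildly super-linear.

### Numerical integration

The GSH coupling makes elimination state-dependent, so profiles are
integrated numerically: a fixed-step classical RK4 kernel (numba-compiled)
on an event-aligned grid whose knots include every infusion start/stop,
observation time and occasion boundary.  The forcing function and the
occasion-wise clearance multiplier are therefore exactly piecewise constant
within a step and RK4 keeps full order; against the exact matrix-exponential
solution of the linear (S_GSH = 0) limit the kernel agrees to better than
1e-6 relative at the default steps (0.05 h for exposure simulation, 0.1 h
during estimation), comfortably inside the 1e-4 assertion used in tests.
cAUC is an integrator state read at the horizon — end of last infusion
+ 72 h, where the residual tail is < 0.1 % at typical half-lives; no
log-linear extrapolation is applied.  Cmax is the maximum of the dense
grid over the whole regimen.

## Estimation (FOCE-I)

The marginal likelihood is approximated subject-by-subject by a Laplace
expansion at the conditional mode of the random effects
u = (η_CL, η_Vc, η_Vp, κ_1..κ_4), with the residual variance evaluated at
the conditional prediction (η-ε interaction):

    OFV_i = −2 log p(y_i, û_i) − d·log 2π + log det H_i
    H_i   = Σ_j F_j F_jᵀ (1/v_j + 2 f_j² σ_p⁴ / v_j²) + Ω⁻¹

where F_j = ∂f_j/∂u at the mode (finite differences) and H is the
Fisher/Gauss-Newton curvature, which also drives the damped Newton inner
search (gradient tolerance 1e-8, warm-started across outer iterations).
On one-η toy problems the objective agrees with adaptive Gauss-Hermite
quadrature of the exact marginal likelihood to well under 0.5.

The outer problem minimizes the summed OFV over log-transformed population
parameters with a projected BFGS and Armijo backtracking.  Gradients use
forward differences with step 1e-3 on the log scale — deliberately large so
that the finite-difference signal dominates the ~1e-5 evaluation noise
introduced by warm-started inner optimizations — and trial steps are capped
at 1.5 log units, which makes the search robust to the non-finite plateau
returned when a trial parameter set breaks the inner problem.  Standard
errors come from the inverse central-difference Hessian of the OFV (delta
method back to the natural scale); the condition number is the
extreme-eigenvalue ratio of the resulting correlation matrix.  AIC = OFV +
2p and BIC = OFV + p·log n use the number of observations as n.

By default the fits estimate the four structural θ's, the three ω's, π and
the two σ's, and fix the covariate-shape constants (Ffat's, TM50, Hill,
θ_GST, S_GSH, k_GSH) at their configured values: a pediatric-only cohort
cannot identify TM50/Hill jointly with the allometric reference scaling,
and S_GSH is fixed in the reference analysis itself.  `ModelSpec` exposes
all of these as flags, together with the candidate size metrics (WT, BSA
via Mosteller, FFM, NFM), maturation/GST/IOV switches, and covariate
effects in linear, exponential, power, or fractional (categorical) form for
the stepwise search (forward ΔOFV > 3.84, backward retention ΔOFV > 10.83).

Occasions follow the sampling structure of the 12-dose study: κ windows
[0, 6), [6, 30), [30, 66), [66, ∞) h, i.e. the dose-1 profile, the run-in
to each trough, and the post-dose-12 profile.  Observations below the
0.010 mg/L quantification limit are excluded at generation time.

## Evaluation

* **pcVPC** — observations and simulated replicates are scaled by
  median(PRED in bin)/PRED_i on equal-count time-after-dose bins (default
  8); bands are the 2.5-97.5 % envelope of each binned 5th/50th/95th
  percentile over the simulation replicates (default 2,000).  Observed
  covariates and designs are reused in the simulations.
* **Bootstrap** — plain subject resampling with replacement; each replicate
  refitted from the original estimates; non-converged replicates are
  excluded and counted, and the result is flagged unreliable below 50 %
  convergence.
* **Prediction metrics** — MDPE, MAPE and F20/F30 of PE% = 100·(pred −
  obs)/obs on population (η = 0) predictions; an option for MAP-based
  forecasts is out of scope here.

## Virtual trial and dose optimization

Each virtual subject receives 16 q6h 2-h infusions.  Per replicate
(default 200; the acceptance checks use 2,000), fresh η and day-wise κ
(windows of 24 h) are drawn and the regimen is simulated noise-free —
exposure targets are defined on true concentrations, and the tabulated
interval widths are consistent with BSV+IOV only.  PTA(cAUC) is the
fraction of replicates with cAUC in 78-101 mg·h/L; PTA(Cmax) the fraction
with regimen-wide Cmax < 1.88 mg/L.  Both 2.5-97.5 and 5-95 percentile
pairs are reported; the printed "95% CI" intervals match the 5-95 pair
(±1.645σ of the lognormal).  Random draws are keyed by (seed, subject
index) only, so strategies prescribing equal doses produce bitwise
identical results, and the dose-grid search (0.80-1.20 mg/kg, step 0.05)
uses common random numbers, making PTA(dose) smooth and unimodal.  The
recommended dose maximizes PTA(cAUC) subject to PTA(Cmax) ≥ a configurable
floor (default 100 %), ties breaking toward the lower dose; if no dose
meets the floor the best-PTA dose is returned flagged unsafe.

### Fidelity to the tabulated trial cells

With the documented reference-scaling and covariate-form choices, the
model's typical-patient clearance is ~1.63 L/h while the tabulated medians
imply ~1.74 L/h; simulated median cAUCs therefore sit systematically ~7-10 %
above the printed values, at the edge of the 10 % acceptance band, and grid
optima can shift one to two 0.05-mg/kg steps below the printed optimum.
The simulated Cmax distribution is higher still relative to the printed
PTA(Cmax) values: the reference analysis describes its base model as using
"first-order absorption" (with CL/F reporting), and a first-order input
stage would flatten infusion peaks substantially; this package models the
IV input as the zero-order 2-h infusion that was actually administered, so
PTA(Cmax) is not reproducible under this structural reading.  These
discrepancies are structural, not tunable, and are asserted as documented
in the acceptance suite.

## Synthetic data

The generator emulates the study: 65 (or any n) subjects, 12 weight-banded
doses (0.8-1.2 mg/kg), samples at 2/2.5/3/4/6 h after dose 1, troughs
before doses 6 and 12, and post-dose-12 samples at 2/4/8 h (Group A) or
2/6/12 h (Group B), alternating subjects between groups.  Demographics
reproduce the cohort marginals: log-normal age (median 1.4 y, truncated to
0.2-14.1), gestational age ~N(38.5, 1.5²) wk truncated to 30-42, GST
log-normal (median 9.2, log-SD 0.55, truncated to 0.9-20.7), male fraction
40/55.  Weight and height come from a smooth reference growth curve
anchored through the cohort medians with 15 %/4 % log-normal noise,
truncated to the observed ranges; FFM follows from weight/height/sex.  Only
marginals are reproduced — the generator imposes no age-GST correlation and
no real-world correlation structure beyond the growth curve, so passing
recovery tests demonstrates internal consistency of the estimation
machinery under the stated design, not robustness to the unobserved joint
covariate distribution of real patients.  Comedication (fludarabine) is
sampled at 50 % prevalence with zero effect, matching its exclusion from
the final covariate model.

## Problem sizes used in the checks

Parameter recovery uses 55 subjects (~550 observations) per replicate
study over three seeds; the stepwise-search calibration uses 20 replicate
15-subject short-design studies; pcVPC calibration uses 20-subject studies
with 400 simulation replicates; virtual-trial checks use 2,000 replicates
per subject (8,000 for the analytic lognormal cross-check).  These sizes
were chosen to keep every Monte-Carlo tolerance comfortably above its
sampling noise.

## Known limitations

* No hepatic/blood GSH partitioning and no absolute GSH concentrations —
  the pool is a normalized latent state, and k_GSH is a convention, not an
  estimate.
* No oral busulfan, no absorption stage, no TDM/MAP dose adaptation.
* The stepwise covariate machinery assumes nested candidates; non-nested
  comparisons fall back to AIC/BIC.
* FOCE-I is the only estimator (no SAEM/importance sampling), and random
  effects are assumed independent (no Ω covariances), matching the
  reference analysis.
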