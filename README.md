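# busulfanpk

Semi-mechanistic population pharmacokinetics of intravenous busulfan in
pediatric allogeneic hematopoietic-cell-transplant (HCT) recipients.

Busulfan is the backbone of myeloablative conditioning before HCT, with a
narrow therapeutic window: cumulative exposure (cAUC) below ~78 mg·h/L
risks graft failure and relapse, above ~101 mg·h/L risks severe toxicity,
and high peak concentrations (Cmax ≥ 1.88 mg/L) are associated with
sinusoidal obstructive syndrome.  Children show large between-subject and
between-occasion variability, partly because busulfan is cleared by
glutathione (GSH) conjugation — catalysed by glutathione S-transferases
(GST) — and the q6h regimen itself depletes the GSH pool over the 4-day
course.

This package implements, estimates and exercises the model end to end, for
pharmacometricians and methodologists who want a self-contained, testable
reimplementation:

* **model_core** — two-compartment infusion kinetics whose clearance is
  scaled by a normalized, depletable GSH pool
  (dA_GSH/dt = k_GSH(1 − A_GSH) − (S_GSH/Vc)·A_GSH·k10·A1), with normal-fat-
  mass (NFM) allometry, a sigmoid post-menstrual-age maturation function
  F_mat = 1/(1 + (PMA/TM50)^(−Hill)) on CL, and an exponential GST-activity
  effect on S_GSH.  Fast event-aligned RK4 simulation with running AUC.
* **estimation** — FOCE with η-ε interaction (Laplace at the conditional
  mode of the subject/occasion random effects), model comparison
  (OFV/AIC/BIC, condition number), stepwise covariate search
  (ΔOFV > 3.84 / > 10.83), shrinkage, CWRES; NONMEM-like event-record
  datasets in delimited text.
* **evaluation** — prediction-corrected VPC, nonparametric bootstrap,
  MDPE/MAPE/F20/F30 prediction metrics, tabular goodness-of-fit.
* **virtual_trial** — Monte-Carlo probability of target attainment
  (cAUC 78–101 mg·h/L, Cmax < 1.88 mg/L) for weight-band and age-band
  dosing strategies, and grid-search dose optimization
  (0.80–1.20 mg/kg, step 0.05).
* **synthetic_data** — virtual populations matching the study cohort's
  demographic envelope and the full 12-dose, 10-sample/subject sampling
  design, so the whole pipeline is testable without any patient data.

See `docs/methods.md` for the model, assumptions, numerical choices and
known limitations.

## Worked example

```python
import numpy as np
from busulfanpk import model_core as mc, virtual_trial as vt

pop = mc.PopulationParameters()          # reference estimates
patient = vt.TYPICAL_PATIENT             # 1.4 y, 9.9 kg, GST 10.12

ind = mc.individual_parameters(pop, patient)
print(f"typical CL = {ind.cl:.3f} L/h, Vc = {ind.vc:.3f} L")

regimen = [mc.DosingEvent(6.0 * k, 1.0 * patient.wt, 2.0) for k in range(16)]
prof = mc.simulate_profile(ind, regimen, obs_times=[2.0, 92.0], k_gsh=pop.k_gsh)
print(f"cAUC = {prof.cauc:.1f} mg*h/L, Cmax = {prof.cmax:.2f} mg/L, "
      f"GSH pool minimum = {prof.gsh.min():.3f}")

spec = vt.TrialSpec(n_rep=2000, seed=1)
row = vt.run_virtual_trial([patient], vt.AGE_BAND, pop, spec).iloc[0]
print(f"1 mg/kg q6h x16: median cAUC {row['cauc_median']:.1f} "
      f"(90% interval {row['cauc_p5']:.1f}-{row['cauc_p95']:.1f}) mg*h/L, "
      f"PTA(cAUC 78-101) = {row['pta_cauc']:.1f}%")
rec = vt.optimize_dose(patient, pop, spec, cmax_floor=0.0)
print(f"optimal dose on the 0.80-1.20 grid: {rec.dose_mgkg} mg/kg")
```

prints

```
typical CL = 1.626 L/h, Vc = 4.104 L
cAUC = 98.3 mg*h/L, Cmax = 1.69 mg/L, GSH pool minimum = 0.989
1 mg/kg q6h x16: median cAUC 97.9 (90% interval 67.2-145.3) mg*h/L, PTA(cAUC 78-101) = 38.2%
optimal dose on the 0.80-1.20 grid: 0.95 mg/kg
```

Reading this: the 1.4-year-old, 9.9-kg typical patient has a clearance of
1.63 L/h (the 9.57 L/h adult value scaled down by NFM allometry and ~73 %
maturation).  Sixteen 2-h infusions of 1 mg/kg every 6 h put the noise-free
cumulative AUC at 98.3 mg·h/L — inside the 78–101 mg·h/L target window —
while the GSH pool dips only ~1 %.  Across 2,000 virtual replicates drawing
between-subject and day-to-day variability, 38 % of patients land inside the
window at that dose; the grid search prefers 0.95 mg/kg, which centers the
exposure distribution on the window.

The same pipeline is scriptable from the shell (each command takes a YAML
config and writes CSV tables with reproducibility metadata):

```sh
busulfanpk generate --config gen.yaml --out data/
busulfanpk fit --config fit.yaml --data data/dataset.csv --out fit/
busulfanpk evaluate --config ev.yaml --data data/dataset.csv --what vpc --out vpc.csv
busulfanpk trial --config trial.yaml --out trial.csv
busulfanpk optimize --config trial.yaml --out optimal.csv
```

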