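"""Virtual pediatric HCT populations and full study datasets.

The generator emulates the sampling design and demographic envelope of the
prospective pediatric busulfan study the package reimplements: 12 doses of
0.8-1.2 mg/kg (weight-banded) as 2-h IV infusions every 6 h; a rich profile
after dose 1 (2, 2.5, 3, 4, 6 h), troughs before doses 6 and 12, and three
post-dose-12 samples at 2/4/8 h (Group A) or 2/6/12 h (Group B, ~50/50
split).  Demographics follow the published cohort's marginals: age median
1.4 y (range 0.2-14.1), weight 2.9-29.5 kg, GST activity median 9.2
nmol/min/mL (0.9-20.7), gestational age ~38.5 wk.  Weight and height are
generated from age via a smooth reference growth curve with log-normal
noise, since only marginal medians/ranges are reported; no age-GST
correlation is imposed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_core as mc
from .data_io import COLUMNS, Dataset, STUDY_OCCASION_BOUNDS
from .virtual_trial import wt_band_dose

__all__ = ["DemographicsSpec", "StudyDesign", "generate_population",
           "generate_study_dataset"]

# age (y) -> median weight (kg) and height (cm) anchors; interpolated on
# log-age.  Anchored to pass through the cohort medians (1.4 y, 9.9 kg,
# 76 cm); HCT candidates run lighter than healthy reference children.
_GROWTH_AGE = np.array([0.2, 0.5, 1.0, 1.4, 2.0, 4.0, 7.0, 10.0, 14.0])
_GROWTH_WT = np.array([4.4, 6.5, 8.8, 9.9, 11.3, 15.0, 20.0, 28.0, 42.0])
_GROWTH_HT = np.array([54.0, 63.0, 72.0, 76.0, 83.0, 98.0, 115.0, 131.0, 152.0])


@dataclass(frozen=True)
class DemographicsSpec:
    """Envelope of the virtual population (defaults mirror the study cohort)."""

    n_subjects: int = 55
    age_median: float = 1.4           # years
    age_sdlog: float = 1.0
    age_range: tuple = (0.2, 14.1)
    male_fraction: float = 40 / 55
    gage_mean: float = 38.5           # weeks
    gage_sd: float = 1.5
    gage_range: tuple = (30.0, 42.0)
    gst_median: float = 9.2           # nmol/min/mL
    gst_sdlog: float = 0.55
    gst_range: tuple = (0.9, 20.7)
    wt_cv: float = 0.15               # log-normal noise around the growth curve
    ht_cv: float = 0.04
    wt_range: tuple = (2.9, 29.5)
    ht_range: tuple = (52.0, 147.0)
    comedication: str = "fludarabine"
    comed_prevalence: float = 0.5

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")
        for lo, hi in (self.age_range, self.gage_range, self.gst_range,
                       self.wt_range, self.ht_range):
            if not lo < hi:
                raise ValueError("ranges must be ordered (lo < hi)")


@dataclass(frozen=True)
class StudyDesign:
    """The observed-study sampling design (12 doses, 10 samples/subject)."""

    n_doses: int = 12
    dose_interval: float = 6.0
    infusion_duration: float = 2.0
    dose1_samples: tuple = (2.0, 2.5, 3.0, 4.0, 6.0)
    trough_before_doses: tuple = (6, 12)
    final_samples_group_a: tuple = (2.0, 4.0, 8.0)
    final_samples_group_b: tuple = (2.0, 6.0, 12.0)
    lloq: float = mc.LLOQ
    occasion_bounds: tuple = STUDY_OCCASION_BOUNDS
    dt: float = 0.05

    def observation_times(self, group: str) -> np.ndarray:
        tau = self.dose_interval
        t = list(self.dose1_samples)
        t += [(k - 1) * tau for k in self.trough_before_doses]
        last = (self.n_doses - 1) * tau
        final = (self.final_samples_group_a if group == "A"
                 else self.final_samples_group_b)
        t += [last + s for s in final]
        return np.array(sorted(t))


def _truncated(draw, lo, hi, rng, max_tries=1000):
    """Rejection-sample a scalar from ``draw(rng)`` into [lo, hi]."""
    for _ in range(max_tries):
        x = draw(rng)
        if lo <= x <= hi:
            return x
    raise RuntimeError("infeasible truncation region in demographics spec")


def generate_population(spec: DemographicsSpec, seed: int
                        ) -> list[mc.SubjectCovariates]:
    """Sample virtual subjects satisfying the demographic envelope.

    Age and GST are truncated log-normals matching the cohort medians;
    weight/height come from the growth curve with log-normal noise,
    truncated to the cohort ranges; fat-free mass is computed from
    weight/height/sex (Janmahasatian).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(spec.n_subjects):
        age = _truncated(
            lambda r: np.exp(np.log(spec.age_median)
                             + spec.age_sdlog * r.standard_normal()),
            *spec.age_range, rng)
        sex = "male" if rng.random() < spec.male_fraction else "female"
        gage = _truncated(
            lambda r: spec.gage_mean + spec.gage_sd * r.standard_normal(),
            *spec.gage_range, rng)
        wt_med = np.exp(np.interp(np.log(age), np.log(_GROWTH_AGE),
                                  np.log(_GROWTH_WT)))
        ht_med = np.exp(np.interp(np.log(age), np.log(_GROWTH_AGE),
                                  np.log(_GROWTH_HT)))
        wt = _truncated(
            lambda r: wt_med * np.exp(spec.wt_cv * r.standard_normal()),
            *spec.wt_range, rng)
        ht = _truncated(
            lambda r: ht_med * np.exp(spec.ht_cv * r.standard_normal()),
            *spec.ht_range, rng)
        gst = _truncated(
            lambda r: np.exp(np.log(spec.gst_median)
                             + spec.gst_sdlog * r.standard_normal()),
            *spec.gst_range, rng)
        comeds = (frozenset([spec.comedication])
                  if rng.random() < spec.comed_prevalence else frozenset())
        subjects.append(mc.SubjectCovariates(
            id=f"S{i + 1:03d}", sex=sex, postnatal_age=float(age),
            gestational_age=float(gage), wt=float(wt), ht=float(ht),
            gst=float(gst), comedication_flags=comeds))
    return subjects


def generate_study_dataset(
    population: list[mc.SubjectCovariates],
    params: mc.PopulationParameters,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> Dataset:
    """Simulate the full study and return an event-record dataset.

    Per subject: weight-banded mg/kg dosing, random effects drawn from the
    population model, scheduled observations with combined residual noise;
    observations below the LLOQ (including noise-driven negatives) are
    excluded, as in the source analysis.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    records = []
    bounds = np.asarray(design.occasion_bounds)
    for i, cov in enumerate(population):
        group = "A" if i % 2 == 0 else "B"
        dose_mg = wt_band_dose(cov.wt) * cov.wt
        doses = [mc.DosingEvent(start_time=k * design.dose_interval,
                                amount=dose_mg,
                                infusion_duration=design.infusion_duration)
                 for k in range(design.n_doses)]
        obs_times = design.observation_times(group)
        eta = rng.standard_normal(3) * np.array(
            [params.omega_cl, params.omega_vc, params.omega_vp])
        kappa = rng.standard_normal(len(bounds) + 1) * params.pi_cl
        ind = mc.individual_parameters(params, cov, eta=eta)
        prof = mc.simulate_profile(
            ind, doses, obs_times, k_gsh=params.k_gsh, dt=design.dt,
            horizon=float(obs_times.max()), kappa_by_occasion=kappa,
            occasion_bounds=design.occasion_bounds)
        dv = mc.apply_residual(prof.conc, params.sigma_prop,
                               params.sigma_add, rng)
        base = {
            "ID": cov.id, "SEX": cov.sex, "AGE": cov.postnatal_age,
            "GAGE": cov.gestational_age, "WT": cov.wt,
            "HT": np.nan if cov.ht is None else cov.ht,
            "FFM": cov.ffm, "GST": cov.gst,
        }
        for d in doses:
            records.append({**base, "TIME": d.start_time, "AMT": d.amount,
                            "DUR": d.infusion_duration, "DV": np.nan,
                            "EVID": 1, "MDV": 1, "OCC": 0})
        occ = np.searchsorted(bounds, obs_times, side="left") + 1
        for t, y, o in zip(obs_times, dv, occ):
            if y < design.lloq:       # BQL: excluded from the analysis rows
                continue
            records.append({**base, "TIME": t, "AMT": 0.0, "DUR": 0.0,
                            "DV": float(y), "EVID": 0, "MDV": 0,
                            "OCC": int(o)})
    df = pd.DataFrame.from_records(records, columns=COLUMNS)
    # observations sort before a dose given at the same time (pre-dose draw)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        kind="stable").reset_index(drop=True)
    meta = {
        "generator": "busulfanpk.synthetic_data",
        "seed": seed,
        "n_subjects": len(population),
        "design": f"{design.n_doses} doses q{design.dose_interval}h "
                  f"{design.infusion_duration}h infusion",
        "concentration_unit": "mg/L",
    }
    return Dataset(df=df, meta=meta)
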