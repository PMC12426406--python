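"""End-to-end experiment orchestration shared by the CLI, tests and
reproduction scripts: simulate-then-refit parameter recovery, and the
headline virtual-trial tables."""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import model_core as mc
from .data_io import Dataset
from .estimation import FitResult, ModelSpec, fit
from .synthetic_data import DemographicsSpec, StudyDesign, \
    generate_population, generate_study_dataset
from .virtual_trial import AGE_BAND, EVALUATION_COHORT, TrialSpec, WT_BAND, \
    run_virtual_trial

__all__ = ["generate_study", "perturbed_initials", "parameter_recovery",
           "trial_table"]


def generate_study(seed: int, n_subjects: int = 55,
                   pop: mc.PopulationParameters | None = None,
                   demo: DemographicsSpec | None = None,
                   design: StudyDesign | None = None) -> Dataset:
    """Sample a virtual population and simulate the full study dataset."""
    pop = pop or mc.PopulationParameters()
    demo = demo or DemographicsSpec(n_subjects=n_subjects)
    population = generate_population(demo, seed)
    return generate_study_dataset(population, pop, design, seed + 1)


def perturbed_initials(truth: mc.PopulationParameters, spec: ModelSpec,
                       seed: int, spread: float = 0.3
                       ) -> mc.PopulationParameters:
    """Initial estimates displaced from the truth by up to ±spread on the
    log scale (deterministic per seed)."""
    rng = np.random.default_rng(seed + 7919)
    upd = {name: getattr(truth, name)
           * float(np.exp(rng.uniform(-spread, spread)))
           for name in spec.estimated}
    return truth.replace(**upd)


def parameter_recovery(
    seed: int,
    n_subjects: int = 55,
    truth: mc.PopulationParameters | None = None,
    spec: ModelSpec | None = None,
    **fit_kw,
) -> tuple[FitResult, mc.PopulationParameters, Dataset]:
    """Simulate a study at the reference parameters and refit by FOCE-I
    from perturbed initial estimates."""
    truth = truth or mc.PopulationParameters()
    spec = spec or ModelSpec()
    ds = generate_study(seed, n_subjects=n_subjects, pop=truth)
    init = perturbed_initials(truth, spec, seed)
    result = fit(ds, spec, init, **fit_kw)
    return result, truth, ds


def trial_table(pop: mc.PopulationParameters | None = None,
                spec: TrialSpec | None = None,
                subjects=EVALUATION_COHORT) -> pd.DataFrame:
    """Weight-band and age-band PTA results side by side, one row per
    virtual subject (the headline dosing-strategy comparison)."""
    pop = pop or mc.PopulationParameters()
    spec = spec or TrialSpec()
    wt = run_virtual_trial(subjects, WT_BAND, pop, spec)
    age = run_virtual_trial(subjects, AGE_BAND, pop, spec)
    merged = wt.merge(age, on="id", suffixes=("_wt", "_age"))
    return merged
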