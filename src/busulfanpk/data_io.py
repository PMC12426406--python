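"""NONMEM-like event-record datasets: in-memory container and delimited-text I/O.

One row per dose or observation.  Columns:

    ID    subject label
    TIME  h since first dose
    AMT   dose amount, mg (dose rows; 0 on observation rows)
    DUR   infusion duration, h (dose rows)
    DV    observed concentration, mg/L (observation rows)
    EVID  1 = dose, 0 = observation
    MDV   1 = DV missing/ignored, 0 = DV present
    OCC   occasion index (1-based) on observation rows
    SEX, AGE (years), GAGE (weeks), WT (kg), HT (cm), FFM (kg), GST
          subject covariates, repeated on every row

Files are comma-separated with '.' decimals; lines starting with '#' hold
``key: value`` metadata (seed, design, units) and are round-tripped.
Concentrations are serialized in mg/L.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import model_core as mc
from ._kernel import Grid, build_grid

__all__ = ["COLUMNS", "Dataset", "SubjectData", "read_dataset",
           "write_dataset", "subjects_from_dataframe"]

COLUMNS = ["ID", "TIME", "AMT", "DUR", "DV", "EVID", "MDV", "OCC",
           "SEX", "AGE", "GAGE", "WT", "HT", "FFM", "GST"]

#: occasion windows of the 12-dose study design (h); kappa_k applies to CL on
#: [b_{k-1}, b_k): dose-1 profile, run-in to the pre-dose-6 trough, run-in to
#: the pre-dose-12 trough, and the post-dose-12 profile.
STUDY_OCCASION_BOUNDS = (6.0, 30.0, 66.0)


@dataclass
class Dataset:
    """Event records plus file metadata."""

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_obs(self) -> int:
        return int(((self.df["EVID"] == 0) & (self.df["MDV"] == 0)).sum())

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        dose = df[df["EVID"] == 1]
        obs = df[(df["EVID"] == 0) & (df["MDV"] == 0)]
        if (dose["AMT"] <= 0).any():
            raise ValueError("dose rows must have AMT > 0")
        if (obs["DV"] < 0).any():
            raise ValueError("observation rows must have DV >= 0")
        if (df["TIME"] < 0).any():
            raise ValueError("times must be non-negative")
        for _, g in df.groupby("ID", sort=False):
            if not g["TIME"].is_monotonic_increasing:
                raise ValueError("times must be non-decreasing within subject")


@dataclass
class SubjectData:
    """One subject's records prepared for estimation/simulation."""

    id: str
    covs: mc.SubjectCovariates
    doses: list
    obs_times: np.ndarray
    y: np.ndarray
    obs_occ: np.ndarray
    grid: Grid = None  # type: ignore[assignment]

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def build_grid(self, dt: float = 0.1,
                   occasion_bounds=STUDY_OCCASION_BOUNDS) -> None:
        horizon = float(self.obs_times.max()) if self.n_obs else None
        self.grid = build_grid(self.doses, self.obs_times, horizon=horizon,
                               dt=dt, occasion_bounds=occasion_bounds)


def subjects_from_dataframe(df: pd.DataFrame, dt: float = 0.1,
                            occasion_bounds=STUDY_OCCASION_BOUNDS
                            ) -> list[SubjectData]:
    """Split an event-record table into per-subject estimation inputs."""
    out = []
    for sid, g in df.groupby("ID", sort=False):
        r0 = g.iloc[0]
        ht = None if pd.isna(r0.get("HT")) else float(r0["HT"])
        ffm = None if pd.isna(r0.get("FFM")) else float(r0["FFM"])
        covs = mc.SubjectCovariates(
            id=str(sid), sex=str(r0["SEX"]), postnatal_age=float(r0["AGE"]),
            gestational_age=float(r0["GAGE"]), wt=float(r0["WT"]),
            ht=ht, ffm=ffm, gst=float(r0["GST"]))
        dose_rows = g[g["EVID"] == 1]
        doses = [mc.DosingEvent(start_time=float(r.TIME), amount=float(r.AMT),
                                infusion_duration=float(r.DUR))
                 for r in dose_rows.itertuples()]
        obs = g[(g["EVID"] == 0) & (g["MDV"] == 0)]
        sub = SubjectData(
            id=str(sid), covs=covs, doses=doses,
            obs_times=obs["TIME"].to_numpy(dtype=float),
            y=obs["DV"].to_numpy(dtype=float),
            obs_occ=obs["OCC"].to_numpy(dtype=int))
        sub.build_grid(dt=dt, occasion_bounds=occasion_bounds)
        out.append(sub)
    return out


def write_dataset(ds: Dataset, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in ds.meta.items():
            fh.write(f"# {k}: {v}\n")
        # 17 significant digits: exact float64 round-trip
        ds.df.to_csv(fh, index=False, float_format="%.17g")


def read_dataset(path: str | Path) -> Dataset:
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    for col in ("TIME", "AMT", "DUR", "DV", "AGE", "GAGE", "WT", "HT",
                "FFM", "GST"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    ds = Dataset(df=df, meta=meta)
    ds.validate()
    return ds
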