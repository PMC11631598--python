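"""PK dataset container and NONMEM-style CSV reading/writing.

The on-disk dialect is one row per event: dosing rows carry AMT (mg) and
DUR (infusion duration, h) with DV empty; observation rows carry DV
(mg/L) with AMT empty.  TIME is hours since the subject's first dose.
Covariates are repeated on every row of a subject.  Units are fixed:
h, mg, L, mg/L, kg, cm, umol/L (SCR), mL/min/1.73 m^2 (eGFR).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import DoseEvent

__all__ = ["Subject", "PKDataset", "read_dataset", "write_dataset", "LLOQ_DEFAULT"]

#: assay lower limit of quantification, mg/L
LLOQ_DEFAULT = 0.025

REQUIRED_COLUMNS = ("ID", "TIME", "AMT", "DUR", "DV")

#: covariate columns the generator produces; readers accept any subset
COVARIATE_COLUMNS = (
    "WT", "AGE", "HT", "BSA", "BMI", "SEX", "SCR", "EGFR",
    "BUN", "CYSC", "UA", "ALT", "AST", "TBIL",
)


@dataclass
class Subject:
    """One subject: dosing history, observations, covariates."""

    id: int | str
    covariates: dict[str, float]
    doses: list[DoseEvent] = field(default_factory=list)
    obs_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    obs_dv: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_obs(self) -> int:
        return len(self.obs_times)


@dataclass
class PKDataset:
    """Ordered subjects plus dataset-level metadata."""

    subjects: list[Subject]
    lloq: float = LLOQ_DEFAULT
    source: str = ""

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_obs(self) -> int:
        return int(sum(s.n_obs for s in self.subjects))

    def covariate_array(self, name: str) -> np.ndarray:
        return np.array([s.covariates[name] for s in self.subjects], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the NONMEM-style event table."""
        rows = []
        for s in self.subjects:
            cov = {k: s.covariates.get(k, np.nan) for k in COVARIATE_COLUMNS if k in s.covariates}
            for d in s.doses:
                rows.append({"ID": s.id, "TIME": d.time, "AMT": d.amount, "DUR": d.tinf, "DV": np.nan, **cov})
            for t, y in zip(s.obs_times, s.obs_dv):
                rows.append({"ID": s.id, "TIME": t, "AMT": np.nan, "DUR": np.nan, "DV": y, **cov})
        df = pd.DataFrame(rows)
        return df.sort_values(["ID", "TIME"], kind="stable").reset_index(drop=True)


class DatasetError(ValueError):
    """Raised for malformed event tables (names the offending row/subject)."""


def _from_frame(df: pd.DataFrame, lloq: float, bql: str, source: str) -> PKDataset:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {', '.join(missing)}")
    if np.any(df["TIME"].to_numpy(dtype=float) < 0):
        bad = df.index[df["TIME"] < 0][0]
        raise DatasetError(f"negative TIME at row {bad}")
    is_dose = df["AMT"].notna()
    is_obs = df["DV"].notna()
    both = df.index[is_dose & is_obs]
    if len(both):
        raise DatasetError(f"row {both[0]}: AMT and DV are mutually exclusive")
    key = df.loc[is_dose | is_obs, ["ID", "TIME"]].assign(_type=is_dose[is_dose | is_obs])
    dup = key.duplicated()
    if dup.any():
        raise DatasetError(f"duplicate (ID, TIME, event-type) at row {key.index[dup][0]}")

    subjects: list[Subject] = []
    seen: set = set()
    for sid, grp in df.groupby("ID", sort=False):
        if sid in seen:  # groupby(sort=False) keeps one group per ID; defensive
            raise DatasetError(f"duplicate subject ID {sid}")
        seen.add(sid)
        grp = grp.sort_values("TIME", kind="stable")
        doses = []
        for idx, row in grp[grp["AMT"].notna()].iterrows():
            if not row["DUR"] > 0:
                raise DatasetError(f"subject {sid} row {idx}: dose row needs DUR > 0")
            doses.append(DoseEvent(time=float(row["TIME"]), amount=float(row["AMT"]), tinf=float(row["DUR"])))
        obs = grp[grp["DV"].notna()]
        if len(obs):
            first_obs = float(obs["TIME"].iloc[0])
            if not doses or first_obs < doses[0].time:
                raise DatasetError(
                    f"subject {sid} row {obs.index[0]}: observation at t={first_obs} precedes any dose"
                )
        t = obs["TIME"].to_numpy(dtype=float)
        y = obs["DV"].to_numpy(dtype=float)
        if bql == "drop":
            keep = y >= lloq
            t, y = t[keep], y[keep]
        covs = {}
        for c in COVARIATE_COLUMNS:
            if c in grp.columns:
                v = grp[c].dropna()
                if len(v):
                    covs[c] = float(v.iloc[0])
        subjects.append(Subject(id=sid, covariates=covs, doses=doses, obs_times=t, obs_dv=y))
    return PKDataset(subjects=subjects, lloq=lloq, source=source)


def read_dataset(path, format: str = "csv", lloq: float = LLOQ_DEFAULT, bql: str = "drop") -> PKDataset:
    """Read and validate a NONMEM-style CSV event table.

    ``bql`` controls below-LLOQ observations: "drop" (default) removes
    them, "keep" retains them unchanged.
    """
    if format != "csv":
        raise ValueError(f"unsupported format: {format}")
    if bql not in ("drop", "keep"):
        raise ValueError("bql must be 'drop' or 'keep'")
    df = pd.read_csv(path)
    return _from_frame(df, lloq=lloq, bql=bql, source=str(path))


def write_dataset(ds: PKDataset, path) -> None:
    """Write the dataset back out as the same CSV dialect."""
    ds.to_frame().to_csv(path, index=False)
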