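"""Synthetic PICU cohorts and concentration datasets.

The study's clinical data are not deposited, so this module generates
stand-in cohorts with the same statistical structure: 88 critically ill
children, ages 0.03-15 y, weight 2.8-95 kg, eGFR 40.42-197.15
mL/min/1.73 m^2, dosed 21.05-76 mg/kg by short IV infusion with 1-3
opportunistic samples each, and concentrations simulated from the
population model plus log-normal IIV and residual error.

Covariate generation is mechanistic rather than purely marginal: age is
drawn first, height and weight follow age through smooth growth curves
with multiplicative noise, serum creatinine follows an age-dependent
reference range, and eGFR is *computed* from height and creatinine by
the bedside Schwartz formula (never drawn independently), so the
age-weight-eGFR correlation structure of a pediatric cohort emerges
mechanically.  Liver/renal panel covariates without a mechanistic role
(BUN, CysC, UA, ALT, AST, TBIL) are drawn log-normally around the
cohort medians and truncated to the observed ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import PKDataset, Subject, LLOQ_DEFAULT
from .model import DoseEvent, EtaVector, ThetaVector, conc_superposition, individual_params
from .modelspec import OmegaMatrix, SigmaSpec

__all__ = [
    "CohortSpec",
    "SyntheticDataset",
    "egfr_schwartz",
    "bsa_mosteller",
    "generate_cohort",
    "generate_dataset",
    "truth_values",
]

#: umol/L serum creatinine per mg/dL
_SCR_UMOL_PER_MGDL = 88.4


def egfr_schwartz(height, scr):
    """Bedside Schwartz eGFR (mL/min/1.73 m^2) from height (cm) and
    serum creatinine (umol/L).

    The formula's constant 0.413 expects creatinine in mg/dL, so the
    input is converted with 88.4 umol/L per mg/dL first.
    """
    height = np.asarray(height, dtype=float)
    scr = np.asarray(scr, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be positive")
    if np.any(scr <= 0):
        raise ValueError("scr must be positive")
    out = 0.413 * height / (scr / _SCR_UMOL_PER_MGDL)
    return out if out.ndim else float(out)


def bsa_mosteller(height, weight):
    """Mosteller body surface area (m^2): sqrt(height_cm * weight_kg / 3600)."""
    height = np.asarray(height, dtype=float)
    weight = np.asarray(weight, dtype=float)
    if np.any(height <= 0) or np.any(weight <= 0):
        raise ValueError("height and weight must be positive")
    out = np.sqrt(height * weight / 3600.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort design: sizes, covariate ranges, sampling/dosing scheme."""

    n_subjects: int = 88
    age_range: tuple = (0.03, 15.0)
    age_mean: float = 5.43
    age_sd: float = 4.10
    weight_range: tuple = (2.8, 95.0)
    height_range: tuple = (50.0, 172.0)
    scr_range: tuple = (15.9, 66.2)
    egfr_range: tuple = (40.42, 197.15)
    samples_per_subject: tuple = (1, 3)
    samples_probs: tuple = (0.88, 0.10, 0.02)
    dose_per_kg_range: tuple = (21.05, 76.0)
    #: prevalence of eGFR bins 30-60 / 60-90 / 90-120 / 120-200, as in the
    #: study population (5, 9, 31 and 43 of 88 children)
    renal_mix: tuple = (5 / 88, 9 / 88, 31 / 88, 43 / 88)
    interval_choices: tuple = (8.0, 12.0)
    interval_probs: tuple = (0.5, 0.5)
    n_doses_range: tuple = (3, 6)
    tinf: float = 0.5
    male_fraction: float = 56 / 88
    lloq: float = LLOQ_DEFAULT
    seed: int = 20240001

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("age_range", "weight_range", "height_range", "scr_range",
                     "egfr_range", "dose_per_kg_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"infeasible range for {name}")


def _height_curve(age):
    """Median height (cm) vs age (y): ~50 cm at birth, 75 cm at 1 y,
    then 6.5 cm/y -- a plausibility curve, not an anthropometric standard."""
    return np.where(age < 1.0, 50.0 + 25.0 * age, 75.0 + 6.5 * (age - 1.0))


def _bmi_curve(age):
    return 13.6 + 0.2 * age


def _scr_curve(age):
    """Median serum creatinine (umol/L) vs age: rises with muscle mass."""
    return 23.0 + 2.1 * age


def _truncated_lognormal(rng, median, sigma, lo, hi, size):
    """Log-normal around ``median`` truncated to [lo, hi] by redraw."""
    out = np.empty(size)
    mask = np.ones(size, dtype=bool)
    for _ in range(200):
        k = int(mask.sum())
        if k == 0:
            break
        out[mask] = median * np.exp(rng.normal(0.0, sigma, size=k))
        mask = (out < lo) | (out > hi)
    out[mask] = np.clip(out[mask], lo, hi)
    return out


def generate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Draw a virtual cohort; one row per subject, columns are covariates."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    lo, hi = spec.age_range
    age = np.empty(n)
    mask = np.ones(n, dtype=bool)
    while mask.any():
        age[mask] = rng.normal(spec.age_mean, spec.age_sd, size=int(mask.sum()))
        mask = (age < lo) | (age > hi)
    ht = _truncated_lognormal(rng, 1.0, 0.04, 0, np.inf, n) * _height_curve(age)
    ht = np.clip(ht, *spec.height_range)
    wt = _truncated_lognormal(rng, 1.0, 0.12, 0, np.inf, n) * _bmi_curve(age) * (ht / 100.0) ** 2
    wt = np.clip(wt, *spec.weight_range)

    # Renal function: each subject is assigned a target eGFR bin with the
    # study's prevalence (moderate/mild insufficiency, normal, augmented),
    # then creatinine is redrawn from its age-dependent range until the
    # Schwartz eGFR lands in the bin.  eGFR is always computed, never drawn.
    bins = np.array([[spec.egfr_range[0], 60.0], [60.0, 90.0], [90.0, 120.0],
                     [120.0, spec.egfr_range[1]]])
    bin_idx = rng.choice(4, size=n, p=np.asarray(spec.renal_mix, dtype=float))
    lo_b, hi_b = bins[bin_idx, 0], bins[bin_idx, 1]
    # creatinine feasible within its assay/cohort range given height
    hi_feas = egfr_schwartz(ht, np.full(n, spec.scr_range[0]))
    lo_feas = egfr_schwartz(ht, np.full(n, spec.scr_range[1]))
    unreachable = lo_feas > hi_b  # small-SCR tall children cannot be this low
    lo_b = np.where(unreachable, np.minimum(lo_feas, spec.egfr_range[1] - 1.0), lo_b)
    hi_b = np.where(unreachable, spec.egfr_range[1], hi_b)
    scr = np.empty(n)
    egfr = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for _ in range(500):
        k = int(mask.sum())
        if k == 0:
            break
        draw = _scr_curve(age[mask]) * np.exp(rng.normal(0.0, 0.28, size=k))
        draw = np.clip(draw, *spec.scr_range)
        scr[mask] = draw
        egfr[mask] = egfr_schwartz(ht[mask], draw)
        mask = (egfr < lo_b) | (egfr > hi_b)
    if mask.any():
        # force stragglers onto the nearest feasible creatinine for their bin
        lo_scr = 0.413 * ht[mask] * _SCR_UMOL_PER_MGDL / hi_b[mask]
        hi_scr = 0.413 * ht[mask] * _SCR_UMOL_PER_MGDL / lo_b[mask]
        scr[mask] = np.clip(np.clip(scr[mask], lo_scr, hi_scr), *spec.scr_range)
        egfr[mask] = egfr_schwartz(ht[mask], scr[mask])

    sex = (rng.uniform(size=n) < spec.male_fraction).astype(float)  # 1 = male
    bun = _truncated_lognormal(rng, 4.19, 0.4, 1.0, 14.1, n)
    cysc = _truncated_lognormal(rng, 0.8, 0.3, 0.3, 2.5, n)
    ua = _truncated_lognormal(rng, 265.3, 0.45, 38.0, 789.0, n)
    alt = _truncated_lognormal(rng, 20.5, 0.8, 4.0, 1672.0, n)
    ast = _truncated_lognormal(rng, 29.0, 0.7, 9.0, 7758.0, n)
    tbil = _truncated_lognormal(rng, 10.1, 0.6, 2.9, 408.7, n)

    return pd.DataFrame({
        "ID": np.arange(1, n + 1),
        "AGE": age,
        "SEX": sex,
        "HT": ht,
        "WT": wt,
        "BMI": wt / (ht / 100.0) ** 2,
        "BSA": bsa_mosteller(ht, wt),
        "SCR": scr,
        "EGFR": egfr,
        "BUN": bun,
        "CYSC": cysc,
        "UA": ua,
        "ALT": alt,
        "AST": ast,
        "TBIL": tbil,
    })


@dataclass
class SyntheticDataset:
    """A simulated dataset with its generating truth embedded."""

    dataset: PKDataset
    theta: ThetaVector
    omega: OmegaMatrix
    sigma: SigmaSpec
    etas: np.ndarray  # (n_subjects, 2): eta_CL, eta_V
    seed: int

    @property
    def truth(self) -> dict:
        return truth_values(self.theta, self.omega, self.sigma)


def truth_values(theta: ThetaVector, omega: OmegaMatrix, sigma: SigmaSpec) -> dict:
    """Generating parameters keyed like the final-model ModelSpec."""
    out = {
        "tvV": theta.tvV, "tvCL": theta.tvCL,
        "V~WT": theta.theta1, "CL~WT": theta.theta2, "CL~EGFR": theta.theta3,
        "om2_CL": omega.omega2_CL, "om2_V": omega.omega2_V,
    }
    if sigma.sigma_add is not None:
        out["sig_add"] = sigma.sigma_add
    if sigma.sigma_prop is not None:
        out["sig_prop"] = sigma.sigma_prop
    return out


def generate_dataset(
    cohort: pd.DataFrame,
    theta: ThetaVector,
    omega: OmegaMatrix,
    sigma: SigmaSpec,
    spec: CohortSpec = CohortSpec(),
    seed: int | None = None,
) -> SyntheticDataset:
    """Simulate sparse opportunistic concentration data for a cohort.

    Each subject receives 3-6 repeated infusions of a uniformly drawn
    per-kg dose at q8h or q12h, and 1-3 observation times drawn
    uniformly over the dosed span (after the first dose).  Observed
    concentrations are the model prediction at the subject's eta plus
    residual noise; values below the LLOQ are censored by dropping, and
    a subject left with no quantifiable sample has its sampling redrawn
    (opportunistic samples from treated patients are quantifiable by
    design).
    """
    if seed is None:
        seed = spec.seed + 1
    rng = np.random.default_rng(seed)
    subjects = []
    etas = np.empty((len(cohort), 2))
    for row_i, row in enumerate(cohort.itertuples(index=False)):
        wt, egfr = row.WT, row.EGFR
        dose_per_kg = rng.uniform(*spec.dose_per_kg_range)
        tau = rng.choice(spec.interval_choices, p=spec.interval_probs)
        n_doses = int(rng.integers(spec.n_doses_range[0], spec.n_doses_range[1] + 1))
        doses = [DoseEvent(i * tau, dose_per_kg * wt, spec.tinf) for i in range(n_doses)]
        e_cl = rng.normal(0.0, np.sqrt(omega.omega2_CL))
        e_v = rng.normal(0.0, np.sqrt(omega.omega2_V))
        etas[row_i] = (e_cl, e_v)
        ip = individual_params(theta, wt, egfr, EtaVector(e_cl, e_v))
        counts = np.arange(spec.samples_per_subject[0], spec.samples_per_subject[1] + 1)
        n_samp = int(rng.choice(counts, p=spec.samples_probs))
        for _ in range(100):
            t_obs = np.sort(rng.uniform(1e-3, n_doses * tau, size=n_samp))
            f = np.asarray(conc_superposition(ip, doses, t_obs), dtype=float)
            y = f + np.sqrt(sigma.variance(f)) * rng.normal(size=n_samp)
            keep = y >= spec.lloq
            if keep.any():
                break
        t_obs, y = t_obs[keep], y[keep]
        cov = {
            "WT": wt, "AGE": row.AGE, "HT": row.HT, "BSA": row.BSA, "BMI": row.BMI,
            "SEX": row.SEX, "SCR": row.SCR, "EGFR": egfr, "BUN": row.BUN,
            "CYSC": row.CYSC, "UA": row.UA, "ALT": row.ALT, "AST": row.AST,
            "TBIL": row.TBIL,
        }
        subjects.append(Subject(id=int(row.ID), covariates=cov, doses=doses,
                                obs_times=t_obs, obs_dv=y))
    ds = PKDataset(subjects=subjects, lloq=spec.lloq, source=f"synthetic(seed={seed})")
    return SyntheticDataset(dataset=ds, theta=theta, omega=omega, sigma=sigma,
                            etas=etas, seed=seed)
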