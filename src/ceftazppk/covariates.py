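"""Covariate screening, stepwise selection, and maturation-model comparison.

The covariate search follows the conventional two-stage procedure for
sparse pediatric PK data:

1. *Prescreen*: each candidate covariate is tested for association with
   the empirical-Bayes individual clearance (Spearman rank correlation
   for continuous covariates, Wilcoxon rank-sum for binary ones);
   candidates with p < 0.05 enter the stepwise search.
2. *Forward selection*: candidates are added one at a time; the
   candidate with the largest OFV drop is accepted while the drop
   exceeds 3.84 (chi-square, p < 0.05, 1 df).
3. *Backward elimination*: covariates whose removal costs less than
   6.635 OFV points (p < 0.01) are removed, cheapest first.

Finally, five allometric/maturation descriptions of the clearance-weight
relation are compared on the full model: fixed 3/4 allometry, an
estimated single exponent, 3/4 allometry with a sigmoidal age-maturation
factor, and weight- or age-dependent exponent models.  Models with
unstable parameters (RSE > 50% or a boundary estimate) are excluded
before ranking by OFV; ties prefer fewer parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset
from .estimate import FitResult, fit
from .modelspec import (
    AgeDependentExponentTerm,
    CategoricalTerm,
    HillMaturationTerm,
    ModelSpec,
    PowerTerm,
    WeightDependentExponentTerm,
)

__all__ = [
    "CovariateCandidate",
    "StepRecord",
    "CONTINUOUS_COVARIATES",
    "CATEGORICAL_COVARIATES",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
    "prescreen",
    "forward_select",
    "backward_eliminate",
    "stepwise",
    "compare_maturation_models",
    "step_log_frame",
]

CONTINUOUS_COVARIATES = ("WT", "AGE", "HT", "BSA", "BMI", "SCR", "BUN",
                         "CYSC", "UA", "ALT", "AST", "TBIL", "EGFR")
CATEGORICAL_COVARIATES = ("SEX",)

#: chi-square thresholds for 1 df: p < 0.05 to enter, p < 0.01 to stay
FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.635

#: reference values fixed by convention rather than by cohort median
_FIXED_REFS = {"WT": 70.0, "EGFR": 116.93}


@dataclass(frozen=True)
class CovariateCandidate:
    name: str
    target: str  # parameter the covariate acts on: "CL" or "V"
    relation: str  # "power" (median-normalized) or "categorical"
    prescreen_p: float
    retained: bool

    def __post_init__(self):
        if not (0 <= self.prescreen_p <= 1):
            raise ValueError("prescreen_p must be in [0, 1]")


@dataclass(frozen=True)
class StepRecord:
    step: int
    action: str  # "add", "remove", or "evaluate"
    covariate: str
    target: str
    ofv_before: float
    ofv_after: float
    decision: str
    threshold: float

    @property
    def delta_ofv(self) -> float:
        return self.ofv_after - self.ofv_before


def step_log_frame(records: list[StepRecord]) -> pd.DataFrame:
    """Step log as a table (the auditable selection path)."""
    return pd.DataFrame([
        {"step": r.step, "action": r.action, "covariate": r.covariate,
         "target": r.target, "ofv_before": r.ofv_before, "ofv_after": r.ofv_after,
         "delta_ofv": r.delta_ofv, "decision": r.decision, "threshold": r.threshold}
        for r in records
    ])


def _individual_cl(ds: PKDataset, base_fit: FitResult) -> np.ndarray:
    from .estimate import compile_dataset

    cd = compile_dataset(ds)
    clpop = base_fit.spec.cl_pop(base_fit.values, cd.cov, cd.n_subj)
    return clpop * np.exp(base_fit.ebes[:, 0])


def prescreen(ds: PKDataset, base_fit: FitResult, target: str = "CL",
              continuous: tuple = CONTINUOUS_COVARIATES,
              categorical: tuple = CATEGORICAL_COVARIATES,
              alpha: float = 0.05) -> list[CovariateCandidate]:
    """Rank-based association tests between EBE clearance and covariates.

    Returns every tested candidate with its p-value; ``retained`` marks
    those below ``alpha``.  Constant covariate columns are skipped with
    a warning.
    """
    icl = _individual_cl(ds, base_fit)
    out: list[CovariateCandidate] = []
    have = set(ds.subjects[0].covariates)
    for name in continuous:
        if name not in have:
            continue
        x = ds.covariate_array(name)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name} is constant; skipped")
            continue
        rho, p = stats.spearmanr(x, icl)
        out.append(CovariateCandidate(name, target, "power", float(p), p < alpha))
    for name in categorical:
        if name not in have:
            continue
        x = ds.covariate_array(name)
        groups = [icl[x == v] for v in np.unique(x)]
        if len(groups) < 2:
            warnings.warn(f"covariate {name} is constant; skipped")
            continue
        _, p = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        out.append(CovariateCandidate(name, target, "categorical", float(p), p < alpha))
    return out


def _term_for(cand: CovariateCandidate, ds: PKDataset):
    pname = f"{cand.target}~{cand.name}"
    if cand.relation == "categorical":
        return CategoricalTerm(cand.name, pname)
    ref = _FIXED_REFS.get(cand.name, float(np.median(ds.covariate_array(cand.name))))
    return PowerTerm(cand.name, ref, pname, init=0.3)


def _refit(ds, spec, prev_fit: FitResult | None, fit_options=None):
    opts = {"compute_se": False, "presearch": prev_fit is None}
    opts.update(fit_options or {})
    init = dict(prev_fit.values) if prev_fit is not None else None
    if init is not None:
        known = {d.name for d in spec.param_defs()}
        init = {k: v for k, v in init.items() if k in known}
    return fit(ds, spec, init=init, options=opts)


def forward_select(ds: PKDataset, base_fit: FitResult,
                   candidates: list[CovariateCandidate],
                   threshold: float = FORWARD_THRESHOLD,
                   fit_options: dict | None = None
                   ) -> tuple[FitResult, list[StepRecord]]:
    """Greedy forward addition: accept the best candidate while its OFV
    drop exceeds the threshold.  Candidates whose fit fails to converge
    are skipped for that round and logged."""
    current = base_fit
    remaining = [c for c in candidates if c.retained]
    records: list[StepRecord] = []
    step = 0
    while remaining:
        step += 1
        results = []
        for cand in remaining:
            spec_c = current.spec.with_term(_term_for(cand, ds), cand.target)
            try:
                fit_c = _refit(ds, spec_c, current, fit_options)
            except Exception:
                fit_c = None
            if fit_c is None or not fit_c.converged:
                records.append(StepRecord(step, "evaluate", cand.name, cand.target,
                                          current.ofv, np.nan, "skipped: non-convergence",
                                          threshold))
                continue
            records.append(StepRecord(step, "evaluate", cand.name, cand.target,
                                      current.ofv, fit_c.ofv, "candidate", threshold))
            results.append((cand, fit_c))
        if not results:
            break
        cand, fit_c = min(results, key=lambda t: t[1].ofv)
        drop = current.ofv - fit_c.ofv
        if drop > threshold:
            records.append(StepRecord(step, "add", cand.name, cand.target,
                                      current.ofv, fit_c.ofv,
                                      f"added (dOFV {-drop:.2f} beats -{threshold})",
                                      threshold))
            current = fit_c
            remaining = [c for c in remaining if c is not cand]
        else:
            records.append(StepRecord(step, "add", cand.name, cand.target,
                                      current.ofv, fit_c.ofv,
                                      f"stopped (best drop {drop:.2f} <= {threshold})",
                                      threshold))
            break
    return current, records


def backward_eliminate(ds: PKDataset, full_fit: FitResult,
                       threshold: float = BACKWARD_THRESHOLD,
                       protected: tuple = (),
                       fit_options: dict | None = None
                       ) -> tuple[FitResult, list[StepRecord]]:
    """Remove, cheapest first, every covariate whose removal raises the
    OFV by less than the threshold.  ``protected`` names (target, cov)
    pairs exempt from elimination (e.g. a structurally fixed term)."""
    current = full_fit
    records: list[StepRecord] = []
    step = 0
    while True:
        step += 1
        removable = []
        for target in ("CL", "V"):
            for cov in current.spec.covariate_names(target):
                if (target, cov) in protected:
                    continue
                removable.append((target, cov))
        if not removable:
            break
        results = []
        for target, cov in removable:
            spec_r = current.spec.without_covariate(cov, target)
            try:
                fit_r = _refit(ds, spec_r, current, fit_options)
            except Exception:
                fit_r = None
            if fit_r is None or not fit_r.converged:
                records.append(StepRecord(step, "evaluate", cov, target, current.ofv,
                                          np.nan, "skipped: non-convergence", threshold))
                continue
            records.append(StepRecord(step, "evaluate", cov, target, current.ofv,
                                      fit_r.ofv, "candidate-removal", threshold))
            results.append((target, cov, fit_r))
        if not results:
            break
        target, cov, fit_r = min(results, key=lambda t: t[2].ofv)
        rise = fit_r.ofv - current.ofv
        if rise < threshold:
            records.append(StepRecord(step, "remove", cov, target, current.ofv,
                                      fit_r.ofv, f"removed (dOFV {rise:.2f} < {threshold})",
                                      threshold))
            current = fit_r
        else:
            records.append(StepRecord(step, "remove", cov, target, current.ofv,
                                      fit_r.ofv,
                                      f"retained all (cheapest rise {rise:.2f} >= {threshold})",
                                      threshold))
            break
    return current, records


def stepwise(ds: PKDataset, base_fit: FitResult,
             candidates: list[CovariateCandidate],
             fit_options: dict | None = None
             ) -> tuple[FitResult, list[StepRecord]]:
    """Forward selection followed by backward elimination."""
    full_fit, rec_f = forward_select(ds, base_fit, candidates, fit_options=fit_options)
    final_fit, rec_b = backward_eliminate(ds, full_fit, fit_options=fit_options)
    return final_fit, rec_f + rec_b


# ---------------------------------------------------------------------------
# maturation models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MaturationModelSpec:
    id: str  # "I".."V"
    description: str
    spec: ModelSpec
    focus_params: tuple  # the maturation-structure parameters judged for stability


def _maturation_specs(full_spec: ModelSpec) -> list[MaturationModelSpec]:
    """The five candidate descriptions of the CL-weight relation; every
    other term of the full model (eGFR on CL, weight on V) is kept."""
    stripped = full_spec.without_covariate("WT", "CL")
    builders = [
        ("I", "3/4 allometric model (exponent fixed at 0.75)",
         stripped.with_term(PowerTerm("WT", 70.0, "CL~WT", fixed_exponent=0.75), "CL"),
         ()),
        ("II", "simple exponent model (estimated exponent)",
         stripped.with_term(PowerTerm("WT", 70.0, "CL~WT", init=0.9), "CL"),
         ("CL~WT",)),
        ("III", "maturation model (3/4 allometry x sigmoidal age factor)",
         stripped.with_term(PowerTerm("WT", 70.0, "CL~WT", fixed_exponent=0.75), "CL")
                 .with_term(HillMaturationTerm("AGE", "CL~MAT"), "CL"),
         ("CL~MAT_hill", "CL~MAT_a50")),
        ("IV", "weight-dependent exponent model",
         stripped.with_term(WeightDependentExponentTerm("CL~WDE"), "CL"),
         ("CL~WDE_k0", "CL~WDE_kmax", "CL~WDE_z50", "CL~WDE_hill")),
        ("V", "age-dependent exponent model",
         stripped.with_term(AgeDependentExponentTerm("CL~ADE"), "CL"),
         ("CL~ADE_k0", "CL~ADE_kmax", "CL~ADE_z50", "CL~ADE_hill")),
    ]
    return [MaturationModelSpec(i, d, s, f) for i, d, s, f in builders]


def compare_maturation_models(ds: PKDataset, full_fit: FitResult,
                              rse_limit: float = 50.0,
                              fit_options: dict | None = None) -> pd.DataFrame:
    """Fit maturation models I-V and rank them.

    Models whose maturation-structure parameters are highly variable
    (RSE above ``rse_limit`` % or no computable SE), sit at a bound, or
    fail to converge are flagged unstable and excluded from selection;
    the remainder are ranked by OFV with ties preferring fewer
    parameters.  Returns one row per model with fit diagnostics, ordered
    by rank (excluded models last).
    """
    rows = []
    for mm in _maturation_specs(full_fit.spec):
        # cold pre-search: the sigmoidal models need their own global search
        opts = {"compute_se": True, "presearch": True}
        opts.update(fit_options or {})
        try:
            fr = _refit(ds, mm.spec, full_fit, opts)
        except Exception as exc:  # noqa: BLE001 - model-specific failure is data
            rows.append({"model": mm.id, "description": mm.description, "ofv": np.nan,
                         "n_params": len(mm.spec.free_defs()), "max_rse_pct": np.nan,
                         "converged": False, "boundary": False, "stable": False,
                         "note": f"fit failed: {exc}", "fit": None})
            continue
        # stability is judged on the maturation-structure parameters:
        # "highly variable" means RSE > limit or no computable SE there
        focus = [fr.rse_pct.get(p, np.nan) for p in mm.focus_params]
        rses = [v for v in focus if np.isfinite(v)]
        max_rse = max(rses) if rses else np.nan
        no_se = bool(mm.focus_params) and len(rses) < len(mm.focus_params)
        unstable = (not fr.converged) or fr.boundary or no_se or \
            (np.isfinite(max_rse) and max_rse > rse_limit)
        note = ""
        if unstable:
            bits = []
            if not fr.converged:
                bits.append("non-convergence")
            if fr.boundary:
                bits.append("boundary estimate")
            if no_se:
                bits.append("no computable standard errors")
            elif max_rse > rse_limit:
                bits.append(f"RSE {max_rse:.0f}% > {rse_limit:.0f}%")
            note = "excluded: " + ", ".join(bits)
        rows.append({"model": mm.id, "description": mm.description, "ofv": fr.ofv,
                     "n_params": len(mm.spec.free_defs()), "max_rse_pct": max_rse,
                     "converged": fr.converged, "boundary": fr.boundary,
                     "stable": not unstable, "note": note, "fit": fr})
    df = pd.DataFrame(rows)
    df["rank"] = np.nan
    stable = df[df["stable"]].sort_values(["ofv", "n_params"], kind="stable")
    df.loc[stable.index, "rank"] = np.arange(1, len(stable) + 1)
    order = df.sort_values(["stable", "rank"], ascending=[False, True], kind="stable")
    return order.reset_index(drop=True)
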