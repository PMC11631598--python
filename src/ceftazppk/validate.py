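"""Model validation: nonparametric bootstrap, NPDE, goodness-of-fit table.

The bootstrap resamples whole subjects with replacement (the exchangeable
unit in sparse PK data), refits each replicate, and summarizes parameter
medians, 95% percentile intervals and bias relative to the original fit.

Normalized prediction distribution errors (NPDE) simulate the fitted
model at the observed design many times, decorrelate observed and
simulated vectors within each subject with the simulation covariance
square root, rank the observation among its simulations, and map the
rank through the standard-normal quantile.  Under a correct model the
NPDE are N(0,1); this is checked with a t-test on the mean, a Fisher
test on the variance, a Shapiro-Wilk normality test, and a Bonferroni
global test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import PKDataset, Subject
from .estimate import FitResult, compile_dataset, cwres, fit

__all__ = [
    "BootstrapResult",
    "NPDEResult",
    "bias_percent",
    "bootstrap",
    "npde",
    "gof_table",
    "simulate_observations",
]


def bias_percent(bootstrap_median: float, final_estimate: float) -> float:
    """Relative deviation of the bootstrap median from the original
    estimate: 100 * (median - estimate) / estimate."""
    if final_estimate == 0:
        return np.nan
    return 100.0 * (bootstrap_median - final_estimate) / final_estimate


@dataclass
class BootstrapResult:
    table: pd.DataFrame  # per parameter: estimate, median, ci_lo, ci_hi, bias_pct
    n_success: int
    n_requested: int
    seed: int
    unreliable: bool

    @property
    def failure_fraction(self) -> float:
        return 1.0 - self.n_success / self.n_requested


def _resample(ds: PKDataset, rng) -> PKDataset:
    idx = rng.integers(0, ds.n_subjects, size=ds.n_subjects)
    subjects = []
    for new_id, i in enumerate(idx, start=1):
        s = ds.subjects[i]
        subjects.append(Subject(id=new_id, covariates=dict(s.covariates),
                                doses=list(s.doses), obs_times=s.obs_times.copy(),
                                obs_dv=s.obs_dv.copy()))
    return PKDataset(subjects=subjects, lloq=ds.lloq, source=ds.source + "|bootstrap")


def bootstrap(ds: PKDataset, fitres: FitResult, B: int = 1000, seed: int = 0,
              fit_options: dict | None = None) -> BootstrapResult:
    """Subject-level nonparametric bootstrap of the fitted model.

    Replicates are refit starting from the original estimates;
    non-converged replicates are dropped (and counted), and the result
    is flagged unreliable when more than 20% fail.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    opts = {"compute_se": False, "presearch": False}
    opts.update(fit_options or {})
    free_names = [d.name for d in fitres.spec.free_defs()]
    draws: list[dict] = []
    n_fail = 0
    for _ in range(B):
        rep = _resample(ds, rng)
        try:
            fr = fit(rep, fitres.spec, init=fitres.values, options=dict(opts))
        except Exception:
            n_fail += 1
            continue
        if not fr.converged:
            n_fail += 1
            continue
        draws.append(fr.values)
    rows = []
    for name in free_names:
        est = fitres.values[name]
        if draws:
            vals = np.array([d[name] for d in draws])
            med = float(np.median(vals))
            lo, hi = np.percentile(vals, [2.5, 97.5])
        else:
            med = lo = hi = np.nan
        rows.append({"parameter": name, "estimate": est, "median": med,
                     "ci_lo": float(lo), "ci_hi": float(hi),
                     "bias_pct": bias_percent(med, est)})
    table = pd.DataFrame(rows)
    return BootstrapResult(table=table, n_success=len(draws), n_requested=B,
                           seed=seed, unreliable=n_fail > 0.2 * B)


def simulate_observations(ds: PKDataset, fitres_spec, values: dict, K: int,
                          rng) -> np.ndarray:
    """Simulate K replicate observation vectors under the model at the
    observed design.  Returns an array of shape (K, n_obs)."""
    cd = compile_dataset(ds)
    clpop = fitres_spec.cl_pop(values, cd.cov, cd.n_subj)
    vpop = fitres_spec.v_pop(values, cd.cov, cd.n_subj)
    om = fitres_spec.omega(values)
    sg = fitres_spec.sigma(values)
    out = np.empty((K, cd.n_obs))
    for k in range(K):
        ecl = rng.normal(0.0, np.sqrt(om.omega2_CL), size=cd.n_subj)
        ev = rng.normal(0.0, np.sqrt(om.omega2_V), size=cd.n_subj)
        f = cd.conc(clpop * np.exp(ecl), vpop * np.exp(ev))
        out[k] = f + np.sqrt(sg.variance(f)) * rng.normal(size=cd.n_obs)
    return out


@dataclass
class NPDEResult:
    npde: np.ndarray
    mean: float
    se_mean: float
    variance: float
    se_variance: float
    p_ttest: float
    p_shapiro_wilk: float
    p_fisher_variance: float
    p_global: float
    n_excluded_subjects: int = 0

    def summary(self) -> dict:
        return {
            "mean": self.mean, "se_mean": self.se_mean,
            "variance": self.variance, "se_variance": self.se_variance,
            "p_ttest": self.p_ttest, "p_shapiro_wilk": self.p_shapiro_wilk,
            "p_fisher_variance": self.p_fisher_variance, "p_global": self.p_global,
        }


def npde(ds: PKDataset, fitres: FitResult | None = None, K: int = 1000,
         seed: int = 0, spec=None, values=None) -> NPDEResult:
    """Normalized prediction distribution errors with their four tests.

    Accepts either a :class:`FitResult` or an explicit (spec, values)
    pair.  Ranks at the extremes are truncated to 1/(2K) and 1 - 1/(2K)
    before the normal-quantile transform.  Subjects whose simulation
    covariance is singular are excluded with a warning; if every subject
    is degenerate (e.g. noise-free data), an error is raised.
    """
    if K < 100:
        raise ValueError("K must be >= 100")
    if fitres is not None:
        spec, values = fitres.spec, fitres.values
    if spec is None or values is None:
        raise ValueError("need a FitResult or (spec, values)")
    rng = np.random.default_rng(seed)
    cd = compile_dataset(ds)
    sims = simulate_observations(ds, spec, values, K, rng)

    npde_all: list[np.ndarray] = []
    n_excluded = 0
    for i in range(cd.n_subj):
        idx = np.where(cd.obs_subj == i)[0]
        if len(idx) == 0:
            continue
        Yi = sims[:, idx]                # (K, n_i)
        Ei = Yi.mean(axis=0)
        Vi = np.cov(Yi, rowvar=False)
        Vi = np.atleast_2d(Vi)
        try:
            if np.any(np.diag(Vi) < 1e-12):  # zero-variance simulations
                raise np.linalg.LinAlgError("degenerate simulation variance")
            L = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular simulation covariance; subject {cd.subject_ids[i]} excluded")
            n_excluded += 1
            continue
        dec_obs = np.linalg.solve(L, cd.y[idx] - Ei)
        dec_sim = np.linalg.solve(L, (Yi - Ei).T)    # (n_i, K)
        pde = (dec_sim < dec_obs[:, None]).mean(axis=1)
        pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
        npde_all.append(stats.norm.ppf(pde))
    if not npde_all:
        raise ValueError("degenerate input: no subject has a non-singular "
                         "simulation covariance (zero-variance data?)")
    x = np.concatenate(npde_all)
    n = len(x)
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=1))
    se_mean = float(np.sqrt(var / n))
    se_var = float(var * np.sqrt(2.0 / (n - 1)))
    _, p_t = stats.ttest_1samp(x, 0.0)
    _, p_sw = stats.shapiro(x)
    # two-sided chi-square test of Var = 1
    chi2 = (n - 1) * var
    p_f = 2.0 * min(stats.chi2.cdf(chi2, n - 1), stats.chi2.sf(chi2, n - 1))
    p_f = min(p_f, 1.0)
    p_global = min(1.0, 3.0 * min(p_t, p_sw, p_f))
    return NPDEResult(npde=x, mean=mean, se_mean=se_mean, variance=var,
                      se_variance=se_var, p_ttest=float(p_t),
                      p_shapiro_wilk=float(p_sw), p_fisher_variance=float(p_f),
                      p_global=float(p_global), n_excluded_subjects=n_excluded)


def gof_table(ds: PKDataset, fitres: FitResult) -> pd.DataFrame:
    """Goodness-of-fit table (DV, IPRED, PRED, CWRES, time after dose),
    one row per observation, ready to write as CSV for plotting."""
    return cwres(ds, fitres)
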