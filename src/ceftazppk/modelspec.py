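"""Hierarchical model specification: fixed effects, IIV, residual error.

A :class:`ModelSpec` describes the population model to be estimated:

* typical values ``tvCL`` and ``tvV``;
* multiplicative covariate terms on CL and on V (power functions of
  median-normalized continuous covariates, proportional shifts for
  categorical ones, and the sigmoidal maturation forms);
* diagonal log-normal inter-individual variability (eta on CL and/or V);
* a residual error model (additive, proportional or combined).

Parameters that must stay positive are optimized on the log scale; the
spec owns the packing/unpacking between the optimizer vector and the
named natural-scale values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ParamDef",
    "PowerTerm",
    "CategoricalTerm",
    "HillMaturationTerm",
    "WeightDependentExponentTerm",
    "AgeDependentExponentTerm",
    "OmegaMatrix",
    "SigmaSpec",
    "ModelSpec",
    "base_model",
    "final_model",
]


@dataclass(frozen=True)
class ParamDef:
    name: str
    init: float
    transform: str = "log"  # "log" or "ident"
    fixed: bool = False


@dataclass(frozen=True)
class PowerTerm:
    """(cov/ref)**exponent; exponent estimated unless ``fixed_exponent``."""

    covariate: str
    ref: float
    name: str
    init: float = 0.75
    fixed_exponent: float | None = None

    def param_defs(self) -> list[ParamDef]:
        if self.fixed_exponent is not None:
            return [ParamDef(self.name, self.fixed_exponent, "ident", fixed=True)]
        return [ParamDef(self.name, self.init, "ident")]

    def factor(self, values: dict, cov: dict) -> np.ndarray:
        return (cov[self.covariate] / self.ref) ** values[self.name]


@dataclass(frozen=True)
class CategoricalTerm:
    """Proportional shift 1 + theta * x for a 0/1 covariate."""

    covariate: str
    name: str
    init: float = 0.0

    def param_defs(self) -> list[ParamDef]:
        return [ParamDef(self.name, self.init, "ident")]

    def factor(self, values: dict, cov: dict) -> np.ndarray:
        f = 1.0 + values[self.name] * cov[self.covariate]
        # keep the multiplier positive for pathological optimizer steps
        return np.maximum(f, 1e-6)


@dataclass(frozen=True)
class HillMaturationTerm:
    """Sigmoidal age maturation AGE^g / (A50^g + AGE^g)."""

    covariate: str = "AGE"
    name: str = "mat"
    init_hill: float = 2.0
    init_a50: float = 0.5  # years

    def param_defs(self) -> list[ParamDef]:
        return [
            ParamDef(f"{self.name}_hill", self.init_hill, "log"),
            ParamDef(f"{self.name}_a50", self.init_a50, "log"),
        ]

    def factor(self, values: dict, cov: dict) -> np.ndarray:
        g = values[f"{self.name}_hill"]
        a50 = values[f"{self.name}_a50"]
        a = cov[self.covariate]
        ag = a ** g
        return ag / (a50 ** g + ag)


@dataclass(frozen=True)
class _SigmoidExponentTerm:
    """(WT/ref)^{k(z)} with k(z) = k0 - kmax * z^g / (z50^g + z^g)."""

    driver: str  # covariate driving the exponent (WT or AGE)
    name: str = "sexp"
    ref: float = 70.0
    init_k0: float = 1.2
    init_kmax: float = 0.5
    init_z50: float = 10.0
    init_hill: float = 2.0

    def param_defs(self) -> list[ParamDef]:
        return [
            ParamDef(f"{self.name}_k0", self.init_k0, "ident"),
            ParamDef(f"{self.name}_kmax", self.init_kmax, "log"),
            ParamDef(f"{self.name}_z50", self.init_z50, "log"),
            ParamDef(f"{self.name}_hill", self.init_hill, "log"),
        ]

    def factor(self, values: dict, cov: dict) -> np.ndarray:
        z = cov[self.driver]
        g = values[f"{self.name}_hill"]
        zg = z ** g
        expo = values[f"{self.name}_k0"] - values[f"{self.name}_kmax"] * zg / (
            values[f"{self.name}_z50"] ** g + zg
        )
        return (cov["WT"] / self.ref) ** expo


def WeightDependentExponentTerm(name: str = "wde", **kw) -> _SigmoidExponentTerm:
    """Allometric weight term whose exponent declines sigmoidally with weight."""
    return _SigmoidExponentTerm(driver="WT", name=name, init_z50=kw.pop("init_z50", 10.0), **kw)


def AgeDependentExponentTerm(name: str = "ade", **kw) -> _SigmoidExponentTerm:
    """Allometric weight term whose exponent declines sigmoidally with age."""
    return _SigmoidExponentTerm(driver="AGE", name=name, init_z50=kw.pop("init_z50", 1.0), **kw)


@dataclass(frozen=True)
class OmegaMatrix:
    """Diagonal IIV variances (log scale) for CL and V."""

    omega2_CL: float
    omega2_V: float

    def __post_init__(self) -> None:
        if self.omega2_CL < 0 or self.omega2_V < 0:
            raise ValueError("IIV variances must be >= 0")


@dataclass(frozen=True)
class SigmaSpec:
    """Residual error model: additive, proportional, or combined."""

    kind: str = "additive"
    sigma_add: float | None = 1.0
    sigma_prop: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown residual error kind: {self.kind}")
        need_add = self.kind in ("additive", "combined")
        need_prop = self.kind in ("proportional", "combined")
        if need_add and not (self.sigma_add and self.sigma_add > 0):
            raise ValueError("sigma_add must be positive for this error model")
        if need_prop and not (self.sigma_prop and self.sigma_prop > 0):
            raise ValueError("sigma_prop must be positive for this error model")
        if not need_add and self.sigma_add is not None:
            object.__setattr__(self, "sigma_add", None)
        if not need_prop and self.sigma_prop is not None:
            object.__setattr__(self, "sigma_prop", None)

    def variance(self, ipred) -> np.ndarray:
        """Residual variance as a function of the individual prediction."""
        v = 0.0
        if self.sigma_add is not None:
            v = v + self.sigma_add ** 2
        if self.sigma_prop is not None:
            v = v + (self.sigma_prop * np.asarray(ipred)) ** 2
        return v * np.ones_like(np.asarray(ipred, dtype=float))


@dataclass(frozen=True)
class ModelSpec:
    """Complete population-model specification."""

    cl_terms: tuple = ()
    v_terms: tuple = ()
    sigma_kind: str = "additive"
    iiv_cl: bool = True
    iiv_v: bool = True
    init: dict = field(default_factory=dict)

    # ---- parameter bookkeeping -------------------------------------
    def param_defs(self) -> list[ParamDef]:
        defaults = {
            "tvV": ParamDef("tvV", 20.0, "log"),
            "tvCL": ParamDef("tvCL", 5.0, "log"),
        }
        defs = [defaults["tvV"], defaults["tvCL"]]
        for term in list(self.cl_terms) + list(self.v_terms):
            defs.extend(term.param_defs())
        defs.append(ParamDef("om2_CL", 0.1, "log", fixed=not self.iiv_cl))
        defs.append(ParamDef("om2_V", 0.1, "log", fixed=not self.iiv_v))
        if self.sigma_kind in ("additive", "combined"):
            defs.append(ParamDef("sig_add", 1.0, "log"))
        if self.sigma_kind in ("proportional", "combined"):
            defs.append(ParamDef("sig_prop", 0.3, "log"))
        out = []
        for d in defs:
            init = self.init.get(d.name, d.init)
            if d.name == "om2_CL" and not self.iiv_cl:
                init = 0.0
            if d.name == "om2_V" and not self.iiv_v:
                init = 0.0
            out.append(replace(d, init=init))
        return out

    def free_defs(self) -> list[ParamDef]:
        return [d for d in self.param_defs() if not d.fixed]

    def initial_values(self) -> dict:
        return {d.name: d.init for d in self.param_defs()}

    def pack(self, values: dict) -> np.ndarray:
        x = []
        for d in self.free_defs():
            v = values[d.name]
            x.append(np.log(v) if d.transform == "log" else v)
        return np.array(x, dtype=float)

    def unpack(self, x: np.ndarray) -> dict:
        values = {d.name: d.init for d in self.param_defs() if d.fixed}
        for d, xi in zip(self.free_defs(), x):
            values[d.name] = float(np.exp(xi)) if d.transform == "log" else float(xi)
        return values

    # ---- model evaluation ------------------------------------------
    @staticmethod
    def _n(cov: dict, n: int | None) -> int:
        if n is not None:
            return n
        return len(np.asarray(next(iter(cov.values())))) if cov else 1

    def cl_pop(self, values: dict, cov: dict, n: int | None = None) -> np.ndarray:
        out = values["tvCL"] * np.ones(self._n(cov, n))
        for term in self.cl_terms:
            out = out * term.factor(values, cov)
        return out

    def v_pop(self, values: dict, cov: dict, n: int | None = None) -> np.ndarray:
        out = values["tvV"] * np.ones(self._n(cov, n))
        for term in self.v_terms:
            out = out * term.factor(values, cov)
        return out

    def sigma(self, values: dict) -> SigmaSpec:
        return SigmaSpec(
            kind=self.sigma_kind,
            sigma_add=values.get("sig_add"),
            sigma_prop=values.get("sig_prop"),
        )

    def omega(self, values: dict) -> OmegaMatrix:
        return OmegaMatrix(omega2_CL=values["om2_CL"], omega2_V=values["om2_V"])

    # ---- stepwise-editing helpers ----------------------------------
    def covariate_names(self, target: str) -> list[str]:
        terms = self.cl_terms if target == "CL" else self.v_terms
        return [t.covariate for t in terms if hasattr(t, "covariate")]

    def with_term(self, term, target: str) -> "ModelSpec":
        if target == "CL":
            return replace(self, cl_terms=tuple(self.cl_terms) + (term,))
        return replace(self, v_terms=tuple(self.v_terms) + (term,))

    def without_covariate(self, covariate: str, target: str) -> "ModelSpec":
        if target == "CL":
            kept = tuple(t for t in self.cl_terms if getattr(t, "covariate", None) != covariate)
            return replace(self, cl_terms=kept)
        kept = tuple(t for t in self.v_terms if getattr(t, "covariate", None) != covariate)
        return replace(self, v_terms=kept)

    def with_init(self, values: dict) -> "ModelSpec":
        known = {d.name for d in self.param_defs()}
        merged = dict(self.init)
        merged.update({k: v for k, v in values.items() if k in known})
        return replace(self, init=merged)


def base_model(sigma_kind: str = "additive", **init) -> ModelSpec:
    """Covariate-free one-compartment model with IIV on CL and V."""
    return ModelSpec(sigma_kind=sigma_kind, init=init)


def final_model(egfr_ref: float = 116.93, **init) -> ModelSpec:
    """The selected covariate model: weight on V (exponent fixed at 1),
    weight (estimated exponent) and eGFR on CL."""
    spec = ModelSpec(
        cl_terms=(
            PowerTerm("WT", 70.0, "CL~WT", init=0.9),
            PowerTerm("EGFR", egfr_ref, "CL~EGFR", init=0.38),
        ),
        v_terms=(PowerTerm("WT", 70.0, "V~WT", fixed_exponent=1.0),),
        sigma_kind="additive",
        init=init,
    )
    return spec
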