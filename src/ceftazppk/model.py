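"""One-compartment IV-infusion pharmacokinetics with covariate effects.

Closed-form concentration solutions (single infusion, multi-dose
superposition, steady state) for a one-compartment model with linear
elimination, parameterized by clearance CL and volume of distribution V.
The covariate model scales CL by body weight and estimated glomerular
filtration rate (eGFR) and V by body weight, each as a power of the
covariate normalized to a reference value:

    CL = tvCL * (WT/70)**theta2 * (eGFR/116.93)**theta3 * exp(eta_CL)
    V  = tvV  * (WT/70)**theta1 * exp(eta_V)

All functions accept scalars or numpy arrays (broadcasting) in the
numeric slots; times are hours since first dose, amounts mg,
concentrations mg/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ThetaVector",
    "EtaVector",
    "IndividualParams",
    "DoseEvent",
    "Regimen",
    "FINAL_MODEL_THETA",
    "individual_params",
    "conc_single_infusion",
    "conc_superposition",
    "conc_steady_state",
]


@dataclass(frozen=True)
class ThetaVector:
    """Fixed effects of the covariate model on CL and V.

    ``theta1``/``theta2`` are the weight exponents on V and CL;
    ``theta3`` is the eGFR exponent on CL.  ``wt_ref`` (kg) and
    ``egfr_ref`` (mL/min/1.73 m^2) are the normalizing constants.
    """

    tvV: float
    tvCL: float
    theta1: float = 1.0
    theta2: float = 0.9
    theta3: float = 0.38
    wt_ref: float = 70.0
    egfr_ref: float = 116.93

    def __post_init__(self) -> None:
        for name in ("tvV", "tvCL", "wt_ref", "egfr_ref"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


#: Final-model population estimates: typical V 27.83 L and CL 7.76 L/h at
#: 70 kg and eGFR 116.93 mL/min/1.73 m^2, weight exponent on CL 0.90 and
#: eGFR exponent 0.38 (weight exponent on V fixed at 1).
FINAL_MODEL_THETA = ThetaVector(tvV=27.83, tvCL=7.76, theta1=1.0, theta2=0.90, theta3=0.38)


@dataclass(frozen=True)
class EtaVector:
    """Subject-level random effects (log scale) on CL and V."""

    eta_CL: float = 0.0
    eta_V: float = 0.0


@dataclass(frozen=True)
class IndividualParams:
    """Realized individual clearance (L/h) and volume (L)."""

    CL: float
    V: float

    def __post_init__(self) -> None:
        if not np.all(np.asarray(self.CL) > 0):
            raise ValueError("CL must be positive")
        if not np.all(np.asarray(self.V) > 0):
            raise ValueError("V must be positive")

    @property
    def k(self):
        """Elimination rate constant CL/V (1/h); always derived."""
        return self.CL / self.V


@dataclass(frozen=True)
class DoseEvent:
    """A constant-rate IV infusion: start time (h), amount (mg), duration (h).

    Infusion duration is always explicit; a true bolus is not representable.
    """

    time: float
    amount: float
    tinf: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if not self.amount > 0:
            raise ValueError("dose amount must be positive")
        if not self.tinf > 0:
            raise ValueError("infusion duration must be positive")


@dataclass(frozen=True)
class Regimen:
    """A per-kg dosing regimen: dose (mg/kg), interval (h), infusion (h)."""

    dose_per_kg: float
    interval: float
    tinf: float = 0.5

    def __post_init__(self) -> None:
        if self.interval not in (6.0, 8.0, 12.0, 6, 8, 12):
            raise ValueError("interval must be 6, 8 or 12 h")
        if not self.dose_per_kg > 0:
            raise ValueError("dose_per_kg must be positive")
        if not self.tinf > 0:
            raise ValueError("tinf must be positive")

    @property
    def n_doses_per_day(self) -> int:
        return int(round(24 / self.interval))

    @property
    def daily_dose_per_kg(self) -> float:
        return self.dose_per_kg * self.n_doses_per_day


def individual_params(theta: ThetaVector, wt, egfr, eta: EtaVector = EtaVector()) -> IndividualParams:
    """Realize individual CL and V from covariates and random effects.

    ``wt`` and ``egfr`` may be scalars or arrays; ``eta`` components may
    likewise be arrays of matching shape.
    """
    wt = np.asarray(wt, dtype=float)
    egfr = np.asarray(egfr, dtype=float)
    if np.any(wt <= 0):
        raise ValueError("covariate wt must be positive")
    if np.any(egfr <= 0):
        raise ValueError("covariate egfr must be positive")
    CL = (
        theta.tvCL
        * (wt / theta.wt_ref) ** theta.theta2
        * (egfr / theta.egfr_ref) ** theta.theta3
        * np.exp(eta.eta_CL)
    )
    V = theta.tvV * (wt / theta.wt_ref) ** theta.theta1 * np.exp(eta.eta_V)
    return IndividualParams(CL=CL if CL.ndim else float(CL), V=V if V.ndim else float(V))


def _conc_infusion(CL, k, dose, tinf, t):
    """Vectorized single-infusion concentration at time t since dose start."""
    t = np.asarray(t, dtype=float)
    te = np.minimum(t, tinf)  # exposure time to the running infusion
    rate = dose / tinf
    c = (rate / CL) * (-np.expm1(-k * te)) * np.exp(-k * (t - te))
    return np.where(t > 0, c, 0.0)


def conc_single_infusion(ip: IndividualParams, dose: float, tinf: float, t) -> float | np.ndarray:
    """Concentration after one constant-rate infusion started at t = 0.

    During the infusion C(t) = (R0/CL)(1 - e^{-kt}) with R0 = dose/tinf;
    afterwards the concentration declines mono-exponentially.
    """
    if np.any(np.asarray(t) < 0):
        raise ValueError("t must be >= 0")
    out = _conc_infusion(ip.CL, ip.k, dose, tinf, t)
    return out if np.ndim(out) else float(out)


def conc_superposition(ip: IndividualParams, doses: Sequence[DoseEvent], t) -> float | np.ndarray:
    """Concentration under multiple infusions by linear superposition.

    ``doses`` must be sorted by start time; doses starting after ``t``
    contribute nothing.
    """
    times = [d.time for d in doses]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("doses must be sorted by time")
    t = np.asarray(t, dtype=float)
    total = np.zeros(np.broadcast(t, np.empty(())).shape, dtype=float)
    for d in doses:
        total = total + _conc_infusion(ip.CL, ip.k, d.amount, d.tinf, t - d.time)
    return total if total.ndim else float(total)


def conc_steady_state(ip: IndividualParams, reg: Regimen, wt: float, t_in_interval) -> float | np.ndarray:
    """Steady-state concentration at time t within the dosing interval.

    Closed-form infinite-superposition profile: the single-dose solution
    plus the accumulated tails of all earlier doses, which sum to the
    geometric accumulation factor e^{-k tau}/(1 - e^{-k tau}).
    """
    t = np.asarray(t_in_interval, dtype=float)
    if np.any(t < 0) or np.any(t > reg.interval):
        raise ValueError("t_in_interval must lie in [0, interval]")
    k = ip.k
    tau = float(reg.interval)
    dose = reg.dose_per_kg * wt
    rate = dose / reg.tinf
    # amount-normalized single-dose value at end of infusion
    a_end = (rate / ip.CL) * (-np.expm1(-k * reg.tinf))
    acc = np.exp(-k * tau) / (-np.expm1(-k * tau))
    current = _conc_infusion(ip.CL, k, dose, reg.tinf, np.maximum(t, 0.0))
    # tails of previous doses, all past end of their infusion
    tail = a_end * acc * np.exp(-k * (t - reg.tinf))
    out = current + tail
    return out if out.ndim else float(out)
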