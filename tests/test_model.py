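"""Structural model: covariate relations and closed-form infusion kinetics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

from ceftazppk.model import (
    FINAL_MODEL_THETA,
    DoseEvent,
    EtaVector,
    IndividualParams,
    Regimen,
    ThetaVector,
    conc_single_infusion,
    conc_steady_state,
    conc_superposition,
    individual_params,
)


def ode_concentration(CL, V, doses, t_eval):
    """Independent oracle: numerically integrate dC/dt = rate(t)/V - (CL/V) C."""
    def rate(t):
        return sum(d.amount / d.tinf for d in doses if d.time <= t < d.time + d.tinf)

    sol = solve_ivp(lambda t, y: [rate(t) / V - (CL / V) * y[0]], (0, max(t_eval) + 1e-9),
                    [0.0], t_eval=t_eval, rtol=1e-10, atol=1e-12, max_step=0.05)
    return sol.y[0]


class TestIndividualParams:
    def test_typical_subject_reproduces_published_estimates(self):
        ip = individual_params(FINAL_MODEL_THETA, wt=70.0, egfr=116.93)
        assert ip.CL == pytest.approx(7.76)
        assert ip.V == pytest.approx(27.83)

    def test_zero_exponents_remove_covariate_effects(self):
        th = ThetaVector(tvV=27.83, tvCL=7.76, theta2=0.0, theta3=0.0)
        for wt, egfr in [(5, 40), (30, 116.93), (95, 197)]:
            ip = individual_params(th, wt, egfr)
            assert ip.CL == pytest.approx(7.76)
            assert ip.V == pytest.approx(27.83 * wt / 70.0)

    def test_median_weight_child_clearance(self):
        # hand evaluation of the power model at the cohort median weight
        ip = individual_params(FINAL_MODEL_THETA, wt=18.35, egfr=116.93)
        assert ip.CL == pytest.approx(2.3257, rel=1e-3)

    @pytest.mark.parametrize("wt,egfr,name", [(-1, 100, "wt"), (0, 100, "wt"),
                                              (20, -5, "egfr"), (20, 0, "egfr")])
    def test_nonpositive_covariates_rejected_by_name(self, wt, egfr, name):
        with pytest.raises(ValueError, match=name):
            individual_params(FINAL_MODEL_THETA, wt, egfr)

    def test_eta_acts_multiplicatively_on_log_scale(self):
        ip0 = individual_params(FINAL_MODEL_THETA, 20, 100)
        ip1 = individual_params(FINAL_MODEL_THETA, 20, 100, EtaVector(0.3, -0.2))
        assert ip1.CL == pytest.approx(ip0.CL * np.exp(0.3))
        assert ip1.V == pytest.approx(ip0.V * np.exp(-0.2))

    def test_k_is_derived_ratio(self):
        ip = IndividualParams(CL=5.0, V=20.0)
        assert ip.k == pytest.approx(0.25)
        with pytest.raises(ValueError):
            IndividualParams(CL=-1.0, V=20.0)


class TestSingleInfusion:
    def test_zero_at_infusion_start(self):
        ip = IndividualParams(CL=7.76, V=27.83)
        assert conc_single_infusion(ip, 1000, 0.5, 0.0) == 0.0

    def test_long_infusion_reaches_clearance_plateau(self):
        ip = IndividualParams(CL=5.0, V=20.0)
        # constant-rate infusion: at t >> t_half, C -> R0/CL
        c = conc_single_infusion(ip, 1e6, 1e4, 200.0)
        assert c == pytest.approx((1e6 / 1e4) / 5.0, rel=1e-3)

    def test_matches_ode_oracle(self):
        ip = IndividualParams(CL=7.76, V=27.83)
        doses = [DoseEvent(0.0, 1000.0, 0.5)]
        t = np.array([0.25, 0.5, 2.0, 8.0])
        closed = np.array([conc_single_infusion(ip, 1000, 0.5, ti) for ti in t])
        oracle = ode_concentration(7.76, 27.83, doses, t)
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_negative_time_rejected(self):
        ip = IndividualParams(CL=5.0, V=20.0)
        with pytest.raises(ValueError):
            conc_single_infusion(ip, 100, 0.5, -1.0)


class TestSuperposition:
    def test_single_dose_reduces_to_single_infusion(self):
        ip = IndividualParams(CL=3.0, V=15.0)
        d = [DoseEvent(0.0, 500.0, 0.5)]
        for t in (0.2, 1.0, 9.0):
            assert conc_superposition(ip, d, t) == pytest.approx(
                conc_single_infusion(ip, 500.0, 0.5, t))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10), t=st.floats(0.1, 40))
    def test_linearity_in_dose(self, scale, t):
        ip = IndividualParams(CL=4.0, V=18.0)
        doses = [DoseEvent(8.0 * i, 600.0, 0.5) for i in range(5)]
        scaled = [DoseEvent(d.time, d.amount * scale, d.tinf) for d in doses]
        c1 = conc_superposition(ip, doses, t)
        c2 = conc_superposition(ip, scaled, t)
        assert c2 == pytest.approx(scale * c1, rel=1e-12, abs=1e-12)

    def test_multidose_matches_ode_oracle(self):
        ip = IndividualParams(CL=7.76, V=27.83)
        doses = [DoseEvent(8.0 * i, 900.0, 0.5) for i in range(5)]
        t = np.array([40.0])
        closed = conc_superposition(ip, doses, t)
        oracle = ode_concentration(7.76, 27.83, doses, t)
        assert np.allclose(closed, oracle, rtol=1e-6)

    def test_unsorted_doses_rejected(self):
        ip = IndividualParams(CL=3.0, V=15.0)
        doses = [DoseEvent(8.0, 100, 0.5), DoseEvent(0.0, 100, 0.5)]
        with pytest.raises(ValueError, match="sorted"):
            conc_superposition(ip, doses, 10.0)


class TestSteadyState:
    def test_agrees_with_long_superposition(self):
        ip = IndividualParams(CL=5.5, V=22.0)
        reg = Regimen(dose_per_kg=25.0, interval=8.0, tinf=0.5)
        wt = 30.0
        doses = [DoseEvent(8.0 * i, 25.0 * wt, 0.5) for i in range(20)]
        t_in = np.array([0.0, 0.25, 0.5, 3.0, 7.99])
        ss = conc_steady_state(ip, reg, wt, t_in)
        sup = conc_superposition(ip, doses, 19 * 8.0 + t_in)
        assert np.allclose(ss, sup, rtol=1e-6)

    def test_mass_balance_auc_times_cl_equals_dose(self):
        ip = IndividualParams(CL=4.2, V=19.0)
        reg = Regimen(dose_per_kg=40.0, interval=12.0, tinf=0.5)
        auc = quad(lambda t: conc_steady_state(ip, reg, 25.0, t), 0, 12, limit=200)[0]
        assert auc * ip.CL == pytest.approx(40.0 * 25.0, rel=1e-6)

    def test_no_accumulation_limit_equals_single_dose(self):
        # k*tau >> 1: everything washes out within an interval
        ip = IndividualParams(CL=50.0, V=5.0)
        reg = Regimen(dose_per_kg=30.0, interval=12.0, tinf=0.5)
        t = np.array([0.5, 1.0, 2.0])
        ss = conc_steady_state(ip, reg, 10.0, t)
        single = np.array([conc_single_infusion(ip, 300.0, 0.5, ti) for ti in t])
        assert np.allclose(ss, single, rtol=1e-5)

    def test_higher_clearance_gives_lower_trough(self):
        reg = Regimen(dose_per_kg=30.0, interval=8.0, tinf=0.5)
        rng = np.random.default_rng(7)
        for _ in range(20):
            V = rng.uniform(5, 40)
            cl_lo, cl_hi = np.sort(rng.uniform(0.5, 15, size=2))
            if cl_lo == cl_hi:
                continue
            trough_lo = conc_steady_state(IndividualParams(cl_lo, V), reg, 20.0, 0.0)
            trough_hi = conc_steady_state(IndividualParams(cl_hi, V), reg, 20.0, 0.0)
            assert trough_hi < trough_lo

    def test_time_outside_interval_rejected(self):
        ip = IndividualParams(CL=5.0, V=20.0)
        reg = Regimen(30.0, 8.0, 0.5)
        with pytest.raises(ValueError):
            conc_steady_state(ip, reg, 20.0, 9.0)


class TestDomainTypes:
    def test_dose_event_invariants(self):
        with pytest.raises(ValueError):
            DoseEvent(time=-1, amount=100, tinf=0.5)
        with pytest.raises(ValueError):
            DoseEvent(time=0, amount=0, tinf=0.5)
        with pytest.raises(ValueError):
            DoseEvent(time=0, amount=100, tinf=0.0)  # explicit infusion only

    def test_regimen_invariants(self):
        assert Regimen(30, 8).n_doses_per_day == 3
        assert Regimen(30, 12).daily_dose_per_kg == 60
        with pytest.raises(ValueError):
            Regimen(30, 7)
        with pytest.raises(ValueError):
            Regimen(-1, 8)

    def test_theta_vector_invariants(self):
        with pytest.raises(ValueError):
            ThetaVector(tvV=-1, tvCL=7.76)
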