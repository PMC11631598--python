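"""Estimation engine: OFV vs quadrature, fitting, EBEs, CWRES."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import optimize

from ceftazppk.dataset import PKDataset, Subject
from ceftazppk.estimate import EstimationError, cwres, ebe, fit, ofv
from ceftazppk.model import (
    FINAL_MODEL_THETA,
    DoseEvent,
    EtaVector,
    IndividualParams,
    conc_single_infusion,
    conc_superposition,
    individual_params,
)
from ceftazppk.modelspec import OmegaMatrix, PowerTerm, SigmaSpec, base_model, final_model
from ceftazppk.synth import CohortSpec, generate_cohort, generate_dataset
from tests.conftest import TABLE3_OMEGA, TABLE3_SIGMA, make_study_dataset, make_toy_dataset

TRUTH = {"tvV": 27.83, "tvCL": 7.76, "V~WT": 1.0, "CL~WT": 0.9, "CL~EGFR": 0.38,
         "om2_CL": 0.06, "om2_V": 0.04, "sig_add": 1.20}


def quadrature_ofv(ds: PKDataset, values: dict) -> float:
    """Independent brute-force quadrature of the marginal likelihood over a
    dense wide eta grid, using the high-level closed-form prediction path."""
    total = 0.0
    om_cl, om_v, sig = values["om2_CL"], values["om2_V"], values["sig_add"]
    g = np.linspace(-4.5, 4.5, 901)
    dg = g[1] - g[0]
    ecl, ev = (a.ravel() for a in np.meshgrid(g, g, indexing="ij"))
    for s in ds.subjects:
        clpop = values["tvCL"] * (s.covariates["WT"] / 70) ** values["CL~WT"] \
            * (s.covariates["EGFR"] / 116.93) ** values["CL~EGFR"]
        vpop = values["tvV"] * (s.covariates["WT"] / 70) ** values["V~WT"]
        ip = IndividualParams(CL=clpop * np.exp(ecl), V=vpop * np.exp(ev))
        ll = -0.5 * (ecl ** 2 / om_cl + np.log(2 * np.pi * om_cl)
                     + ev ** 2 / om_v + np.log(2 * np.pi * om_v))
        for t, dv in zip(s.obs_times, s.obs_dv):
            f = np.zeros_like(ecl)
            for d in s.doses:
                dt = t - d.time
                if dt > 0:
                    te = min(dt, d.tinf)
                    f += conc_single_infusion(ip, d.amount, d.tinf, te) \
                        * np.exp(-ip.k * (dt - te))
            ll += -0.5 * ((dv - f) ** 2 / sig ** 2 + np.log(2 * np.pi * sig ** 2))
        m = ll.max()
        total += -2.0 * (m + np.log(np.exp(ll - m).sum() * dg * dg))
    return total


class TestOfv:
    def test_collapses_to_weighted_least_squares_without_iiv(self):
        ds = make_toy_dataset(n_subjects=4, seed=1)
        spec = replace(final_model(), iiv_cl=False, iiv_v=False)
        vals = dict(TRUTH, om2_CL=0.0, om2_V=0.0)
        got = ofv(ds, spec, vals)
        # closed form: sum (y - PRED)^2/sigma^2 + n (ln sigma^2 + ln 2 pi)
        expect = 0.0
        for s in ds.subjects:
            ip = individual_params(FINAL_MODEL_THETA, s.covariates["WT"], s.covariates["EGFR"])
            f = np.asarray(conc_superposition(ip, s.doses, s.obs_times))
            expect += np.sum((s.obs_dv - f) ** 2 / 1.2 ** 2
                             + np.log(1.2 ** 2) + np.log(2 * np.pi))
        assert got == pytest.approx(expect, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_brute_force_quadrature(self, seed):
        # random draws around the study's magnitudes (omega^2 0.04/0.06,
        # additive sigma 1.2 mg/L)
        rng = np.random.default_rng(seed)
        ds = make_toy_dataset(n_subjects=3, seed=seed)
        vals = dict(TRUTH,
                    om2_CL=float(rng.uniform(0.02, 0.10)),
                    om2_V=float(rng.uniform(0.02, 0.10)),
                    sig_add=float(rng.uniform(0.8, 1.8)))
        assert ofv(ds, final_model(), vals) == pytest.approx(
            quadrature_ofv(ds, vals), abs=0.1)

    def test_subject_relabeling_leaves_ofv_unchanged(self):
        ds = make_toy_dataset(n_subjects=5, seed=3)
        perm = PKDataset(subjects=[ds.subjects[i] for i in (3, 0, 4, 2, 1)])
        spec = final_model()
        assert ofv(ds, spec, TRUTH) == pytest.approx(ofv(perm, spec, TRUTH), abs=1e-9)


class TestFit:
    def test_recovers_typical_values_without_iiv_rich_sampling(self):
        # omega = 0, 6 samples/subject: near-deterministic identification
        spec_gen = CohortSpec(seed=61, n_subjects=50, samples_per_subject=(3, 3),
                              samples_probs=(1.0,))
        cohort = generate_cohort(spec_gen)
        sd = generate_dataset(cohort, FINAL_MODEL_THETA, OmegaMatrix(0.0, 0.0),
                              SigmaSpec("additive", 0.5), spec_gen)
        mspec = replace(final_model(), iiv_cl=False, iiv_v=False)
        fr = fit(sd.dataset, mspec, options={"compute_se": False})
        assert fr.converged
        assert fr.values["tvCL"] == pytest.approx(7.76, rel=0.02)
        assert fr.values["tvV"] == pytest.approx(27.83, rel=0.02)

    def test_refit_from_truth_does_not_increase_ofv(self, study_synth, final_spec):
        ds = study_synth.dataset
        at_truth = ofv(ds, final_spec, study_synth.truth)
        fr = fit(ds, final_spec, init=study_synth.truth, options={"compute_se": False})
        assert fr.ofv <= at_truth + 1e-6

    def test_adding_unused_covariate_never_increases_ofv(self):
        sd = make_study_dataset(seed=71, n_subjects=40)
        ds = sd.dataset
        rng = np.random.default_rng(0)
        for s in ds.subjects:
            s.covariates["NOISE"] = float(rng.lognormal(0, 0.3))
        base = fit(ds, final_model(), options={"compute_se": False, "nodes": 1})
        super_spec = base.spec.with_term(PowerTerm("NOISE", 1.0, "CL~NOISE", init=0.0), "CL")
        sup = fit(ds, super_spec, init=base.values,
                  options={"compute_se": False, "nodes": 1})
        assert sup.ofv <= base.ofv + 1e-3

    def test_standard_errors_reported(self):
        sd = make_study_dataset(seed=81, n_subjects=40)
        fr = fit(sd.dataset, final_model())
        assert fr.converged
        for name in ("tvV", "tvCL", "sig_add"):
            assert fr.rse_pct[name] > 0

    def test_invalid_initial_values_rejected(self, study_synth, final_spec):
        with pytest.raises(ValueError, match="positive"):
            fit(study_synth.dataset, final_spec, init={"tvCL": -5.0})


class TestEbe:
    def test_prior_mode_without_observations(self, final_spec):
        s = Subject(id=1, covariates={"WT": 20.0, "EGFR": 100.0},
                    doses=[DoseEvent(0.0, 600.0, 0.5)],
                    obs_times=np.empty(0), obs_dv=np.empty(0))
        assert np.allclose(ebe(s, final_spec, TRUTH), [0.0, 0.0])

    def test_flat_prior_limit_approaches_least_squares(self, final_spec):
        rng = np.random.default_rng(5)
        wt, egfr = 25.0, 110.0
        doses = [DoseEvent(8.0 * i, 30 * wt, 0.5) for i in range(3)]
        t = np.array([0.6, 4.0, 10.0, 17.0, 23.0])
        ip_true = individual_params(FINAL_MODEL_THETA, wt, egfr, EtaVector(0.35, -0.25))
        dv = np.asarray(conc_superposition(ip_true, doses, t)) + 0.2 * rng.normal(size=len(t))
        s = Subject(id=1, covariates={"WT": wt, "EGFR": egfr}, doses=doses,
                    obs_times=t, obs_dv=dv)
        vals = dict(TRUTH, om2_CL=100.0, om2_V=100.0, sig_add=0.2)
        eta = ebe(s, final_spec, vals)[0]

        ip_pop = individual_params(FINAL_MODEL_THETA, wt, egfr)

        def ssr(x):
            ip = IndividualParams(CL=ip_pop.CL * np.exp(x[0]), V=ip_pop.V * np.exp(x[1]))
            f = np.asarray(conc_superposition(ip, doses, t))
            return np.sum((dv - f) ** 2)

        ls = optimize.minimize(ssr, [0, 0], method="Nelder-Mead",
                               options={"xatol": 1e-12, "fatol": 1e-14}).x
        assert np.allclose(eta, ls, atol=5e-3)

    def test_matches_independent_mode_search(self, final_spec):
        ds = make_toy_dataset(n_subjects=1, seed=9)
        s = ds.subjects[0]
        eta = ebe(s, final_spec, TRUTH)[0]

        clpop = 7.76 * (s.covariates["WT"] / 70) ** 0.9 * (s.covariates["EGFR"] / 116.93) ** 0.38
        vpop = 27.83 * (s.covariates["WT"] / 70)

        def neg2joint(x):
            ip = IndividualParams(CL=clpop * np.exp(x[0]), V=vpop * np.exp(x[1]))
            f = np.asarray(conc_superposition(ip, s.doses, s.obs_times))
            return (np.sum((s.obs_dv - f) ** 2) / 1.2 ** 2
                    + x[0] ** 2 / 0.06 + x[1] ** 2 / 0.04)

        # coarse grid scan then polish: an independent mode oracle
        grid = np.linspace(-1.0, 1.0, 81)
        vals = [(neg2joint([a, b]), a, b) for a in grid for b in grid]
        _, a0, b0 = min(vals)
        res = optimize.minimize(neg2joint, [a0, b0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert np.allclose(eta, res.x, atol=1e-4)


class TestCwres:
    def test_reduces_to_population_residuals_without_iiv(self):
        ds = make_toy_dataset(n_subjects=4, seed=11)
        spec = replace(final_model(), iiv_cl=False, iiv_v=False)
        fr = fit(ds, spec, init=dict(TRUTH, om2_CL=0.0, om2_V=0.0),
                 options={"compute_se": False})
        tab = cwres(ds, fr)
        sig = fr.values["sig_add"]
        assert np.allclose(tab["CWRES"], (tab["DV"] - tab["PRED"]) / sig, atol=1e-6)

    def test_invariant_to_subject_order(self, study_synth, final_spec):
        ds = study_synth.dataset
        fr = fit(ds, final_spec, init=study_synth.truth, options={"compute_se": False})
        tab = cwres(ds, fr)
        rng = np.random.default_rng(1)
        order = rng.permutation(ds.n_subjects)
        ds_perm = PKDataset(subjects=[ds.subjects[i] for i in order])
        tab_perm = cwres(ds_perm, fr)
        a = tab.set_index(["ID", "TIME"]).sort_index()
        b = tab_perm.set_index(["ID", "TIME"]).sort_index()
        assert np.allclose(a["CWRES"], b["CWRES"], atol=1e-8)

    def test_calibrated_on_well_specified_data(self):
        # large simulated dataset at the generating truth: CWRES ~ N(0,1),
        # so the within-(-2,2) fraction should sit near 95.4%
        sd = make_study_dataset(seed=91, n_subjects=600)
        fr = fit(sd.dataset, final_model(), init=sd.truth,
                 options={"compute_se": False, "presearch": False, "maxiter": 60})
        tab = cwres(sd.dataset, fr)
        frac = float(np.mean(np.abs(tab["CWRES"]) < 2.0))
        assert frac == pytest.approx(0.954, abs=0.02)
        assert abs(tab["CWRES"].mean()) < 0.1

    def test_carries_required_columns(self, study_synth, final_spec):
        ds = study_synth.dataset
        fr = fit(ds, final_spec, init=study_synth.truth, options={"compute_se": False})
        tab = cwres(ds, fr)
        assert list(tab.columns) == ["ID", "TIME", "TAD", "DV", "IPRED", "PRED", "CWRES"]
        assert len(tab) == ds.n_obs
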