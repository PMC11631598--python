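"""Covariate prescreen, stepwise selection, and maturation-model ranking."""

import warnings

import numpy as np
import pytest

from ceftazppk.covariates import (
    CovariateCandidate,
    backward_eliminate,
    compare_maturation_models,
    forward_select,
    prescreen,
    step_log_frame,
    stepwise,
)
from ceftazppk.estimate import fit
from ceftazppk.model import ThetaVector
from ceftazppk.modelspec import PowerTerm, base_model, final_model
from tests.conftest import TABLE3_OMEGA, TABLE3_SIGMA, make_study_dataset

FAST = {"nodes": 1}


@pytest.fixture(scope="module")
def egfr_effect_data():
    """Synthetic study replicate generated with the real covariate model
    (weight and eGFR effects on CL)."""
    return make_study_dataset(seed=20240205)


@pytest.fixture(scope="module")
def wt_base_fit(egfr_effect_data):
    """Base for the eGFR question: weight effects already in the model."""
    ds = egfr_effect_data.dataset
    spec = base_model().with_term(PowerTerm("WT", 70.0, "CL~WT", init=0.9), "CL") \
                       .with_term(PowerTerm("WT", 70.0, "V~WT", fixed_exponent=1.0), "V")
    return fit(ds, spec, options=dict(FAST, compute_se=False))


class TestPrescreen:
    def test_perfect_association_retained_with_tiny_p(self, egfr_effect_data, wt_base_fit):
        ds = egfr_effect_data.dataset
        from ceftazppk.covariates import _individual_cl

        icl = _individual_cl(ds, wt_base_fit)
        for s, v in zip(ds.subjects, icl):
            s.covariates["SELF"] = float(v)
        try:
            out = prescreen(ds, wt_base_fit, continuous=("SELF",), categorical=())
        finally:
            for s in ds.subjects:
                del s.covariates["SELF"]
        assert out[0].retained and out[0].prescreen_p < 1e-10

    def test_constant_covariate_skipped_with_warning(self, egfr_effect_data, wt_base_fit):
        ds = egfr_effect_data.dataset
        for s in ds.subjects:
            s.covariates["CONST"] = 1.0
        try:
            with pytest.warns(UserWarning, match="constant"):
                out = prescreen(ds, wt_base_fit, continuous=("CONST",), categorical=())
        finally:
            for s in ds.subjects:
                del s.covariates["CONST"]
        assert out == []

    def test_type_one_error_calibrated(self, egfr_effect_data, wt_base_fit):
        # covariate independent of CL: retention rate should sit near alpha
        ds = egfr_effect_data.dataset
        rng = np.random.default_rng(17)
        hits = 0
        n_rep = 400
        for _ in range(n_rep):
            x = rng.lognormal(0, 0.5, size=ds.n_subjects)
            for s, v in zip(ds.subjects, x):
                s.covariates["RND"] = float(v)
            out = prescreen(ds, wt_base_fit, continuous=("RND",), categorical=())
            hits += out[0].retained
        for s in ds.subjects:
            del s.covariates["RND"]
        assert hits / n_rep == pytest.approx(0.05, abs=0.025)

    def test_prescreen_covers_full_panel(self, egfr_effect_data, wt_base_fit):
        out = prescreen(egfr_effect_data.dataset, wt_base_fit)
        names = {c.name for c in out}
        assert {"WT", "AGE", "EGFR", "SEX"} <= names
        assert all(0 <= c.prescreen_p <= 1 for c in out)


class TestForwardSelect:
    def test_decision_consistent_with_delta_ofv_threshold(self, egfr_effect_data,
                                                          wt_base_fit):
        # on a single replicate the eGFR signal may or may not clear 3.84;
        # the decision must match the measured OFV drop either way
        ds = egfr_effect_data.dataset
        cands = [CovariateCandidate("EGFR", "CL", "power", 0.001, True)]
        final, records = forward_select(ds, wt_base_fit, cands, fit_options=FAST)
        adds = [r for r in records if r.action == "add"]
        assert len(adds) == 1
        selected = "EGFR" in final.spec.covariate_names("CL")
        assert selected == (adds[0].delta_ofv < -3.84)
        if selected:
            assert final.ofv < wt_base_fit.ofv

    def test_null_candidate_not_added(self, egfr_effect_data, wt_base_fit):
        ds = egfr_effect_data.dataset
        rng = np.random.default_rng(23)
        for s in ds.subjects:
            s.covariates["RND"] = float(rng.lognormal(0, 0.5))
        try:
            cands = [CovariateCandidate("RND", "CL", "power", 0.01, True)]
            final, records = forward_select(ds, wt_base_fit, cands, fit_options=FAST)
        finally:
            for s in ds.subjects:
                del s.covariates["RND"]
        assert "RND" not in final.spec.covariate_names("CL")
        assert any("stopped" in r.decision for r in records)

    def test_no_candidates_returns_base(self, egfr_effect_data, wt_base_fit):
        final, records = forward_select(egfr_effect_data.dataset, wt_base_fit, [])
        assert final is wt_base_fit
        assert records == []


class TestBackwardEliminate:
    def test_empty_model_is_identity(self, egfr_effect_data):
        ds = egfr_effect_data.dataset
        base = fit(ds, base_model(), options=dict(FAST, compute_se=False))
        final, records = backward_eliminate(ds, base)
        assert final is base
        assert records == []

    def test_strong_weight_effect_survives_elimination(self, egfr_effect_data):
        # the weight effect on CL is overwhelming (dOFV tens of points),
        # so backward elimination must keep it; the weaker eGFR term may go
        # either way on a single replicate, consistently with its dOFV
        ds = egfr_effect_data.dataset
        full = fit(ds, final_model(), options=dict(FAST, compute_se=False))
        final, records = backward_eliminate(ds, full, protected=(("V", "WT"),),
                                            fit_options=FAST)
        assert "WT" in final.spec.covariate_names("CL")
        egfr_kept = "EGFR" in final.spec.covariate_names("CL")
        egfr_steps = [r for r in records if r.covariate == "EGFR" and r.action == "remove"]
        if egfr_steps:
            assert egfr_kept == (egfr_steps[-1].delta_ofv >= 6.635)

    def test_step_log_frame_reconstructs_path(self, egfr_effect_data, wt_base_fit):
        ds = egfr_effect_data.dataset
        cands = [CovariateCandidate("EGFR", "CL", "power", 0.001, True)]
        _, records = forward_select(ds, wt_base_fit, cands, fit_options=FAST)
        df = step_log_frame(records)
        assert set(df.columns) >= {"step", "action", "covariate", "ofv_before",
                                   "ofv_after", "delta_ofv", "decision", "threshold"}
        assert np.allclose(df["delta_ofv"], df["ofv_after"] - df["ofv_before"],
                           equal_nan=True)


class TestMaturationModels:
    @pytest.fixture(scope="class")
    def maturation_table(self, egfr_effect_data):
        ds = egfr_effect_data.dataset
        full = fit(ds, final_model(), options=dict(FAST, compute_se=False))
        return full, compare_maturation_models(ds, full, fit_options=FAST)

    def test_estimated_exponent_model_is_the_full_model(self, maturation_table):
        full, table = maturation_table
        assert set(table["model"]) == {"I", "II", "III", "IV", "V"}
        row_ii = table[table["model"] == "II"].iloc[0]
        assert row_ii["ofv"] == pytest.approx(full.ofv, abs=1.0)

    def test_ranking_prefers_lower_ofv_among_stable(self, maturation_table):
        _, table = maturation_table
        ranked = table.dropna(subset=["rank"]).sort_values("rank")
        assert len(ranked) >= 1
        ofvs = ranked["ofv"].to_numpy()
        assert (np.diff(ofvs) >= -1e-6).all()
        assert not ranked.iloc[0]["boundary"]

    def test_estimated_exponent_beats_fixed_when_truth_is_steeper(self):
        # generating exponent 0.9 vs the fixed 0.75 allometric model: the
        # nested estimated-exponent fit must attain a lower OFV
        from ceftazppk.modelspec import final_model as _fm

        wins = 0
        n_rep = 4
        for i in range(n_rep):
            sd = make_study_dataset(seed=3000 + i, n_subjects=60)
            ds = sd.dataset
            spec_ii = _fm()
            spec_i = spec_ii.without_covariate("WT", "CL").with_term(
                PowerTerm("WT", 70.0, "CL~WT", fixed_exponent=0.75), "CL")
            f_ii = fit(ds, spec_ii, options=dict(FAST, compute_se=False))
            f_i = fit(ds, spec_i, init=f_ii.values,
                      options=dict(FAST, compute_se=False, presearch=False))
            wins += f_ii.ofv < f_i.ofv
        assert wins == n_rep


class TestStepwiseEndToEnd:
    def test_recovers_generating_covariates(self):
        ds = make_study_dataset(seed=20240210, n_subjects=50).dataset
        base = fit(ds, base_model(), options=dict(FAST, compute_se=False))
        cands = prescreen(ds, base)
        final, records = stepwise(ds, base, cands, fit_options=FAST)
        # weight (or its strongly collinear proxies BSA/HT/AGE/BMI) must be
        # selected; the true eGFR effect should survive elimination
        sel = set(final.spec.covariate_names("CL")) | set(final.spec.covariate_names("V"))
        assert sel & {"WT", "BSA", "HT", "AGE", "BMI"}
        assert final.ofv < base.ofv - 3.84
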