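import numpy as np
import pytest

from ceftazppk.dataset import PKDataset, Subject
from ceftazppk.model import (
    FINAL_MODEL_THETA,
    DoseEvent,
    EtaVector,
    conc_superposition,
    individual_params,
)
from ceftazppk.modelspec import OmegaMatrix, SigmaSpec, final_model
from ceftazppk.synth import CohortSpec, generate_cohort, generate_dataset

#: generating truth used throughout: the published final-model estimates
TABLE3_OMEGA = OmegaMatrix(omega2_CL=0.06, omega2_V=0.04)
TABLE3_SIGMA = SigmaSpec("additive", sigma_add=1.20)


@pytest.fixture(scope="session")
def table3_theta():
    return FINAL_MODEL_THETA


@pytest.fixture(scope="session")
def table3_omega():
    return TABLE3_OMEGA


@pytest.fixture(scope="session")
def table3_sigma():
    return TABLE3_SIGMA


def make_study_dataset(seed: int, n_subjects: int = 88, theta=FINAL_MODEL_THETA,
                       omega=TABLE3_OMEGA, sigma=TABLE3_SIGMA):
    """One synthetic replicate of the study design (sparse opportunistic
    sampling, Table-1-like cohort)."""
    spec = CohortSpec(seed=seed, n_subjects=n_subjects)
    cohort = generate_cohort(spec)
    return generate_dataset(cohort, theta, omega, sigma, spec)


@pytest.fixture(scope="session")
def study_synth():
    return make_study_dataset(seed=20240101)


@pytest.fixture(scope="session")
def final_spec():
    return final_model()


def make_toy_subject(sid, wt, egfr, obs_times, rng, theta=FINAL_MODEL_THETA,
                     omega=TABLE3_OMEGA, sigma_add=1.2, n_doses=3, dose_per_kg=30.0,
                     tau=8.0):
    """Small hand-assembled subject with observations simulated from the model."""
    doses = [DoseEvent(i * tau, dose_per_kg * wt, 0.5) for i in range(n_doses)]
    eta = EtaVector(rng.normal(0, np.sqrt(omega.omega2_CL)),
                    rng.normal(0, np.sqrt(omega.omega2_V)))
    ip = individual_params(theta, wt, egfr, eta)
    t = np.asarray(obs_times, dtype=float)
    f = np.asarray(conc_superposition(ip, doses, t), dtype=float)
    dv = np.abs(f + sigma_add * rng.normal(size=len(t)))
    return Subject(id=sid, covariates={"WT": wt, "EGFR": egfr}, doses=doses,
                   obs_times=t, obs_dv=dv)


def make_toy_dataset(n_subjects=3, seed=0, **kw):
    rng = np.random.default_rng(seed)
    subs = []
    for i in range(n_subjects):
        wt = float(rng.uniform(5, 60))
        egfr = float(rng.uniform(50, 180))
        n_obs = int(rng.integers(1, 4))
        tobs = np.sort(rng.uniform(0.5, 24, n_obs))
        subs.append(make_toy_subject(i + 1, wt, egfr, tobs, rng, **kw))
    return PKDataset(subjects=subs)
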