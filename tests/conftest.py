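import numpy as np
import pytest

from vancopk import (
    CohortConfig,
    Covariates,
    DosingEvent,
    IndividualParameters,
    PopulationParameters,
    load_model_spec,
    simulate_dataset,
)
from vancopk.cohort import Observation, SubjectRecord
from vancopk.covariates import ResidualErrorSpec


@pytest.fixture(scope="session")
def model2_spec():
    return load_model_spec("model2")


@pytest.fixture(scope="session")
def model2_params():
    return PopulationParameters.published("model2")


@pytest.fixture(scope="session")
def model1_spec():
    return load_model_spec("model1")


@pytest.fixture(scope="session")
def model1_params():
    return PopulationParameters.published("model1")


@pytest.fixture(scope="session")
def arc_cohort(model2_spec, model2_params):
    """One 64-subject ARC cohort simulated from the published model."""
    cfg = CohortConfig(n_subjects=64, group="augmented", seed=20240501)
    return simulate_dataset(cfg, model2_params, model2_spec)


def make_toy_subject(sid="T1", cl=0.7, v=4.0, dv=None, times=(7.5, 9.5),
                     n_doses=5, amount=60.0, interval=8.0, wt=4.6, scr=16.8):
    """Hand-built subject with a q8h regimen and explicit observations."""
    from vancopk.pk import concentration_at

    doses = tuple(DosingEvent(i * interval, amount, 1.0) for i in range(n_doses))
    ip = IndividualParameters(cl, v)
    times = tuple(times)
    if dv is None:
        dv = [float(concentration_at(t, doses, ip)) for t in times]
    obs = tuple(Observation(t, y, "trough" if j == 0 else "peak")
                for j, (t, y) in enumerate(zip(times, dv)))
    cov = Covariates(wt=wt, ht=54.0, scr=scr, age_months=1.0)
    return SubjectRecord(id=sid, covariates=cov, egfr=127.9, group="augmented",
                         doses=doses, observations=obs)


@pytest.fixture()
def toy_subject():
    return make_toy_subject()


@pytest.fixture()
def toy_params(model2_spec):
    return PopulationParameters(
        theta=tuple(model2_spec.theta), omega_cl=0.3,
        sigma=ResidualErrorSpec("proportional", 0.2), spec=model2_spec,
    )
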