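"""Shared fixtures: synthetic datasets and fitted objects reused across tests.

Session scope keeps the expensive nonlinear fits to one run each; every
fixture is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from doxopkpd.fitting import fit_response_models
from doxopkpd.pk import PKParameters
from doxopkpd.synthetic import (
    ExperimentDesign,
    TruthSurfaces,
    generate_pk_dataset,
    generate_response_dataset,
)
from doxopkpd.workflow import dose_data_for_exposure, fit_growth_from_counts


@pytest.fixture(scope="session")
def design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def small_design():
    """Reduced plate for the heavier fitting tests: 5 doses + control."""
    return ExperimentDesign(
        response_concentrations=(0.0, 10.0, 39.0, 156.0, 625.0, 2500.0),
        post_treatment_days=20,
    )


@pytest.fixture(scope="session")
def truth_noiseless():
    return TruthSurfaces(noise_cv=0.0)


@pytest.fixture(scope="session")
def truth_noisy():
    return TruthSurfaces()  # default 5% CV


@pytest.fixture(scope="session")
def pk_dataset_noiseless(truth_noiseless, design):
    return generate_pk_dataset(truth_noiseless, design, seed=11)


@pytest.fixture(scope="session")
def response_dataset_noiseless(truth_noiseless, design):
    return generate_response_dataset(truth_noiseless, design, seed=11)


@pytest.fixture(scope="session")
def response_dataset_noisy(truth_noisy, design):
    return generate_response_dataset(truth_noisy, design, seed=7)


@pytest.fixture(scope="session")
def pk_params_true(response_dataset_noisy):
    _, rec = response_dataset_noisy
    return PKParameters(**rec["pk"])


@pytest.fixture(scope="session")
def growth_noisy(response_dataset_noisy):
    df, _ = response_dataset_noisy
    return fit_growth_from_counts(df)


@pytest.fixture(scope="session")
def training_12h(response_dataset_noisy, pk_params_true, growth_noisy):
    """Both-variant response fits on the noisy 12 h exposure experiment."""
    df, _ = response_dataset_noisy
    data = dose_data_for_exposure(df, 12.0, pk_params_true)
    return fit_response_models(data, growth_noisy.growth_, 12.0, alpha=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
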