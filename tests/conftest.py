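import logging

import numpy as np
import pytest

from survgam.model import DeltaGammaModel, DeltaModelSpec, FitOptions
from survgam.simulate import DomainConfig, generate_domain, simulate_survey

logging.getLogger("survgam").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_truth():
    """Small deterministic-habitat domain (no latent fields)."""
    cfg = DomainConfig(
        extent_km=100.0,
        grid_res_km=10.0,
        n_years=3,
        sigma_spatial=0.0,
        sigma_st=0.0,
        n_strata=2,
        truth_mesh_cutoff_km=25.0,
    )
    return generate_domain(cfg, seed=7)


@pytest.fixture(scope="session")
def small_survey(small_truth):
    return simulate_survey(small_truth, n_per_year=60, seed=17)


@pytest.fixture(scope="session")
def field_truth():
    """Domain with spatial + AR1 spatio-temporal fields."""
    cfg = DomainConfig(
        extent_km=120.0,
        grid_res_km=6.0,
        n_years=4,
        sigma_spatial=0.6,
        sigma_st=0.6,
        rho=0.6,
        n_strata=3,
        truth_mesh_cutoff_km=20.0,
    )
    return generate_domain(cfg, seed=3)


@pytest.fixture(scope="session")
def field_survey(field_truth):
    return simulate_survey(field_truth, n_per_year=70, seed=13)


@pytest.fixture(scope="session")
def glm_fit(small_survey):
    """Delta fit with smoothers only (no fields) on the small survey."""
    spec = DeltaModelSpec.from_formula("year + temp + depth", n_knots=5)
    model = DeltaGammaModel(small_survey, spec)
    return model.fit(seed=0, options=FitOptions(compute_se="none"))


@pytest.fixture(scope="session")
def field_fit(field_survey):
    """Full spatio-temporal delta fit on the field survey."""
    spec = DeltaModelSpec.from_formula("year + temp + depth + spatial + AR1", n_knots=5)
    model = DeltaGammaModel(field_survey, spec, mesh_cutoff_km=30.0)
    return model.fit(seed=0, options=FitOptions(compute_se="none"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
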