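"""Joint likelihood and Laplace marginal against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from survgam.data import SurveyDataset
from survgam.families import BernoulliLogit, GammaLog, GaussianIdentity, LinearPredictorOverflow
from survgam.geo import LocalProjection
from survgam.model import (
    DeltaGammaModel,
    DeltaModelSpec,
    build_bundle,
    joint_nll,
    laplace_marginal_nll,
    profile_laplace_nll,
)


def _tiny_dataset(n=20, seed=0, all_positive=False):
    rng = np.random.default_rng(seed)
    proj = LocalProjection(-51.0, 45.0)
    x = rng.uniform(0, 100, n)
    y = rng.uniform(0, 100, n)
    lon, lat = proj.to_lonlat(x, y)
    z = np.ones(n, dtype=int) if all_positive else rng.integers(0, 2, n)
    biomass = np.where(z == 1, rng.gamma(2.0, 3.0, n) + 0.01, 0.0)
    tows = pd.DataFrame(
        {
            "tow_id": np.arange(n),
            "x": x,
            "y": y,
            "lon": lon,
            "lat": lat,
            "year": 2000 + (np.arange(n) % 3),
            "depth_m": rng.uniform(50, 400, n),
            "temp_c": rng.uniform(0, 6, n),
            "swept_km2": rng.uniform(0.02, 0.03, n),
            "z": z,
            "biomass_kg": biomass,
            "stratum": 0,
        }
    )
    strata = pd.DataFrame(
        {"stratum": [0], "depth_min_m": [0.0], "depth_max_m": [500.0], "area_km2": [1e4]}
    )
    return SurveyDataset(tows=tows, strata=strata, projection=proj)


GLM_SPEC = DeltaModelSpec(covariates=(), year_effect=True, spatial=False, st_structure="none")


class TestJointNll:
    def test_bernoulli_matches_direct_formula(self):
        ds = _tiny_dataset(20, seed=1)
        b = build_bundle(ds, GLM_SPEC, BernoulliLogit)
        beta = np.array([0.3, -0.2, 0.5])
        val = joint_nll(beta, np.zeros(0), b)
        eta = b.x @ beta + b.offset
        p = 1.0 / (1.0 + np.exp(-eta))
        oracle = -np.sum(b.y * np.log(p) + (1 - b.y) * np.log(1 - p))
        assert val == pytest.approx(oracle, rel=1e-10)

    def test_gamma_matches_direct_formula(self):
        ds = _tiny_dataset(20, seed=2, all_positive=True)
        b = build_bundle(ds, GLM_SPEC, GammaLog)
        outer = np.array([1.0, 0.1, -0.3, np.log(1.7)])  # beta, log_phi
        val = joint_nll(outer, np.zeros(0), b)
        from scipy.stats import gamma as gamma_dist

        phi = 1.7
        mu = np.exp(b.x @ outer[:3] + b.offset)
        oracle = -np.sum(gamma_dist.logpdf(b.y, a=phi, scale=mu / phi))
        assert val == pytest.approx(oracle, rel=1e-9)

    def test_gamma_shape_one_is_exponential(self):
        # five hand-computable points: phi=1 gives f(y) = exp(-y/mu)/mu
        y = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        eta = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        mu = np.exp(eta)
        oracle = float(np.sum(np.log(mu) + y / mu))
        assert GammaLog.nll(y, eta, 1.0) == pytest.approx(oracle, rel=1e-12)

    def test_offset_intercept_reparameterization_invariance(self):
        ds = _tiny_dataset(20, seed=3)
        b = build_bundle(ds, GLM_SPEC, BernoulliLogit)
        beta = np.array([0.4, -0.1, 0.2])
        v1 = joint_nll(beta, np.zeros(0), b)
        c = 1.234
        b2 = build_bundle(ds, GLM_SPEC, BernoulliLogit)
        b2.offset = b.offset + c
        beta2 = beta.copy()
        beta2[0] -= c
        assert joint_nll(beta2, np.zeros(0), b2) == pytest.approx(v1, rel=1e-12)

    def test_nonfinite_eta_reports_row(self):
        y = np.array([1.0, 2.0])
        eta = np.array([0.0, np.inf])
        with pytest.raises(LinearPredictorOverflow) as err:
            GammaLog.nll(y, eta, 1.0)
        assert err.value.rows == [1]

    def test_permutation_invariance(self, field_survey):
        spec = DeltaModelSpec.from_formula("year + temp + depth + spatial + iid", n_knots=5)
        model = DeltaGammaModel(field_survey, spec, mesh_cutoff_km=40.0)
        b = model._bundle("occurrence")
        outer = model._initial_outer(b)
        v1, _ = laplace_marginal_nll(outer, b)
        perm = np.random.default_rng(0).permutation(field_survey.n)
        shuffled = field_survey.subset(pd.Series(True, index=field_survey.tows.index)).tows.iloc[perm]
        ds2 = SurveyDataset(
            tows=shuffled.reset_index(drop=True),
            strata=field_survey.strata,
            projection=field_survey.projection,
        )
        model2 = DeltaGammaModel(ds2, spec, mesh=model.mesh)
        b2 = model2._bundle("occurrence")
        v2, _ = laplace_marginal_nll(outer, b2)
        assert v2 == pytest.approx(v1, rel=1e-9)


class TestLaplace:
    @pytest.fixture(scope="class")
    def gaussian_bundle(self, field_survey):
        spec = DeltaModelSpec.from_formula("year + temp + depth + spatial + AR1", n_knots=5)
        model = DeltaGammaModel(field_survey, spec, mesh_cutoff_km=35.0)
        b = build_bundle(field_survey, spec, GaussianIdentity, model.mesh, model.spde)
        outer = np.concatenate(
            [
                np.zeros(b.p),
                [np.log(0.4), np.log(0.5), np.log(40.0), np.log(0.7), np.log(0.5), 0.5],
            ]
        )
        outer[0] = 2.0
        return b, outer

    def _dense_gaussian_marginal(self, b, beta, hypers):
        q, _ = b.prior_precision(hypers)
        z = b.z.toarray()
        sigma = z @ np.linalg.solve(q.toarray(), z.T) + np.eye(b.n)
        r = b.y - (b.x @ beta + b.offset)
        _, ld = np.linalg.slogdet(2.0 * np.pi * sigma)
        return 0.5 * (ld + r @ np.linalg.solve(sigma, r))

    def test_gaussian_laplace_equals_exact_marginal(self, gaussian_bundle):
        b, outer = gaussian_bundle
        val, _ = laplace_marginal_nll(outer, b)
        beta, hypers = b.split_outer(outer)
        oracle = self._dense_gaussian_marginal(b, beta, hypers)
        assert val == pytest.approx(oracle, rel=1e-9)  # >= 8 significant digits

    def test_profiled_gaussian_laplace_equals_gls_profile(self, gaussian_bundle):
        """Profiling beta in the inner Newton reproduces the GLS solution."""
        b, outer = gaussian_bundle
        _, hypers = b.split_outer(outer)
        hv = outer[b.p :]
        val, beta_hat, _ = profile_laplace_nll(hv, b)
        # oracle: GLS beta and the exact marginal evaluated there
        q, _ = b.prior_precision(hypers)
        z = b.z.toarray()
        sigma = z @ np.linalg.solve(q.toarray(), z.T) + np.eye(b.n)
        si = np.linalg.inv(sigma)
        beta_gls = np.linalg.solve(b.x.T @ si @ b.x, b.x.T @ si @ (b.y - b.offset))
        np.testing.assert_allclose(beta_hat, beta_gls, rtol=1e-7)
        assert val == pytest.approx(self._dense_gaussian_marginal(b, beta_gls, hypers), rel=1e-9)

    def test_zero_variance_fields_reduce_to_glm(self, field_survey):
        spec = DeltaModelSpec(covariates=(), year_effect=True, spatial=True, st_structure="none")
        model = DeltaGammaModel(field_survey, spec, mesh_cutoff_km=35.0)
        b = model._bundle("occurrence")
        beta = np.array([0.2, -0.1, 0.3, 0.1])
        outer = np.concatenate([beta, [np.log(40.0), np.log(1e-5)]])
        val, u = laplace_marginal_nll(outer, b)
        glm = BernoulliLogit.nll(b.y, b.x @ beta + b.offset)
        assert val == pytest.approx(glm, abs=1e-4)
        assert np.max(np.abs(u)) < 1e-4
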