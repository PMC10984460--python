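"""Screening, AIC weights, cross-validation and residual diagnostics."""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from survgam.model import DeltaModelSpec, FitOptions
from survgam.selection import (
    CvResult,
    UndefinedCorrelationError,
    _held_out_lpd,
    aic_and_weights,
    attach_elpd,
    kfold_elpd,
    moran_statistic,
    pearson_screen,
    quantile_residuals,
    vif,
)


class TestPearsonScreen:
    def test_perfectly_proportional_columns(self, rng):
        x = rng.normal(size=50)
        res = pearson_screen(pd.DataFrame({"a": x, "b": 2 * x}))
        assert res.pearson.loc["a", "b"] == pytest.approx(1.0)
        assert not res.passed

    def test_independent_columns_near_zero(self, rng):
        n = 10_000
        res = pearson_screen(pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)}))
        assert abs(res.pearson.loc["a", "b"]) < 0.05
        assert res.passed

    def test_matches_bruteforce_on_five_rows(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        b = np.array([2.0, 1.0, 3.0, 5.0, 4.0])
        res = pearson_screen(pd.DataFrame({"a": a, "b": b}))
        num = np.sum((a - a.mean()) * (b - b.mean()))
        den = np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        assert res.pearson.loc["a", "b"] == pytest.approx(num / den, rel=1e-12)

    def test_constant_column_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_screen(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]}))


class TestVif:
    def test_orthogonal_covariates_have_unit_vif(self):
        t = pd.DataFrame({"a": [1.0, -1.0, 1.0, -1.0], "b": [1.0, 1.0, -1.0, -1.0]})
        assert vif(t).max() == pytest.approx(1.0, abs=1e-12)

    def test_near_collinear_flagged(self, rng):
        x = rng.normal(size=200)
        t = pd.DataFrame({"a": x, "b": x + 1e-4 * rng.normal(size=200), "c": rng.normal(size=200)})
        v = vif(t)
        assert v["a"] > 3 and v["b"] > 3 and v["c"] < 3

    def test_equicorrelated_half_gives_three_halves(self):
        # exact sample correlation 0.5 between all pairs via a known design
        base = np.eye(3) * np.sqrt(0.5) + np.full((3, 3), (np.sqrt(2.0) - np.sqrt(0.5)) / 3)
        # columns of Z have unit norm and pairwise inner product 0.5
        g = base.T @ base
        np.testing.assert_allclose(np.diag(g), 1.0, atol=1e-12)
        rows = np.vstack([base, -base])  # mean-zero columns, same Gram structure
        t = pd.DataFrame(rows, columns=["a", "b", "c"])
        np.testing.assert_allclose(vif(t).to_numpy(), 1.5, rtol=1e-10)

    def test_perfect_collinearity_reported_as_inf(self):
        t = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        assert np.isinf(vif(t)).all()


@dataclass
class _StubFit:
    label: str
    marginal_nll: float
    df: int
    converged: bool = True

    @property
    def aic(self):
        return 2 * self.marginal_nll + 2 * self.df

    @property
    def spec(self):
        return self

    @property
    def labels(self):
        return self.label


class TestAicWeights:
    def test_equal_aic_gives_equal_weights(self):
        fits = [_StubFit("m1", 100.0, 5), _StubFit("m2", 100.0, 5)]
        comp = aic_and_weights(fits, ["m1", "m2"])
        np.testing.assert_allclose(comp.table["weight"], [0.5, 0.5])

    def test_delta_two_gives_weight_ratio_exp_minus_one(self):
        fits = [_StubFit("m1", 100.0, 5), _StubFit("m2", 100.0, 6)]  # dAIC = 2
        comp = aic_and_weights(fits, ["m1", "m2"])
        t = comp.table.set_index("label")
        assert t.loc["m2", "weight"] / t.loc["m1", "weight"] == pytest.approx(
            np.exp(-1.0), rel=1e-12
        )
        assert t.loc["m1", "delta_aic"] == 0.0
        assert t.loc["m2", "delta_aic"] == pytest.approx(-2.0)

    def test_weights_sum_to_one(self, rng):
        fits = [_StubFit(f"m{i}", 100 + 10 * rng.random(), 5 + i) for i in range(6)]
        comp = aic_and_weights(fits, [f.label for f in fits])
        assert comp.table["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_nonconverged_fit_excluded(self, caplog):
        fits = [_StubFit("good", 100.0, 5), _StubFit("bad", 50.0, 5, converged=False)]
        comp = aic_and_weights(fits, ["good", "bad"])
        assert list(comp.table["label"]) == ["good"]

    def test_attach_elpd_signs(self):
        fits = [_StubFit("m1", 100.0, 5), _StubFit("m2", 101.0, 5)]
        comp = attach_elpd(aic_and_weights(fits, ["m1", "m2"]), {"m1": -10.0, "m2": -12.5})
        t = comp.table.set_index("label")
        assert t.loc["m1", "delta_elpd"] == 0.0
        assert t.loc["m2", "delta_elpd"] == pytest.approx(-2.5)


class TestKfold:
    SPEC = DeltaModelSpec(covariates=("temp",), year_effect=True, n_knots=5)

    def test_folds_partition_evenly_and_deterministically(self, small_survey):
        r1 = kfold_elpd(small_survey, self.SPEC, k=4, seed=11)
        r2 = kfold_elpd(small_survey, self.SPEC, k=4, seed=11)
        np.testing.assert_array_equal(r1.fold_of_row, r2.fold_of_row)
        assert r1.elpd == r2.elpd
        sizes = np.bincount(r1.fold_of_row)
        assert sizes.sum() == small_survey.n
        assert sizes.max() - sizes.min() <= 1

    def test_held_out_lpd_matches_hand_formula(self, glm_fit, small_survey):
        held = small_survey.tows.iloc[:25]
        lpd = _held_out_lpd(glm_fit, held)
        assert lpd.shape == (25,)
        from scipy.special import expit
        from scipy.stats import gamma as gamma_dist

        offset = np.log(held["swept_km2"].to_numpy())
        pi = expit(glm_fit.occurrence.linear_predictor(held, offset))
        row = 0
        y0 = held["biomass_kg"].iloc[row]
        if y0 == 0:
            assert lpd[row] == pytest.approx(np.log(1 - pi[row]), rel=1e-9)
        pos_rows = np.nonzero(held["biomass_kg"].to_numpy() > 0)[0]
        r = pos_rows[0]
        mu = np.exp(
            glm_fit.positive.linear_predictor(held.iloc[[r]], offset[[r]])
        )[0]
        phi = glm_fit.positive.hypers["phi"]
        expected = np.log(pi[r]) + gamma_dist.logpdf(
            held["biomass_kg"].iloc[r], a=phi, scale=mu / phi
        )
        assert lpd[r] == pytest.approx(expected, rel=1e-9)

    def test_elpd_is_sum_of_folds(self, small_survey):
        r = kfold_elpd(small_survey, self.SPEC, k=3, seed=2)
        assert r.elpd == pytest.approx(sum(r.fold_elpd))
        assert r.n_scored == small_survey.n
        assert isinstance(r, CvResult)


class TestQuantileResiduals:
    def test_residual_count_and_calibration(self, glm_fit, small_survey):
        """Residuals of data simulated from (approximately) the fitted model
        itself should look standard normal."""
        passes = 0
        for seed in range(3):
            res = quantile_residuals(glm_fit, small_survey, seed=seed)
            assert len(res) == small_survey.n
            stat = kstest(res["residual"], "norm")
            passes += stat.pvalue > 0.01
        assert passes >= 2

    def test_moran_on_shuffled_residuals_is_null(self, glm_fit, small_survey, rng):
        res = quantile_residuals(glm_fit, small_survey, seed=0)
        coords = res[["x", "y"]].to_numpy()
        vals = res["residual"].to_numpy().copy()
        stats = []
        for _ in range(30):
            rng.shuffle(vals)
            stats.append(moran_statistic(vals, coords)["I"])
        null_mean = -1.0 / (len(vals) - 1)
        assert np.mean(stats) == pytest.approx(null_mean, abs=0.02)
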