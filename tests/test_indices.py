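"""Surfaces, biomass indices, centres of gravity and the design-based
comparator, against hand computations."""

import numpy as np
import pandas as pd
import pytest

from survgam.data import SurveyDataset
from survgam.geo import LocalProjection
from survgam.indices import (
    SNOW_CRAB_CATCHABILITY,
    DensitySurface,
    PredictionGrid,
    UndefinedStatisticError,
    agreement_r2,
    biomass_index,
    centre_of_gravity,
    cog_from_data,
    fishing_regression,
    predict_surface,
    strata_index,
)
from survgam.simulate import truth_prediction_grid


def _uniform_surface(density=1.0, n=100, area=25.0, ref=25.0, years=(2000,)):
    rows = []
    side = int(np.sqrt(n))
    for year in years:
        for i in range(n):
            x = (i % side) * 5.0
            y = (i // side) * 5.0
            rows.append(
                {
                    "year": year, "cell": i, "x": x, "y": y, "area_km2": area,
                    "pi": 1.0, "mu": density, "density": density,
                    "biomass_kg": density * area / ref, "extrapolated": False,
                }
            )
    return DensitySurface(table=pd.DataFrame(rows), ref_swept_km2=ref)


class TestPredictSurface:
    @pytest.fixture(scope="class")
    def surface(self, field_fit, field_truth):
        grid = PredictionGrid(truth_prediction_grid(field_truth))
        return predict_surface(field_fit, grid, ref_swept_km2=0.025)

    def test_density_is_elementwise_product(self, surface):
        t = surface.table.sample(10, random_state=0)
        np.testing.assert_allclose(t["density"], t["pi"] * t["mu"], rtol=1e-12)
        np.testing.assert_allclose(
            t["biomass_kg"], t["density"] * t["area_km2"] / surface.ref_swept_km2, rtol=1e-12
        )

    def test_probability_and_density_bounds(self, surface):
        assert surface.table["pi"].between(0, 1).all()
        assert (surface.table["mu"] > 0).all()
        assert (surface.table["density"] >= 0).all()

    def test_all_grid_years_predicted(self, surface, field_truth):
        assert list(surface.years) == list(field_truth.years)


class TestBiomassIndex:
    def test_uniform_surface_arithmetic(self):
        surf = _uniform_surface(density=1.0, n=100, area=25.0, ref=25.0)
        idx = biomass_index(surf, catchability=1.0, n_draws=0)
        # 100 cells x 1 kg per reference unit x (25/25) = 100 kg = 0.1 t
        assert idx.table["index_t"].iloc[0] == pytest.approx(0.1, rel=1e-12)

    def test_snow_crab_catchability_is_exact_multiplication(self):
        surf = _uniform_surface(density=3.7, n=64, years=(2000, 2001, 2002))
        raw = biomass_index(surf, catchability=1.0, n_draws=0)
        adj = biomass_index(surf, catchability=SNOW_CRAB_CATCHABILITY, n_draws=0)
        np.testing.assert_array_equal(
            adj.table["index_t"].to_numpy(), 0.126 * raw.table["index_t"].to_numpy()
        )

    def test_invalid_catchability_rejected(self):
        with pytest.raises(ValueError):
            biomass_index(_uniform_surface(), catchability=0.0, n_draws=0)

    def test_draw_ci_brackets_point_and_is_seeded(self, field_fit, field_truth):
        grid = PredictionGrid(truth_prediction_grid(field_truth))
        surf = predict_surface(field_fit, grid, ref_swept_km2=0.025)
        idx1 = biomass_index(surf, n_draws=150, seed=5)
        idx2 = biomass_index(surf, n_draws=150, seed=5)
        pd.testing.assert_frame_equal(idx1.table, idx2.table)
        t = idx1.table
        assert (t["lo_t"] <= t["hi_t"]).all()
        # the point estimate (plug-in mode) should sit inside the draw CI
        inside = ((t["index_t"] >= t["lo_t"]) & (t["index_t"] <= t["hi_t"])).mean()
        assert inside >= 0.75


class TestSampleCoefsGaussianity:
    def test_draw_quantiles_match_wald_for_linear_functional(self, glm_fit, rng):
        """Percentile interval of a linear functional over 2000 joint draws
        matches the closed-form Wald interval from the same precision."""
        sub = glm_fit.occurrence
        draws = sub.sample_coefs(2000, rng)
        c = np.zeros(sub.bundle.p + sub.bundle.n_latent)
        c[: sub.bundle.p] = 1.0
        vals = np.array([c[: sub.bundle.p] @ b + c[sub.bundle.p :] @ u for b, u in draws])
        ji = np.linalg.inv(sub.joint_precision.toarray())
        sd = np.sqrt(c @ ji @ c)
        mean = c[: sub.bundle.p] @ sub.beta + c[sub.bundle.p :] @ sub.latent
        lo, hi = np.percentile(vals, [2.5, 97.5])
        assert hi - lo == pytest.approx(2 * 1.959964 * sd, rel=0.05)
        assert (lo + hi) / 2 == pytest.approx(mean, abs=0.2 * sd)


class TestCentreOfGravity:
    def test_uniform_weights_give_centroid(self):
        surf = _uniform_surface(n=100)
        cog = centre_of_gravity(surf)
        t = surf.table
        assert cog.table["cg_x"].iloc[0] == pytest.approx(t["x"].mean())
        assert cog.table["cg_y"].iloc[0] == pytest.approx(t["y"].mean())

    def test_point_mass_sits_at_its_cell(self):
        surf = _uniform_surface(n=25)
        surf.table["biomass_kg"] = 0.0
        surf.table.loc[7, "biomass_kg"] = 5.0
        cog = centre_of_gravity(surf)
        assert cog.table["cg_x"].iloc[0] == surf.table.loc[7, "x"]
        assert cog.table["cg_y"].iloc[0] == surf.table.loc[7, "y"]

    def test_hand_computed_weighted_mean(self):
        table = pd.DataFrame(
            {
                "year": 2000, "cell": [0, 1, 2], "x": [0.0, 10.0, 20.0],
                "y": [0.0, 0.0, 0.0], "area_km2": 25.0, "pi": 1.0, "mu": 1.0,
                "density": 1.0, "biomass_kg": [1.0, 1.0, 2.0], "extrapolated": False,
            }
        )
        cog = centre_of_gravity(DensitySurface(table=table, ref_swept_km2=25.0))
        assert cog.table["cg_x"].iloc[0] == pytest.approx(12.5)

    def test_translation_equivariance(self):
        surf = _uniform_surface(n=49)
        surf.table["biomass_kg"] = np.arange(49.0) + 1.0
        c1 = centre_of_gravity(surf)
        shifted = DensitySurface(table=surf.table.assign(
            x=surf.table["x"] + 13.0, y=surf.table["y"] - 4.0
        ), ref_swept_km2=surf.ref_swept_km2)
        c2 = centre_of_gravity(shifted)
        assert c2.table["cg_x"].iloc[0] - c1.table["cg_x"].iloc[0] == pytest.approx(13.0)
        assert c2.table["cg_y"].iloc[0] - c1.table["cg_y"].iloc[0] == pytest.approx(-4.0)

    def test_all_zero_year_flagged(self):
        surf = _uniform_surface(n=9)
        surf.table["biomass_kg"] = 0.0
        cog = centre_of_gravity(surf)
        assert not cog.table["defined"].iloc[0]


class TestCogFromData:
    def test_single_positive_tow_defines_cog(self, small_survey):
        t = small_survey.tows.copy()
        year0 = t["year"].min()
        pos = t[(t["year"] == year0) & (t["biomass_kg"] > 0)].index
        t.loc[pos[1:], "biomass_kg"] = 0.0
        t.loc[pos[1:], "z"] = 0
        ds = SurveyDataset(tows=t, strata=small_survey.strata, projection=small_survey.projection)
        cog = cog_from_data(ds).table.set_index("year")
        assert cog.loc[year0, "cg_x"] == pytest.approx(t.loc[pos[0], "x"])

    def test_permutation_invariance(self, field_survey):
        c1 = cog_from_data(field_survey)
        shuffled = field_survey.tows.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ds = SurveyDataset(
            tows=shuffled, strata=field_survey.strata, projection=field_survey.projection
        )
        c2 = cog_from_data(ds)
        pd.testing.assert_frame_equal(
            c1.table.sort_values("year").reset_index(drop=True),
            c2.table.sort_values("year").reset_index(drop=True),
        )


def _toy_survey(rows, strata):
    proj = LocalProjection(0.0, 0.0)
    df = pd.DataFrame(rows)
    df["lon"], df["lat"] = proj.to_lonlat(df["x"], df["y"])
    df["tow_id"] = np.arange(len(df))
    df["depth_m"] = 100.0
    df["temp_c"] = 3.0
    df["z"] = (df["biomass_kg"] > 0).astype(int)
    return SurveyDataset(tows=df, strata=pd.DataFrame(strata), projection=proj)


class TestStrataIndex:
    def test_single_stratum_uniform_density(self):
        ds = _toy_survey(
            [
                {"x": 1.0, "y": 1.0, "year": 2000, "swept_km2": 0.02, "biomass_kg": 0.02, "stratum": 0},
                {"x": 2.0, "y": 2.0, "year": 2000, "swept_km2": 0.04, "biomass_kg": 0.04, "stratum": 0},
            ],
            {"stratum": [0], "depth_min_m": [0.0], "depth_max_m": [500.0], "area_km2": [3000.0]},
        )
        # both tows catch 1 kg per km^2 swept -> index = stratum area in kg
        idx = strata_index(ds)
        assert idx.table["index_t"].iloc[0] == pytest.approx(3.0)  # 3000 kg

    def test_two_strata_matches_hand_computation(self):
        ds = _toy_survey(
            [
                {"x": 1.0, "y": 1.0, "year": 2000, "swept_km2": 0.02, "biomass_kg": 0.06, "stratum": 0},
                {"x": 2.0, "y": 2.0, "year": 2000, "swept_km2": 0.02, "biomass_kg": 0.02, "stratum": 0},
                {"x": 3.0, "y": 3.0, "year": 2000, "swept_km2": 0.05, "biomass_kg": 0.25, "stratum": 1},
            ],
            {
                "stratum": [0, 1], "depth_min_m": [0.0, 100.0],
                "depth_max_m": [100.0, 500.0], "area_km2": [1000.0, 2000.0],
            },
        )
        # stratum 0: mean(3, 1) = 2 kg/km^2 * 1000; stratum 1: 5 * 2000
        expected_kg = 2.0 * 1000.0 + 5.0 * 2000.0
        assert strata_index(ds).table["index_t"].iloc[0] == pytest.approx(expected_kg / 1000.0)

    def test_doubling_areas_doubles_index(self, field_survey):
        i1 = strata_index(field_survey)
        ds2 = SurveyDataset(
            tows=field_survey.tows,
            strata=field_survey.strata.assign(area_km2=2 * field_survey.strata["area_km2"]),
            projection=field_survey.projection,
        )
        i2 = strata_index(ds2)
        np.testing.assert_allclose(
            i2.table["index_t"], 2.0 * i1.table["index_t"], rtol=1e-12
        )

    def test_empty_stratum_omitted_with_warning(self, caplog):
        ds = _toy_survey(
            [{"x": 1.0, "y": 1.0, "year": 2000, "swept_km2": 0.02, "biomass_kg": 0.02, "stratum": 0}],
            {
                "stratum": [0, 1], "depth_min_m": [0.0, 100.0],
                "depth_max_m": [100.0, 500.0], "area_km2": [1000.0, 2000.0],
            },
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="survgam.indices"):
            idx = strata_index(ds)
        assert "no tows" in caplog.text
        assert idx.table["index_t"].iloc[0] == pytest.approx(1.0)  # stratum 1 missing


class TestAgreement:
    def test_identical_series(self):
        s = pd.Series([1.0, 2.0, 3.0, 4.0], index=[2000, 2001, 2002, 2003])
        assert agreement_r2(s, s) == pytest.approx(1.0)

    def test_affine_invariance(self):
        s = pd.Series([1.0, 2.0, 5.0, 3.0], index=range(4))
        assert agreement_r2(s, 2 * s + 3) == pytest.approx(1.0)

    def test_four_year_toy_matches_formula(self):
        a = pd.Series([1.0, 3.0, 2.0, 5.0], index=range(4))
        b = pd.Series([2.0, 4.0, 1.0, 6.0], index=range(4))
        r = np.corrcoef(a, b)[0, 1]
        assert agreement_r2(a, b) == pytest.approx(r**2, rel=1e-12)

    def test_constant_series_flagged(self):
        a = pd.Series([1.0, 1.0, 1.0], index=range(3))
        b = pd.Series([1.0, 2.0, 3.0], index=range(3))
        with pytest.raises(UndefinedStatisticError):
            agreement_r2(a, b)

    def test_too_few_years_rejected(self):
        a = pd.Series([1.0, 2.0], index=range(2))
        with pytest.raises(ValueError):
            agreement_r2(a, a)


class TestFishingRegression:
    def _frame(self, division, years, values):
        return pd.DataFrame({"year": years, "division": division, "value": values})

    def test_exact_line_recovers_slope(self):
        years = np.arange(2000, 2010)
        catch = np.linspace(1, 5, 10)
        bio = -2.0 * catch + 10.0
        res = fishing_regression(
            self._frame("3L", years, bio), self._frame("3L", years, catch)
        )
        assert res["slope"].iloc[0] == pytest.approx(-2.0, rel=1e-10)
        assert res["p_value"].iloc[0] < 1e-12

    def test_five_point_toy_matches_normal_equations(self):
        years = np.arange(5)
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 2.5, 2.0, 4.0, 3.5])
        slope_hand = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        res = fishing_regression(self._frame("3N", years, y), self._frame("3N", years, x))
        assert res["slope"].iloc[0] == pytest.approx(slope_hand, rel=1e-12)

    def test_independent_series_rarely_significant(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            years = np.arange(100)
            res = fishing_regression(
                self._frame("3O", years, rng.normal(size=100)),
                self._frame("3O", years, rng.normal(size=100)),
            )
            hits += res["p_value"].iloc[0] > 0.05
        assert hits >= 4

    def test_degenerate_predictor_flagged(self):
        years = np.arange(2000, 2006)
        res = fishing_regression(
            self._frame("3L", years, np.arange(6.0)),
            self._frame("3L", years, np.full(6, 2.0)),
        )
        assert res["degenerate"].iloc[0]
        assert np.isnan(res["slope"].iloc[0])

    def test_divisions_fit_independently(self):
        years = np.arange(2000, 2010)
        catch = pd.concat([
            self._frame("3L", years, np.linspace(1, 5, 10)),
            self._frame("3N", years, np.linspace(2, 4, 10)),
        ])
        bio = pd.concat([
            self._frame("3L", years, -1.0 * np.linspace(1, 5, 10) + 7),
            self._frame("3N", years, 3.0 * np.linspace(2, 4, 10) + 1),
        ])
        res = fishing_regression(bio, catch).set_index("division")
        assert res.loc["3L", "slope"] == pytest.approx(-1.0, rel=1e-9)
        assert res.loc["3N", "slope"] == pytest.approx(3.0, rel=1e-9)
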