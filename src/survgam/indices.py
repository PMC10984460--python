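"""Derived products: gridded density surfaces, biomass indices with
uncertainty, centres of gravity, the design-based comparator, and the
divisional fishing regression."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import linregress

from .data import SurveyDataset
from .geo import LocalProjection
from .model import DeltaGammaResults

logger = logging.getLogger(__name__)

#: catchability preset for the snow-crab trawl-survey conversion factor
SNOW_CRAB_CATCHABILITY = 0.126


class UndefinedStatisticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# prediction grid


@dataclass
class PredictionGrid:
    """Regular prediction grid: cell centres, areas, depth, per-year
    bottom temperature (columns ``temp_<year>``)."""

    cells: pd.DataFrame
    projection: LocalProjection | None = None

    def __post_init__(self):
        for c in ("x", "y", "area_km2", "depth_m"):
            if c not in self.cells.columns:
                raise ValueError(f"grid table missing column {c!r}")
        if (self.cells["area_km2"] <= 0).any():
            raise ValueError("cell areas must be > 0")
        temp_cols = self.temp_columns
        if not temp_cols:
            raise ValueError("grid table has no temp_<year> columns")
        finite = np.isfinite(
            self.cells[["x", "y", "area_km2", "depth_m"] + list(temp_cols.values())]
        ).all(axis=1)
        n_bad = int((~finite).sum())
        if n_bad:
            logger.warning("excluding %d grid cells with missing covariates", n_bad)
            self.cells = self.cells[finite].reset_index(drop=True)

    @property
    def temp_columns(self) -> dict[int, str]:
        out = {}
        for c in self.cells.columns:
            if c.startswith("temp_"):
                try:
                    out[int(c.split("_", 1)[1])] = c
                except ValueError:
                    continue
        return dict(sorted(out.items()))

    @property
    def years(self) -> list[int]:
        return list(self.temp_columns)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class DensitySurface:
    """Per-year, per-cell predictions of the delta model.

    ``table`` columns: year, cell, x, y, area_km2, pi, mu, density
    (pi * mu, kg per reference swept-area unit), biomass_kg
    (density * area / reference area), extrapolated flag.
    """

    table: pd.DataFrame
    ref_swept_km2: float
    n_excluded: int = 0
    projection: LocalProjection | None = None
    _fit: DeltaGammaResults | None = field(default=None, repr=False)
    _grid: PredictionGrid | None = field(default=None, repr=False)

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.table["year"].unique())

    def year_table(self, year: int) -> pd.DataFrame:
        return self.table[self.table["year"] == year]


def _grid_frame_for_year(grid: PredictionGrid, year: int) -> pd.DataFrame:
    df = grid.cells[["x", "y", "depth_m"]].copy()
    df["temp_c"] = grid.cells[grid.temp_columns[year]].to_numpy()
    df["year"] = year
    return df


def predict_surface(
    fitted: DeltaGammaResults, grid: PredictionGrid, ref_swept_km2: float = 0.025
) -> DensitySurface:
    """Predict pi, mu and combined density over the grid for every year.

    The prediction offset is log(reference swept area), so densities are in
    kg per reference-swept-area unit.  Cells outside the mesh hull are
    excluded (counted); cells whose covariates lie beyond the observed
    covariate range are retained but flagged as extrapolated (their smooth
    terms are clamped at the boundary).
    """
    cells = grid.cells
    n_excluded = 0
    inside = np.ones(len(cells), dtype=bool)
    if fitted.mesh is not None:
        inside = fitted.mesh.delaunay.find_simplex(cells[["x", "y"]].to_numpy()) >= 0
        n_excluded = int((~inside).sum())
        if n_excluded:
            logger.warning("excluding %d grid cells outside the mesh hull", n_excluded)
    years = [y for y in grid.years if y in set(fitted.occurrence.bundle.years)]
    rows = []
    occ_b = fitted.occurrence.bundle
    for year in years:
        df = _grid_frame_for_year(grid, year)[inside].reset_index(drop=True)
        offset = np.full(len(df), np.log(ref_swept_km2))
        pi = expit(fitted.occurrence.linear_predictor(df, offset))
        mu = np.exp(fitted.positive.linear_predictor(df, offset))
        extrap = np.zeros(len(df), dtype=bool)
        for cov in occ_b.spec.covariates:
            basis = occ_b.bases[cov]
            vals = df["temp_c"].to_numpy() if cov == "temp" else np.log(df["depth_m"].to_numpy())
            extrap |= (vals < basis.knots[3]) | (vals > basis.knots[-4])
        area = cells["area_km2"].to_numpy()[inside]
        rows.append(
            pd.DataFrame(
                {
                    "year": year,
                    "cell": np.nonzero(inside)[0],
                    "x": df["x"].to_numpy(),
                    "y": df["y"].to_numpy(),
                    "area_km2": area,
                    "pi": pi,
                    "mu": mu,
                    "density": pi * mu,
                    "biomass_kg": pi * mu * area / ref_swept_km2,
                    "extrapolated": extrap,
                }
            )
        )
    return DensitySurface(
        table=pd.concat(rows, ignore_index=True),
        ref_swept_km2=ref_swept_km2,
        n_excluded=n_excluded,
        projection=grid.projection,
        _fit=fitted,
        _grid=grid,
    )


# ---------------------------------------------------------------------------
# biomass index


@dataclass
class IndexSeries:
    """Yearly biomass index (tonnes) with optional 95% bounds."""

    table: pd.DataFrame  # year, index_t, lo_t, hi_t
    catchability: float = 1.0

    def series(self) -> pd.Series:
        return self.table.set_index("year")["index_t"]

    def plot(self, ax=None, label: str | None = None, color=None):
        """Index series with its shaded 95% band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        (line,) = ax.plot(t["year"], t["index_t"], marker="o", label=label, color=color)
        if np.isfinite(t["lo_t"]).any():
            ax.fill_between(
                t["year"], t["lo_t"], t["hi_t"], alpha=0.25, color=line.get_color()
            )
        ax.set_xlabel("year")
        ax.set_ylabel("biomass index (t)")
        if label:
            ax.legend()
        return ax


def biomass_index(
    surface: DensitySurface,
    catchability: float = 1.0,
    n_draws: int = 500,
    seed: int = 0,
) -> IndexSeries:
    """Yearly index = catchability x sum of cell biomasses, in tonnes.

    Confidence bounds come from ``n_draws`` samples of the joint Gaussian
    approximation of (fixed effects, latent effects) in each sub-model,
    propagated through the prediction; percentile 2.5/97.5.  Draw-based
    bounds require the surface to have been produced by
    :func:`predict_surface` (set ``n_draws=0`` to skip them).
    """
    if catchability <= 0:
        raise ValueError("catchability must be > 0")
    # catchability is applied as the literal final multiplication, so the
    # adjusted index is bit-identical to catchability x the unadjusted one
    point = surface.table.groupby("year")["biomass_kg"].sum().div(1000.0).mul(catchability)
    lo = pd.Series(np.nan, index=point.index)
    hi = pd.Series(np.nan, index=point.index)
    if n_draws and surface._fit is not None and surface._grid is not None:
        if n_draws < 100:
            raise ValueError("need n_draws >= 100 for confidence bounds")
        draws = _index_draws(surface, n_draws, seed)
        draws = draws * catchability / 1000.0
        lo = pd.Series(np.percentile(draws, 2.5, axis=0), index=point.index)
        hi = pd.Series(np.percentile(draws, 97.5, axis=0), index=point.index)
    table = pd.DataFrame(
        {"year": point.index, "index_t": point.to_numpy(), "lo_t": lo.to_numpy(), "hi_t": hi.to_numpy()}
    )
    return IndexSeries(table=table, catchability=catchability)


def _index_draws(surface: DensitySurface, n_draws: int, seed: int) -> np.ndarray:
    """(n_draws, n_years) unadjusted index draws in kg."""
    fit = surface._fit
    grid = surface._grid
    rng = np.random.default_rng(seed)
    occ_draws = fit.occurrence.sample_coefs(n_draws, rng)
    pos_draws = fit.positive.sample_coefs(n_draws, rng)
    years = list(surface.years)
    # precompute designs per year once
    designs = {}
    inside = np.ones(grid.n_cells, dtype=bool)
    if fit.mesh is not None:
        inside = fit.mesh.delaunay.find_simplex(grid.cells[["x", "y"]].to_numpy()) >= 0
    offset_val = np.log(surface.ref_swept_km2)
    for year in years:
        df = _grid_frame_for_year(grid, year)[inside].reset_index(drop=True)
        designs[year] = (
            fit.occurrence.design_for(df),
            fit.positive.design_for(df),
            grid.cells["area_km2"].to_numpy()[inside],
        )
    out = np.empty((n_draws, len(years)))
    n_rejected = 0
    d = 0
    attempts = 0
    while d < n_draws:
        if attempts >= len(occ_draws):
            extra = max(10, n_draws // 10)
            occ_draws += fit.occurrence.sample_coefs(extra, rng)
            pos_draws += fit.positive.sample_coefs(extra, rng)
        bo, uo = occ_draws[attempts]
        bp, up = pos_draws[attempts]
        attempts += 1
        vals = []
        ok = True
        for year in years:
            (xo, zo), (xp, zp), area = designs[year]
            eta_o = xo @ bo + offset_val + (zo @ uo if uo.size else 0.0)
            eta_p = xp @ bp + offset_val + (zp @ up if up.size else 0.0)
            dens = expit(eta_o) * np.exp(eta_p)
            if not np.all(np.isfinite(dens)):
                ok = False
                break
            vals.append(np.sum(dens * area / surface.ref_swept_km2))
        if ok:
            out[d] = vals
            d += 1
        else:
            n_rejected += 1
            if n_rejected > 0.1 * n_draws:
                raise RuntimeError(
                    f"more than 10% of posterior draws produced non-finite densities "
                    f"({n_rejected} rejections)"
                )
    return out


# ---------------------------------------------------------------------------
# centre of gravity


@dataclass
class CogSeries:
    """Yearly biomass-weighted mean location and per-axis weighted variance."""

    table: pd.DataFrame  # year, cg_x, cg_y, var_x, var_y, lon, lat, defined

    def plot(self, ax=None):
        """Centre-of-gravity trajectory, coloured by year, with error bars
        of one weighted SD per axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table[self.table["defined"]].sort_values("year")
        sc = ax.scatter(t["cg_x"], t["cg_y"], c=t["year"], cmap="viridis", zorder=3)
        ax.errorbar(
            t["cg_x"], t["cg_y"],
            xerr=np.sqrt(t["var_x"]), yerr=np.sqrt(t["var_y"]),
            fmt="none", ecolor="grey", alpha=0.5, zorder=2,
        )
        ax.plot(t["cg_x"], t["cg_y"], color="grey", alpha=0.5, zorder=1)
        plt.colorbar(sc, ax=ax, label="year")
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        return ax


def _weighted_cog(x, y, w, projection=None):
    w = np.asarray(w, dtype=float)
    total = w.sum()
    if total <= 0:
        return None
    cx = float(np.sum(x * w) / total)
    cy = float(np.sum(y * w) / total)
    vx = float(np.sum(w * (x - cx) ** 2) / total)
    vy = float(np.sum(w * (y - cy) ** 2) / total)
    lon = lat = np.nan
    if projection is not None:
        lon, lat = projection.to_lonlat(cx, cy)
        lon, lat = float(lon), float(lat)
    return cx, cy, vx, vy, lon, lat


def centre_of_gravity(surface: DensitySurface) -> CogSeries:
    """Per-year centre of gravity of the predicted biomass surface:
    CG = sum(x_i w_i) / sum(w_i) per axis, with w_i the cell biomass."""
    rows = []
    for year in surface.years:
        t = surface.year_table(year)
        res = _weighted_cog(
            t["x"].to_numpy(), t["y"].to_numpy(), t["biomass_kg"].to_numpy(), surface.projection
        )
        if res is None:
            logger.warning("all-zero surface in year %s: COG undefined", year)
            rows.append({"year": year, "defined": False})
            continue
        cx, cy, vx, vy, lon, lat = res
        rows.append(
            {
                "year": year,
                "cg_x": cx,
                "cg_y": cy,
                "var_x": vx,
                "var_y": vy,
                "lon": lon,
                "lat": lat,
                "defined": True,
            }
        )
    return CogSeries(table=pd.DataFrame(rows))


def cog_from_data(dataset: SurveyDataset) -> CogSeries:
    """Design-based centre of gravity: tow biomasses as weights."""
    rows = []
    for year in dataset.years:
        t = dataset.tows[dataset.tows["year"] == year]
        res = _weighted_cog(
            t["x"].to_numpy(), t["y"].to_numpy(), t["biomass_kg"].to_numpy(), dataset.projection
        )
        if res is None:
            logger.warning("no positive tows in year %s: COG undefined", year)
            rows.append({"year": year, "defined": False})
            continue
        cx, cy, vx, vy, lon, lat = res
        rows.append(
            {
                "year": year,
                "cg_x": cx,
                "cg_y": cy,
                "var_x": vx,
                "var_y": vy,
                "lon": lon,
                "lat": lat,
                "defined": True,
            }
        )
    return CogSeries(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# design-based comparator


def strata_index(dataset: SurveyDataset) -> IndexSeries:
    """Stratified design-based index: per stratum, mean catch per swept
    area (kg/km^2) times stratum area, summed over strata; tonnes.

    Strata with zero tows in a year are omitted with a warning, so the
    design-based index is biased low in low-coverage years — exactly the
    situation the model-based index is meant to handle.
    """
    if dataset.strata.empty:
        raise ValueError("dataset has no strata table")
    areas = dataset.strata.set_index("stratum")["area_km2"]
    rows = []
    for year in dataset.years:
        t = dataset.tows[dataset.tows["year"] == year]
        total = 0.0
        missing = []
        for s, area in areas.items():
            ts = t[t["stratum"] == s]
            if len(ts) == 0:
                missing.append(s)
                continue
            dens = (ts["biomass_kg"] / ts["swept_km2"]).mean()  # kg per km^2
            total += dens * area
        if missing:
            logger.warning("year %s: strata %s have no tows; omitted", year, missing)
        rows.append({"year": int(year), "index_t": total / 1000.0, "lo_t": np.nan, "hi_t": np.nan})
    return IndexSeries(table=pd.DataFrame(rows), catchability=1.0)


# ---------------------------------------------------------------------------
# agreement and fishing regression


def agreement_r2(series_a: pd.Series, series_b: pd.Series) -> float:
    """R^2 (squared Pearson correlation) between two yearly series over
    their shared years."""
    joined = pd.concat([series_a, series_b], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"need >= 3 overlapping years, got {len(joined)}")
    a = joined.iloc[:, 0].to_numpy(dtype=float)
    b = joined.iloc[:, 1].to_numpy(dtype=float)
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedStatisticError("R^2 undefined for a constant series")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def fishing_regression(
    index_by_division: pd.DataFrame, catch_by_division: pd.DataFrame
) -> pd.DataFrame:
    """Per-division OLS of yearly biomass on yearly catch.

    Both inputs have columns (year, division, value); divisions are fit
    independently.  Returns slope, standard error, t-test p-value and n.
    """
    rows = []
    for div in sorted(index_by_division["division"].unique()):
        bio = index_by_division[index_by_division["division"] == div].set_index("year")["value"]
        cat = catch_by_division[catch_by_division["division"] == div].set_index("year")["value"]
        joined = pd.concat([bio, cat], axis=1, keys=["bio", "catch"], join="inner").dropna()
        if len(joined) < 4:
            raise ValueError(f"division {div!r}: need >= 4 paired years, got {len(joined)}")
        if np.std(joined["catch"].to_numpy()) == 0:
            logger.warning("division %r: degenerate (constant) catch predictor", div)
            rows.append(
                {"division": div, "slope": np.nan, "se": np.nan, "p_value": np.nan,
                 "n": len(joined), "degenerate": True}
            )
            continue
        res = linregress(joined["catch"], joined["bio"])
        rows.append(
            {
                "division": div,
                "slope": float(res.slope),
                "se": float(res.stderr),
                "p_value": float(res.pvalue),
                "n": len(joined),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
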