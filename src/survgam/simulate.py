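"""Synthetic Grand-Banks-like domains and stratified-random trawl surveys.

Ground truth is fully known, so every downstream stage (mesh, fitting,
selection, indices) can be tested without the real survey: bathymetry is a
smooth gradient plus bumps, bottom temperature has a spatial gradient with
yearly anomalies and an optional warming trend, covariate responses are
quadratic domes on the link scale (so the preferred temperature/depth are
known analytically), and residual structure comes from the same SPDE/Matern
GMRFs the model fits, with iid/RW/AR1 dynamics across years.

The default scale emulates the spring multispecies trawl survey the package
targets — stratified-random tows in depth strata, zero-inflated biomass,
occasional low-coverage years — at a size where full fits run in minutes:
300x300 km domain, 5-km truth grid, 10 years, 150 tows per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data import SurveyDataset
from .geo import LocalProjection
from .gmrf import sample_gmrf, spde_precision
from .mesh import Mesh, fem_matrices, projection_matrix, thin_and_mesh


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DomainConfig:
    """Ground-truth generator settings (defaults = the package's reference
    synthetic study conditions)."""

    extent_km: float = 300.0
    grid_res_km: float = 5.0
    n_years: int = 10
    # latent field parameters (shared by both sub-processes)
    range_km: float = 70.0
    sigma_spatial: float = 0.8
    sigma_st: float = 0.5
    structure: str = "AR1"  # iid | RW | AR1
    rho: float = 0.7
    # observation / habitat parameters
    phi: float = 1.5
    beta_z: float = 2.0
    beta_y: float = 3.0
    year_sd: float = 0.3
    temp_opt_c: float = 3.0
    temp_curv: float = 0.15
    depth_opt_m: float = 80.0
    depth_curv: float = 0.8
    catchability: float = 1.0
    temp_trend_c_per_year: float = 0.0
    temp_anomaly_sd: float = 0.5
    truth_mesh_cutoff_km: float = 12.0
    ref_swept_km2: float = 0.025
    swept_cv: float = 0.08
    n_strata: int = 4
    lon0: float = -51.0
    lat0: float = 45.0

    def __post_init__(self):
        if self.extent_km <= 0 or self.grid_res_km <= 0:
            raise InvalidConfigError("extent and grid resolution must be > 0")
        if self.n_years < 1:
            raise InvalidConfigError("n_years must be >= 1")
        if self.structure not in ("iid", "RW", "AR1"):
            raise InvalidConfigError(f"unknown structure {self.structure!r}")
        if self.structure == "AR1" and not abs(self.rho) < 1:
            raise InvalidConfigError("AR1 requires |rho| < 1")
        if self.sigma_spatial < 0 or self.sigma_st < 0:
            raise InvalidConfigError("field sigmas must be >= 0")
        if self.phi <= 0 or self.range_km <= 0:
            raise InvalidConfigError("phi and range must be > 0")


@dataclass
class DomainTruth:
    """Realized ground truth on the truth grid.

    ``grid`` has one row per cell: x, y (km), lon, lat, depth_m and one
    temperature column per year (``temp_y{t}``).  Latent field values are
    stored per year per cell for both sub-processes, so every simulated
    expectation can be recomputed deterministically.
    """

    config: DomainConfig
    seed: int
    grid: pd.DataFrame
    years: np.ndarray
    year_eff_z: np.ndarray
    year_eff_y: np.ndarray
    v_z: np.ndarray  # (n_years, n_cells), fields projected to the grid
    v_y: np.ndarray
    v_z_vertices: np.ndarray  # (n_years, n_vertices), fields at mesh vertices
    v_y_vertices: np.ndarray
    truth_mesh: Mesh
    projection: LocalProjection

    def field_at(self, part: str, year_index: int, points: np.ndarray) -> np.ndarray:
        """Realized latent field at arbitrary locations (barycentric)."""
        a = projection_matrix(self.truth_mesh, np.atleast_2d(points))
        vert = self.v_z_vertices if part == "occurrence" else self.v_y_vertices
        return a @ vert[year_index]

    @property
    def n_cells(self) -> int:
        return len(self.grid)

    @property
    def cell_area_km2(self) -> float:
        return self.config.grid_res_km**2

    def f_temp(self, temp: np.ndarray) -> np.ndarray:
        c = self.config
        return -c.temp_curv * (np.asarray(temp) - c.temp_opt_c) ** 2

    def f_depth(self, depth_m: np.ndarray) -> np.ndarray:
        c = self.config
        return -c.depth_curv * (np.log(depth_m) - np.log(c.depth_opt_m)) ** 2

    def eta(self, part: str, year_index: int) -> np.ndarray:
        """True link-scale predictor over the grid for one year (at the
        reference swept area; no offset)."""
        c = self.config
        temp = self.grid[f"temp_y{year_index}"].to_numpy()
        depth = self.grid["depth_m"].to_numpy()
        smooth = self.f_temp(temp) + self.f_depth(depth)
        if part == "occurrence":
            return c.beta_z + self.year_eff_z[year_index] + smooth + self.v_z[year_index]
        if part == "positive":
            return c.beta_y + self.year_eff_y[year_index] + smooth + self.v_y[year_index]
        raise ValueError(part)

    def pi(self, year_index: int) -> np.ndarray:
        from scipy.special import expit

        return expit(self.eta("occurrence", year_index))

    def mu(self, year_index: int) -> np.ndarray:
        """Expected positive biomass (kg) per reference-swept-area tow."""
        return np.exp(self.eta("positive", year_index))

    def true_density(self, year_index: int) -> np.ndarray:
        """Unconditional expected catch pi*mu (kg per reference tow)."""
        return self.pi(year_index) * self.mu(year_index)

    def true_index_tonnes(self) -> pd.Series:
        """True integrated biomass per year (tonnes, catchability applied)."""
        c = self.config
        vals = []
        for t in range(c.n_years):
            d = self.true_density(t)
            kg = c.catchability * np.sum(d * self.cell_area_km2 / c.ref_swept_km2)
            vals.append(kg / 1000.0)
        return pd.Series(vals, index=self.years, name="true_index_t")


def _bathymetry(x: np.ndarray, y: np.ndarray, extent: float) -> np.ndarray:
    """Smooth positive-down depth surface: shelf gradient plus bumps."""
    d = 40.0 + 500.0 * (x / extent) + 60.0 * (y / extent)
    for cx, cy, amp, width in (
        (0.3, 0.7, -120.0, 0.18),
        (0.7, 0.25, 150.0, 0.22),
        (0.5, 0.5, -60.0, 0.3),
    ):
        r2 = ((x / extent - cx) ** 2 + (y / extent - cy) ** 2) / width**2
        d = d + amp * np.exp(-r2)
    # fine-scale ridges and channels: real bathymetry varies on scales far
    # below the residual field's correlation range, which is what makes the
    # depth effect separable from the latent field
    d = d * (
        1.0
        + 0.25 * np.sin(2.0 * np.pi * x / 31.0) * np.cos(2.0 * np.pi * y / 23.0)
        + 0.15 * np.sin(2.0 * np.pi * (x + y) / 17.0)
    )
    return np.maximum(d, 15.0)


def _base_temperature(x: np.ndarray, y: np.ndarray, extent: float) -> np.ndarray:
    """Spring bottom-temperature field: large-scale gradient plus mesoscale
    fronts.  The sub-range-scale structure matters: a purely planar thermal
    gradient would be absorbed by the latent spatial field (spatial
    confounding), leaving the temperature response unidentifiable."""
    return (
        1.0
        + 3.5 * (y / extent)
        + 1.5 * np.sin(2.0 * np.pi * x / extent)
        + 0.9 * np.sin(2.0 * np.pi * x / 47.0) * np.cos(2.0 * np.pi * y / 61.0)
        + 0.7 * np.sin(2.0 * np.pi * (x - 0.6 * y) / 37.0)
    )


def generate_domain(config: DomainConfig, seed: int) -> DomainTruth:
    """Realize a ground-truth domain: surfaces, year effects, latent fields.

    Deterministic given ``(config, seed)``.  Latent fields are drawn from
    the exact SPDE/Matern GMRF used by the fitting code, on a thinned truth
    mesh, then projected to the grid barycentrically.
    """
    c = config
    rng = np.random.default_rng(seed)
    half = c.grid_res_km / 2.0
    coords = np.arange(half, c.extent_km, c.grid_res_km)
    xg, yg = np.meshgrid(coords, coords)
    x = xg.ravel()
    y = yg.ravel()
    depth = _bathymetry(x, y, c.extent_km)
    base_t = _base_temperature(x, y, c.extent_km)
    years = np.arange(2000, 2000 + c.n_years)
    grid = pd.DataFrame({"x": x, "y": y, "depth_m": depth})
    proj = LocalProjection(c.lon0, c.lat0)
    grid["lon"], grid["lat"] = proj.to_lonlat(x, y)
    anomalies = rng.normal(0.0, c.temp_anomaly_sd, size=c.n_years)
    for t in range(c.n_years):
        grid[f"temp_y{t}"] = base_t + c.temp_trend_c_per_year * t + anomalies[t]

    # truth mesh over the grid; fields drawn at vertices then projected.
    # Jitter breaks the grid regularity that would otherwise create
    # degenerate (zero-area) Delaunay triangles.
    cand = grid[["x", "y"]].to_numpy() + rng.uniform(
        -0.3, 0.3, size=(len(grid), 2)
    ) * c.grid_res_km
    mesh = thin_and_mesh(cand, c.truth_mesh_cutoff_km, hull_buffer_km=c.range_km)
    spde = fem_matrices(mesh)
    a = projection_matrix(mesh, grid[["x", "y"]].to_numpy())
    nv = mesh.n_vertices
    n_cells = len(grid)

    def draw_fields() -> np.ndarray:
        """(n_years, n_vertices) combined spatial + spatio-temporal field.

        The spatio-temporal draw uses the exact year-by-year recursion of
        the iid/RW/AR1 (stationary-scaled) Kronecker GMRF, so only the
        spatial precision is ever factorized.
        """
        total = np.zeros((c.n_years, nv))
        if c.sigma_spatial > 0:
            qs = spde_precision(spde, c.range_km, c.sigma_spatial)
            total += sample_gmrf(qs.q, rng)[0][None, :]
        if c.sigma_st > 0:
            qs = spde_precision(spde, c.range_km, c.sigma_st)
            eps = sample_gmrf(qs.q, rng, n_draws=c.n_years)
            w = np.empty_like(eps)
            w[0] = eps[0]
            for t in range(1, c.n_years):
                if c.structure == "AR1":
                    w[t] = c.rho * w[t - 1] + np.sqrt(1.0 - c.rho**2) * eps[t]
                elif c.structure == "RW":
                    w[t] = w[t - 1] + eps[t]
                else:
                    w[t] = eps[t]
            total += w
        return total

    v_z_vert = draw_fields()
    v_y_vert = draw_fields()
    v_z = v_z_vert @ a.T
    v_y = v_y_vert @ a.T
    year_eff_z = np.concatenate([[0.0], rng.normal(0.0, c.year_sd, c.n_years - 1)])
    year_eff_y = np.concatenate([[0.0], rng.normal(0.0, c.year_sd, c.n_years - 1)])
    return DomainTruth(
        config=c,
        seed=seed,
        grid=grid,
        years=years,
        year_eff_z=year_eff_z,
        year_eff_y=year_eff_y,
        v_z=v_z,
        v_y=v_y,
        v_z_vertices=v_z_vert,
        v_y_vertices=v_y_vert,
        truth_mesh=mesh,
        projection=proj,
    )


def _strata_table(truth: DomainTruth) -> tuple[pd.DataFrame, np.ndarray]:
    """Depth-band strata with areas from cell counts."""
    c = truth.config
    depth = truth.grid["depth_m"].to_numpy()
    edges = np.quantile(depth, np.linspace(0, 1, c.n_strata + 1))
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    stratum = np.clip(np.searchsorted(edges, depth, side="right") - 1, 0, c.n_strata - 1)
    rows = []
    for s in range(c.n_strata):
        n_cells = int(np.sum(stratum == s))
        rows.append(
            {
                "stratum": s,
                "depth_min_m": float(edges[s]),
                "depth_max_m": float(edges[s + 1]),
                "area_km2": n_cells * truth.cell_area_km2,
            }
        )
    return pd.DataFrame(rows), stratum


def simulate_survey(
    truth: DomainTruth,
    n_per_year: int = 150,
    seed: int = 0,
    coverage_gaps: dict[int, int] | None = None,
) -> SurveyDataset:
    """Stratified-random survey of a realized domain.

    Tows are allocated to depth strata proportionally to stratum area and
    placed on distinct grid cells (jittered within the cell).  Occurrence is
    Bernoulli(pi(s,t)); positive biomass is Gamma with mean
    mu(s,t) * a_tow / a_ref and shape phi.  ``coverage_gaps`` maps year
    (calendar value) to a reduced tow count, emulating low-coverage surveys.
    """
    c = truth.config
    if n_per_year < 1:
        raise InvalidConfigError("n_per_year must be >= 1")
    rng = np.random.default_rng(seed)
    strata, cell_stratum = _strata_table(truth)
    n_cells = truth.n_cells
    if n_per_year > n_cells:
        raise InvalidConfigError(f"n_per_year={n_per_year} exceeds {n_cells} grid cells")
    gaps = coverage_gaps or {}
    frames = []
    tow_id = 0
    areas = strata["area_km2"].to_numpy()
    from scipy.special import expit

    gx = truth.grid["x"].to_numpy()
    gy = truth.grid["y"].to_numpy()
    depth = truth.grid["depth_m"].to_numpy()
    for t, year in enumerate(truth.years):
        n_year = int(gaps.get(int(year), n_per_year))
        if n_year < 1:
            continue
        # proportional allocation, at least 1 per stratum where possible
        alloc = np.maximum(np.round(n_year * areas / areas.sum()).astype(int), 1)
        while alloc.sum() > n_year:
            alloc[np.argmax(alloc)] -= 1
        while alloc.sum() < n_year:
            alloc[np.argmin(alloc)] += 1
        temp_t = truth.grid[f"temp_y{t}"].to_numpy()
        chosen: list[int] = []
        stratum_of: list[int] = []
        for s in range(len(strata)):
            cells = np.nonzero(cell_stratum == s)[0]
            take = min(alloc[s], cells.size)
            pick = rng.choice(cells, size=take, replace=False)
            chosen.extend(pick.tolist())
            stratum_of.extend([s] * take)
        chosen_arr = np.asarray(chosen, dtype=int)
        m = chosen_arr.size
        jx = gx[chosen_arr] + rng.uniform(-0.45, 0.45, m) * c.grid_res_km
        jy = gy[chosen_arr] + rng.uniform(-0.45, 0.45, m) * c.grid_res_km
        coords = np.column_stack([jx, jy])
        # covariates are the recorded cell values; the latent field is
        # evaluated at the actual tow location
        smooth = truth.f_temp(temp_t[chosen_arr]) + truth.f_depth(depth[chosen_arr])
        eta_z = (
            c.beta_z + truth.year_eff_z[t] + smooth
            + truth.field_at("occurrence", t, coords)
        )
        eta_y = (
            c.beta_y + truth.year_eff_y[t] + smooth
            + truth.field_at("positive", t, coords)
        )
        pi = expit(eta_z)
        mu = np.exp(eta_y)
        sln = np.log(1.0 + c.swept_cv**2)
        a_tow = c.ref_swept_km2 * rng.lognormal(-0.5 * sln, np.sqrt(sln), m)
        z = (rng.random(m) < pi).astype(int)
        mean = mu * a_tow / c.ref_swept_km2
        biomass = np.where(
            z == 1,
            np.maximum(rng.gamma(shape=c.phi, scale=mean / c.phi), 1e-9),
            0.0,
        )
        lon, lat = truth.projection.to_lonlat(jx, jy)
        frames.append(
            pd.DataFrame(
                {
                    "tow_id": tow_id + np.arange(m),
                    "x": jx,
                    "y": jy,
                    "lon": lon,
                    "lat": lat,
                    "year": int(year),
                    "depth_m": depth[chosen_arr],
                    "temp_c": temp_t[chosen_arr],
                    "swept_km2": a_tow,
                    "z": z,
                    "biomass_kg": biomass,
                    "stratum": stratum_of,
                }
            )
        )
        tow_id += m
    tows = pd.concat(frames, ignore_index=True)
    return SurveyDataset(tows=tows, strata=strata, projection=truth.projection)


def truth_prediction_grid(truth: DomainTruth) -> pd.DataFrame:
    """Prediction-grid table (indices module layout) from the truth grid."""
    c = truth.config
    out = truth.grid[["x", "y", "depth_m"]].copy()
    for t, year in enumerate(truth.years):
        out[f"temp_{year}"] = truth.grid[f"temp_y{t}"]
    out["area_km2"] = truth.cell_area_km2
    # synthetic division labels (three longitudinal bands, NAFO-style)
    thirds = np.digitize(out["x"], np.quantile(out["x"], [1 / 3, 2 / 3]))
    out["division"] = np.array(["3L", "3N", "3O"])[thirds]
    return out
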