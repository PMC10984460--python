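"""Two-part (delta-gamma) spatio-temporal GAM, fitted by maximum marginal
likelihood with a Laplace approximation over the latent Gaussian effects.

The model for a tow at location s in year t is

    Z(s,t) ~ Bernoulli(pi(s,t))        occurrence
    Y(s,t) | Z=1 ~ Gamma(mu(s,t), phi) positive biomass, Var = mu^2/phi

    logit pi = b_z + year_t + f_temp(T) + f_depth(log D) + V_z(s,t) + offset
    log  mu  = b_Y + year_t + f_temp(T) + f_depth(log D) + V_Y(s,t) + offset

with the log swept area as offset, P-spline smoothers f, and V a spatial
and/or spatio-temporal Gaussian Markov random field (SPDE/Matern nu=1) with
iid, random-walk, or AR1 dynamics across years.  The two sub-models are fit
independently; expected density combines them as pi * mu.

Estimation: the smoother coefficients and field values are integrated out
by a Laplace approximation (sparse inner Newton to the latent mode); fixed
effects and log/logit-transformed hyperparameters are maximized in an outer
quasi-Newton loop with finite-difference gradients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize

from .data import SurveyDataset
from .families import FAMILIES, BernoulliLogit, GammaLog
from .gmrf import logdet_spd, spacetime_precision, spde_precision, splu_factor
from .mesh import Mesh, SpdeStructures, fem_matrices, projection_matrix, thin_and_mesh
from .splines import SplineBasis, build_spline

logger = logging.getLogger(__name__)

ST_STRUCTURES = ("none", "iid", "RW", "AR1")


class NonConvergenceError(RuntimeError):
    pass


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class DeltaModelSpec:
    """Which terms enter both sub-models (Table-2-style structure strings).

    ``covariates`` maps model term names to tow-table columns; "depth" is
    log-transformed automatically (the smoother acts on log depth).
    """

    covariates: tuple[str, ...] = ("temp", "depth")
    year_effect: bool = True
    spatial: bool = True
    st_structure: str = "none"
    offset_column: str = "swept_km2"
    n_knots: int = 8

    def __post_init__(self):
        if self.st_structure not in ST_STRUCTURES:
            raise ValueError(f"st_structure must be one of {ST_STRUCTURES}")
        for c in self.covariates:
            if c not in ("temp", "depth"):
                raise ValueError(f"unknown covariate {c!r} (expected 'temp'/'depth')")

    @classmethod
    def from_formula(cls, formula: str, **overrides) -> "DeltaModelSpec":
        """Parse a structure string like ``biomass ~ year + temp + depth +
        spatial + AR1`` (the response part is optional; ``AR`` == ``AR1``)."""
        rhs = formula.split("~")[-1]
        tokens = [t.strip() for t in rhs.split("+") if t.strip()]
        cov = []
        year = False
        spatial = False
        st = "none"
        for tok in tokens:
            tl = tok.lower()
            if tl == "year":
                year = True
            elif tl in ("temp", "temperature"):
                cov.append("temp")
            elif tl in ("depth", "log_depth"):
                cov.append("depth")
            elif tl == "spatial":
                spatial = True
            elif tl in ("ar", "ar1"):
                st = "AR1"
            elif tl == "rw":
                st = "RW"
            elif tl == "iid":
                st = "iid"
            elif tl in ("1", "intercept"):
                pass
            else:
                raise ValueError(f"unknown model term {tok!r}")
        return cls(
            covariates=tuple(cov), year_effect=year, spatial=spatial, st_structure=st, **overrides
        )

    @property
    def label(self) -> str:
        parts = []
        if self.year_effect:
            parts.append("year")
        parts += list(self.covariates)
        if self.spatial:
            parts.append("spatial")
        if self.st_structure != "none":
            parts.append(self.st_structure)
        return "biomass ~ " + " + ".join(parts) if parts else "biomass ~ 1"


@dataclass
class FitOptions:
    inner_tol: float = 1e-8
    inner_maxit: int = 100
    outer_gtol: float = 1e-3
    outer_maxit: int = 300
    fd_eps: float = 1e-5
    compute_se: str = "full"  # "full" | "none"
    hessian_step: float = 1e-3


# ---------------------------------------------------------------------------
# design bundle


@dataclass
class RandomBlock:
    name: str
    kind: str  # "spline" | "spatial" | "st"
    z: sp.csr_matrix
    size: int


@dataclass
class DesignBundle:
    """Everything `joint_nll` needs: response, designs, priors, offset."""

    y: np.ndarray
    x: np.ndarray
    x_names: list[str]
    offset: np.ndarray
    blocks: list[RandomBlock]
    hyper_names: list[str]
    family: type
    spec: DeltaModelSpec
    years: np.ndarray
    bases: dict[str, SplineBasis]
    mesh: Mesh | None = None
    spde: SpdeStructures | None = None
    kept_cols: np.ndarray | None = None  # indices into the full fixed design
    _z: sp.csr_matrix | None = None
    _qs_logdet_cache: dict = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.x.shape[1]

    @property
    def n_hyper(self) -> int:
        return len(self.hyper_names)

    @property
    def n_latent(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def z(self) -> sp.csr_matrix:
        if self._z is None:
            if self.blocks:
                self._z = sp.hstack([b.z for b in self.blocks], format="csr")
            else:
                self._z = sp.csr_matrix((self.n, 0))
        return self._z

    # -- hyperparameters ----------------------------------------------------
    def split_outer(self, outer: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
        outer = np.asarray(outer, dtype=float)
        beta = outer[: self.p]
        hypers = dict(zip(self.hyper_names, outer[self.p :]))
        return beta, hypers

    def natural_hypers(self, hypers: dict[str, float]) -> dict[str, float]:
        """Working-scale (log / atanh) hypers to natural scale."""
        out = {}
        for k, v in hypers.items():
            if k == "trho":
                out["rho"] = float(np.tanh(v))
            else:
                out[k.replace("log_", "")] = float(np.exp(v))
        return out

    def _spatial_logdet(self, range_km: float) -> float:
        """logdet of the unit-sigma spatial SPDE precision, cached by range."""
        key = round(float(range_km), 10)
        if key not in self._qs_logdet_cache:
            q1 = spde_precision(self.spde, range_km, 1.0)
            self._qs_logdet_cache[key] = logdet_spd(q1.q)
        return self._qs_logdet_cache[key]

    def prior_precision(self, hypers: dict[str, float]) -> tuple[sp.csc_matrix, float]:
        """Block-diagonal latent prior precision and its log-determinant.

        Log-determinants use the scale identities (Q scales as 1/sigma^2)
        and the analytic temporal factors, so only one sparse factorization
        per distinct range value is ever needed.
        """
        nat = self.natural_hypers(hypers)
        qs = None
        mats = []
        logdet = 0.0
        for b in self.blocks:
            if b.kind == "spline":
                sd = nat[f"sd_{b.name}"]
                mats.append(sp.eye(b.size) / sd**2)
                logdet += -2.0 * b.size * np.log(sd)
            elif b.kind == "spatial":
                qs_unit_ld = self._spatial_logdet(nat["range"])
                qsp = spde_precision(self.spde, nat["range"], nat["sigma_sp"])
                mats.append(qsp.q)
                logdet += qs_unit_ld - 2.0 * qsp.q.shape[0] * np.log(nat["sigma_sp"])
            elif b.kind == "st":
                if qs is None:
                    qs = spde_precision(self.spde, nat["range"], nat["sigma_st"])
                nv = qs.q.shape[0]
                t = len(self.years)
                structure = self.spec.st_structure
                rho = nat.get("rho")
                qst = spacetime_precision(qs, structure, rho, t)
                mats.append(qst.q)
                ld_qs = self._spatial_logdet(nat["range"]) - 2.0 * nv * np.log(nat["sigma_st"])
                if structure == "AR1":
                    ld_qt = -(t - 1) * np.log(1.0 - rho**2)
                else:  # iid and the anchored RW both have unit determinant
                    ld_qt = 0.0
                logdet += t * ld_qs + nv * ld_qt
        if not mats:
            return sp.csc_matrix((0, 0)), 0.0
        return sp.block_diag(mats, format="csc"), float(logdet)

    def phi(self, hypers: dict[str, float]) -> float | None:
        return float(np.exp(hypers["log_phi"])) if "log_phi" in hypers else None


def _full_fixed_design(
    df: pd.DataFrame, spec: DeltaModelSpec, years: np.ndarray, bases: dict[str, SplineBasis]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if spec.year_effect:
        for yr in years[1:]:
            cols.append((df["year"].to_numpy() == yr).astype(float))
            names.append(f"year_{yr}")
    for cov in spec.covariates:
        basis = bases[cov]
        xval = _covariate_values(df, cov)
        lin, _ = basis.evaluate(xval)
        cols.append(lin)
        names.append(f"{cov}_lin")
    return np.column_stack(cols), names


def _covariate_values(df: pd.DataFrame, cov: str) -> np.ndarray:
    if cov == "temp":
        return df["temp_c"].to_numpy(dtype=float)
    if cov == "depth":
        return np.log(df["depth_m"].to_numpy(dtype=float))
    raise KeyError(cov)


def _st_projection(
    a: sp.csr_matrix, year_idx: np.ndarray, n_years: int
) -> sp.csr_matrix:
    """Expand a spatial projection matrix to vertices-by-years columns."""
    a = a.tocoo()
    nv = a.shape[1]
    cols = year_idx[a.row] * nv + a.col
    return sp.coo_matrix((a.data, (a.row, cols)), shape=(a.shape[0], nv * n_years)).tocsr()


def build_bundle(
    dataset: SurveyDataset,
    spec: DeltaModelSpec,
    family,
    mesh: Mesh | None = None,
    spde: SpdeStructures | None = None,
    years: np.ndarray | None = None,
    bases: dict[str, SplineBasis] | None = None,
) -> DesignBundle:
    """Assemble the design bundle for one sub-model."""
    df = dataset.tows
    if years is None:
        years = np.sort(df["year"].unique())
    if bases is None:
        bases = {
            cov: build_spline(_covariate_values(df, cov), spec.n_knots, name=cov)
            for cov in spec.covariates
        }
    x_full, names_full = _full_fixed_design(df, spec, years, bases)
    keep = np.nonzero(np.abs(x_full).sum(axis=0) > 0)[0]
    if keep.size < x_full.shape[1]:
        dropped = [names_full[i] for i in range(x_full.shape[1]) if i not in keep]
        logger.warning("dropping all-zero fixed-effect columns: %s", dropped)
    x = x_full[:, keep]
    x_names = [names_full[i] for i in keep]

    blocks: list[RandomBlock] = []
    hyper_names: list[str] = []
    for cov in spec.covariates:
        basis = bases[cov]
        _, zp = basis.evaluate(_covariate_values(df, cov))
        blocks.append(RandomBlock(cov, "spline", sp.csr_matrix(zp), zp.shape[1]))
        hyper_names.append(f"log_sd_{cov}")
    needs_mesh = spec.spatial or spec.st_structure != "none"
    a = None
    if needs_mesh:
        if mesh is None:
            raise ValueError("spec includes a field term but no mesh was supplied")
        if spde is None:
            spde = fem_matrices(mesh)
        a = projection_matrix(mesh, df[["x", "y"]].to_numpy())
        hyper_names.append("log_range")
    if spec.spatial:
        blocks.append(RandomBlock("spatial", "spatial", a, mesh.n_vertices))
        hyper_names.append("log_sigma_sp")
    if spec.st_structure != "none":
        yidx = np.searchsorted(years, df["year"].to_numpy())
        zst = _st_projection(a, yidx, len(years))
        blocks.append(RandomBlock("st", "st", zst, mesh.n_vertices * len(years)))
        hyper_names.append("log_sigma_st")
        if spec.st_structure == "AR1":
            hyper_names.append("trho")
    if family is GammaLog:
        hyper_names.append("log_phi")
        y = df["biomass_kg"].to_numpy(dtype=float)
    elif family is BernoulliLogit:
        y = df["z"].to_numpy(dtype=float)
    else:
        y = df["biomass_kg"].to_numpy(dtype=float)
    offset = np.log(df[spec.offset_column].to_numpy(dtype=float))
    return DesignBundle(
        y=y,
        x=x,
        x_names=x_names,
        offset=offset,
        blocks=blocks,
        hyper_names=hyper_names,
        family=family,
        spec=spec,
        years=years,
        bases=bases,
        mesh=mesh,
        spde=spde,
        kept_cols=keep,
    )


# ---------------------------------------------------------------------------
# likelihood machinery


def joint_nll(outer: np.ndarray, latent: np.ndarray, bundle: DesignBundle, family=None) -> float:
    """Negative log of [data likelihood x latent GMRF and smoother priors].

    ``outer`` stacks the fixed effects and working-scale hyperparameters;
    ``latent`` stacks penalized spline coefficients and field values.
    """
    fam = family or bundle.family
    beta, hypers = bundle.split_outer(outer)
    latent = np.asarray(latent, dtype=float)
    eta = bundle.x @ beta + bundle.offset
    if latent.size:
        eta = eta + bundle.z @ latent
    val = fam.nll(bundle.y, eta, bundle.phi(hypers))
    if latent.size:
        q, logdet_q = bundle.prior_precision(hypers)
        val += float(
            0.5 * latent @ (q @ latent)
            - 0.5 * logdet_q
            + 0.5 * latent.size * np.log(2.0 * np.pi)
        )
    return float(val)


def laplace_marginal_nll(
    outer: np.ndarray,
    bundle: DesignBundle,
    family=None,
    u0: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> tuple[float, np.ndarray]:
    """Laplace-approximate marginal negative log-likelihood.

    Inner sparse Newton iterations find the latent mode u*; the marginal is
    joint(u*) + 0.5 logdet H(u*) - (n_latent/2) log 2pi with H the inner
    Hessian.  Exact whenever the data likelihood is Gaussian in the latents.
    Returns (marginal nll, latent mode).
    """
    opts = options or FitOptions()
    fam = family or bundle.family
    beta, hypers = bundle.split_outer(outer)
    phi = bundle.phi(hypers)
    m = bundle.n_latent
    eta_fixed = bundle.x @ beta + bundle.offset
    if m == 0:
        return fam.nll(bundle.y, eta_fixed, phi), np.zeros(0)
    q, logdet_q = bundle.prior_precision(hypers)
    z = bundle.z
    u = np.zeros(m) if u0 is None or u0.size != m else u0.copy()

    def inner_obj(uv):
        eta = eta_fixed + z @ uv
        return fam.nll(bundle.y, eta, phi) + 0.5 * uv @ (q @ uv), eta

    f_cur, eta = inner_obj(u)
    lu = None
    for _ in range(opts.inner_maxit):
        d1 = fam.d1(bundle.y, eta, phi)
        grad = z.T @ d1 + q @ u
        if np.max(np.abs(grad)) < opts.inner_tol:
            break
        w = fam.d2(bundle.y, eta, phi)
        h = (q + (z.T @ sp.diags(w) @ z)).tocsc()
        lu = splu_factor(h)
        step = lu.solve(grad)
        t = 1.0
        for _ in range(30):
            u_new = u - t * step
            f_new, eta_new = inner_obj(u_new)
            if f_new <= f_cur + 1e-12 * abs(f_cur):
                break
            t *= 0.5
        u, f_cur, eta = u_new, f_new, eta_new
    else:
        d1 = fam.d1(bundle.y, eta, phi)
        grad = z.T @ d1 + q @ u
        gnorm = float(np.max(np.abs(grad)))
        # accept a near-stationary mode (floating-point floor); the Laplace
        # value is second-order insensitive to the residual gradient
        if gnorm > 1e-5 * max(1.0, abs(f_cur)):
            raise NonConvergenceError(
                f"inner Newton did not converge: |grad|_inf = {gnorm:.3g}"
            )
    # Hessian at the mode (recompute; the last factorization predates the step)
    w = fam.d2(bundle.y, eta, phi)
    h = (q + (z.T @ sp.diags(w) @ z)).tocsc()
    logdet_h = logdet_spd(h)
    marginal = f_cur - 0.5 * logdet_q + 0.5 * logdet_h
    return float(marginal), u


def profile_laplace_nll(
    hyper_vec: np.ndarray,
    bundle: DesignBundle,
    warm: dict | None = None,
    options: FitOptions | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Laplace marginal nll with the fixed effects profiled in the inner loop.

    The inner Newton optimizes (beta, u) jointly — beta carries no prior —
    and the Laplace log-determinant is taken over the latent block only,
    via logdet H_uu = logdet J + logdet (J^-1)_bb with J the joint Hessian.
    This keeps the outer optimization down to the few hyperparameters; it
    agrees with maximizing :func:`laplace_marginal_nll` over beta up to the
    (weak) dependence of the latent log-determinant on beta, and is exact
    for Gaussian responses.  Returns (marginal nll, beta, latent mode).
    """
    opts = options or FitOptions()
    fam = bundle.family
    hypers = dict(zip(bundle.hyper_names, np.asarray(hyper_vec, dtype=float)))
    phi = bundle.phi(hypers)
    p = bundle.p
    m = bundle.n_latent
    x = bundle.x
    z = bundle.z
    if m:
        q, logdet_q = bundle.prior_precision(hypers)
    beta = np.zeros(p)
    u = np.zeros(m)
    if warm:
        if warm.get("beta") is not None and warm["beta"].size == p:
            beta = warm["beta"].copy()
        if warm.get("u") is not None and warm["u"].size == m:
            u = warm["u"].copy()

    def obj(bv, uv):
        eta = x @ bv + bundle.offset
        if m:
            eta = eta + z @ uv
        val = fam.nll(bundle.y, eta, phi)
        if m:
            val += 0.5 * uv @ (q @ uv)
        return val, eta

    f_cur, eta = obj(beta, u)
    lu = None
    for _ in range(opts.inner_maxit):
        d1 = fam.d1(bundle.y, eta, phi)
        gb = x.T @ d1
        grad = gb if m == 0 else np.concatenate([gb, z.T @ d1 + q @ u])
        if np.max(np.abs(grad)) < max(opts.inner_tol, 1e-10 * max(1.0, abs(f_cur))):
            break
        w = fam.d2(bundle.y, eta, phi)
        xw = x * w[:, None]
        j11 = sp.csc_matrix(x.T @ xw)
        if m:
            j12 = sp.csc_matrix(xw.T @ z)
            j22 = q + z.T @ sp.diags(w) @ z
            j = sp.bmat([[j11, j12], [j12.T, j22]], format="csc")
        else:
            j = j11
        lu = splu_factor(j)
        step = lu.solve(grad)
        t = 1.0
        for _ in range(30):
            bn = beta - t * step[:p]
            un = u - t * step[p:]
            f_new, eta_new = obj(bn, un)
            if f_new <= f_cur + 1e-12 * abs(f_cur):
                break
            t *= 0.5
        beta, u, f_cur, eta = bn, un, f_new, eta_new
    else:
        gnorm = float(np.max(np.abs(grad)))
        if gnorm > 1e-5 * max(1.0, abs(f_cur)):
            raise NonConvergenceError(
                f"inner Newton (profiled) did not converge: |grad|_inf = {gnorm:.3g}"
            )
    if warm is not None:
        warm["beta"], warm["u"] = beta.copy(), u.copy()
    if m == 0:
        return float(f_cur), beta, u
    # logdet of the latent block of the joint Hessian at the mode
    w = fam.d2(bundle.y, eta, phi)
    xw = x * w[:, None]
    j11 = sp.csc_matrix(x.T @ xw)
    j12 = sp.csc_matrix(xw.T @ z)
    j22 = q + z.T @ sp.diags(w) @ z
    j = sp.bmat([[j11, j12], [j12.T, j22]], format="csc")
    lu = splu_factor(j)
    logdet_j = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
    eb = np.zeros((p + m, p))
    eb[np.arange(p), np.arange(p)] = 1.0
    cov_bb = lu.solve(eb)[:p, :p]
    sign, logdet_cov_bb = np.linalg.slogdet(cov_bb)
    if sign <= 0:
        raise NonConvergenceError("joint Hessian not positive definite at the mode")
    logdet_h_uu = logdet_j + logdet_cov_bb
    marginal = f_cur - 0.5 * logdet_q + 0.5 * logdet_h_uu
    return float(marginal), beta, u


# ---------------------------------------------------------------------------
# fitted sub-model and results


@dataclass
class SubModelFit:
    """One sub-model (occurrence or positive biomass) after optimization."""

    part: str
    bundle: DesignBundle
    outer: np.ndarray
    latent: np.ndarray
    marginal_nll: float
    converged: bool
    message: str
    n_obs: int
    beta_se: np.ndarray | None = None
    hyper_cov: np.ndarray | None = None  # FD covariance of the working-scale hypers
    joint_precision: sp.csc_matrix | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.outer[: self.bundle.p]

    @property
    def hypers_working(self) -> dict[str, float]:
        return dict(zip(self.bundle.hyper_names, self.outer[self.bundle.p :]))

    @property
    def hypers(self) -> dict[str, float]:
        return self.bundle.natural_hypers(self.hypers_working)

    @property
    def df(self) -> int:
        """Outer parameters only: fixed effects + hyperparameters."""
        return self.bundle.p + self.bundle.n_hyper

    def hyper_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Wald interval on the working scale, transformed to natural scale."""
        from scipy.stats import norm

        if self.hyper_cov is None:
            raise ValueError("fit was run without standard errors")
        i = self.bundle.hyper_names.index(name)
        se = float(np.sqrt(max(self.hyper_cov[i, i], 0.0)))
        zq = norm.ppf(0.5 + level / 2)
        est = self.outer[self.bundle.p + i]
        lo, hi = est - zq * se, est + zq * se
        if name == "trho":
            return float(np.tanh(lo)), float(np.tanh(hi))
        return float(np.exp(lo)), float(np.exp(hi))

    def smooth_effect(
        self, name: str, x_eval: np.ndarray, coefs: tuple | None = None
    ) -> np.ndarray:
        """Fitted smooth f(x) (linear + penalized parts) at covariate values.

        ``name`` is a model covariate ("temp" or "depth"); depth values are
        on the log-depth scale used by the smoother.
        """
        b = self.bundle
        basis = b.bases[name]
        lin, zpen = basis.evaluate(np.asarray(x_eval, dtype=float))
        beta, latent = coefs if coefs is not None else (self.beta, self.latent)
        i_lin = b.x_names.index(f"{name}_lin")
        offset_u = 0
        for blk in b.blocks:
            if blk.name == name:
                break
            offset_u += blk.size
        return lin * beta[i_lin] + zpen @ latent[offset_u : offset_u + blk.size]

    def smooth_optimum(
        self,
        name: str,
        n_grid: int = 201,
        n_draws: int = 300,
        seed: int = 0,
        level: float = 0.95,
    ) -> tuple[float, float, float]:
        """Location of the maximum of a fitted smooth, with a percentile
        interval from draws of the joint Gaussian approximation."""
        b = self.bundle
        basis = b.bases[name]
        xg = np.linspace(basis.knots[3], basis.knots[-4], n_grid)
        opt = float(xg[np.argmax(self.smooth_effect(name, xg))])
        rng = np.random.default_rng(seed)
        draws = self.sample_coefs(n_draws, rng)
        opts = np.array([xg[np.argmax(self.smooth_effect(name, xg, coefs=d))] for d in draws])
        a = (1.0 - level) / 2.0
        return opt, float(np.quantile(opts, a)), float(np.quantile(opts, 1.0 - a))

    # -- prediction ---------------------------------------------------------
    def design_for(self, df_new: pd.DataFrame) -> tuple[np.ndarray, sp.csr_matrix]:
        """Fixed and random designs for new rows (same coding as training)."""
        b = self.bundle
        x_full, _ = _full_fixed_design(df_new, b.spec, b.years, b.bases)
        x = x_full[:, b.kept_cols]
        zparts = []
        a = None
        for blk in b.blocks:
            if blk.kind == "spline":
                _, zp = b.bases[blk.name].evaluate(_covariate_values(df_new, blk.name))
                zparts.append(sp.csr_matrix(zp))
            elif blk.kind == "spatial":
                if a is None:
                    a = projection_matrix(b.mesh, df_new[["x", "y"]].to_numpy())
                zparts.append(a)
            elif blk.kind == "st":
                if a is None:
                    a = projection_matrix(b.mesh, df_new[["x", "y"]].to_numpy())
                yidx = np.searchsorted(b.years, df_new["year"].to_numpy())
                zparts.append(_st_projection(a, yidx, len(b.years)))
        z = sp.hstack(zparts, format="csr") if zparts else sp.csr_matrix((len(df_new), 0))
        return x, z

    def linear_predictor(
        self, df_new: pd.DataFrame, offset_new: np.ndarray, coefs: tuple | None = None
    ) -> np.ndarray:
        """eta at new rows; latent effects at their (posterior-mode) values.

        ``coefs`` optionally overrides (beta, latent), e.g. for CI draws.
        """
        x, z = self.design_for(df_new)
        beta, latent = coefs if coefs is not None else (self.beta, self.latent)
        eta = x @ beta + np.asarray(offset_new, dtype=float)
        if latent.size:
            eta = eta + z @ latent
        return eta

    def sample_coefs(self, n_draws: int, rng: np.random.Generator) -> list[tuple]:
        """Draws of (beta, latent) from the joint Gaussian approximation."""
        if self.joint_precision is None:
            raise ValueError("fit was run without the joint precision")
        mean = np.concatenate([self.beta, self.latent])
        qd = np.asarray(self.joint_precision.todense())
        chol = np.linalg.cholesky(qd)
        from scipy.linalg import solve_triangular

        zd = rng.standard_normal((qd.shape[0], n_draws))
        devs = solve_triangular(chol.T, zd, lower=False).T
        p = self.bundle.p
        return [(mean[:p] + d[:p], mean[p:] + d[p:]) for d in devs]


@dataclass
class DeltaGammaResults:
    """Fitted delta-gamma model: both sub-fits plus combined bookkeeping."""

    spec: DeltaModelSpec
    occurrence: SubModelFit
    positive: SubModelFit
    mesh: Mesh | None

    @property
    def marginal_nll(self) -> float:
        return self.occurrence.marginal_nll + self.positive.marginal_nll

    @property
    def df(self) -> int:
        return self.occurrence.df + self.positive.df

    @property
    def aic(self) -> float:
        return 2.0 * self.marginal_nll + 2.0 * self.df

    @property
    def converged(self) -> bool:
        return self.occurrence.converged and self.positive.converged

    def sub(self, part: str) -> SubModelFit:
        return {"occurrence": self.occurrence, "positive": self.positive}[part]

    def summary(self) -> str:
        lines = [
            "Delta-gamma spatio-temporal GAM",
            f"  structure : {self.spec.label}",
            f"  df = {self.df}   marginal nll = {self.marginal_nll:.4f}   "
            f"AIC = {self.aic:.4f}",
            f"  converged : {self.converged}",
        ]
        if self.mesh is not None:
            lines.append(
                f"  mesh      : {self.mesh.n_vertices} vertices "
                f"(cutoff {self.mesh.cutoff_km} km)"
            )
        for part in ("occurrence", "positive"):
            f = self.sub(part)
            lines.append(f"-- {part} sub-model (n = {f.n_obs}) --")
            lines.append(f"   {'term':<14}{'estimate':>12}{'std err':>12}")
            se = f.beta_se if f.beta_se is not None else [np.nan] * f.bundle.p
            for name, b, s in zip(f.bundle.x_names, f.beta, se):
                lines.append(f"   {name:<14}{b:>12.4f}{s:>12.4f}")
            for hname, hval in f.hypers.items():
                lines.append(f"   {hname:<14}{hval:>12.4f}")
        return "\n".join(lines)


class DeltaGammaModel:
    """Two-part spatio-temporal GAM of survey biomass.

    Parameters
    ----------
    dataset : SurveyDataset
        Tow-level observations (validated container).
    spec : DeltaModelSpec
        Model structure; see :meth:`DeltaModelSpec.from_formula`.
    mesh_cutoff_km : float
        Minimum vertex spacing when a mesh has to be built from the tow
        locations (ignored if ``mesh`` is given).
    hull_buffer_km : float
        Outward hull buffer for the mesh boundary; defaults to the assumed
        spatial range if None.
    """

    def __init__(
        self,
        dataset: SurveyDataset,
        spec: DeltaModelSpec,
        mesh: Mesh | None = None,
        mesh_cutoff_km: float = 20.0,
        hull_buffer_km: float | None = None,
    ):
        self.dataset = dataset
        self.spec = spec
        needs_mesh = spec.spatial or spec.st_structure != "none"
        if needs_mesh and mesh is None:
            buf = hull_buffer_km if hull_buffer_km is not None else 3.0 * mesh_cutoff_km
            mesh = thin_and_mesh(
                dataset.tows[["x", "y"]].to_numpy(), mesh_cutoff_km, buf
            )
        self.mesh = mesh if needs_mesh else None
        self.spde = fem_matrices(self.mesh) if self.mesh is not None else None

    @classmethod
    def from_formula(cls, formula: str, dataset: SurveyDataset, **kwargs) -> "DeltaGammaModel":
        spec_kw = {k: kwargs.pop(k) for k in ("n_knots", "offset_column") if k in kwargs}
        return cls(dataset, DeltaModelSpec.from_formula(formula, **spec_kw), **kwargs)

    # -- fitting ------------------------------------------------------------
    def fit(
        self,
        seed: int = 0,
        options: FitOptions | None = None,
        start: "DeltaGammaResults | None" = None,
    ) -> DeltaGammaResults:
        """Maximize the Laplace-approximate marginal likelihood.

        The seed only matters for optimizer restarts after a failed first
        attempt; the objective itself is deterministic.  ``start``
        optionally warm-starts the hyperparameters from a previous fit of
        the same structure (e.g. the full-data fit when cross-validating).
        """
        opts = options or FitOptions()
        occ = self._fit_sub(
            "occurrence", self._bundle("occurrence"), seed, opts,
            start=None if start is None else start.occurrence,
        )
        posfit = self._fit_sub(
            "positive", self._bundle("positive"), seed, opts,
            start=None if start is None else start.positive,
        )
        return DeltaGammaResults(
            spec=self.spec, occurrence=occ, positive=posfit, mesh=self.mesh
        )

    def fit_part(
        self,
        part: str,
        seed: int = 0,
        options: FitOptions | None = None,
        start: "SubModelFit | None" = None,
    ) -> SubModelFit:
        """Fit a single sub-model ("occurrence" or "positive") on its own."""
        opts = options or FitOptions()
        return self._fit_sub(part, self._bundle(part), seed, opts, start=start)

    def _bundle(self, part: str) -> DesignBundle:
        years = self.dataset.years
        if part == "occurrence":
            return build_bundle(
                self.dataset, self.spec, BernoulliLogit, self.mesh, self.spde, years
            )
        if part == "positive":
            pos = self.dataset.positive()
            if len(pos.tows) < 10:
                raise InsufficientDataError(
                    f"only {len(pos.tows)} positive tows; need at least 10"
                )
            return build_bundle(pos, self.spec, GammaLog, self.mesh, self.spde, years)
        raise ValueError(part)

    def _initial_outer(self, bundle: DesignBundle) -> np.ndarray:
        beta0 = np.zeros(bundle.p)
        if bundle.family is BernoulliLogit:
            pbar = float(np.clip(bundle.y.mean(), 0.02, 0.98))
            beta0[0] = np.log(pbar / (1 - pbar)) - bundle.offset.mean()
        else:
            beta0[0] = float(np.log(bundle.y.mean())) - bundle.offset.mean()
        h0 = []
        extent = 1.0
        if bundle.mesh is not None:
            pts = bundle.mesh.points[: bundle.mesh.n_interior]
            extent = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
        for name in bundle.hyper_names:
            if name.startswith("log_sd_"):
                h0.append(np.log(0.5))
            elif name == "log_range":
                h0.append(np.log(max(extent / 4.0, 1.0)))
            elif name in ("log_sigma_sp", "log_sigma_st"):
                h0.append(np.log(0.5))
            elif name == "trho":
                h0.append(np.arctanh(0.5))
            elif name == "log_phi":
                h0.append(0.0)
        return np.concatenate([beta0, np.asarray(h0)])

    def _bounds(self, bundle: DesignBundle) -> list[tuple]:
        bounds: list[tuple] = [(None, None)] * bundle.p
        extent = 1.0
        if bundle.mesh is not None:
            pts = bundle.mesh.points[: bundle.mesh.n_interior]
            extent = float(np.max(pts.max(axis=0) - pts.min(axis=0)))
        for name in bundle.hyper_names:
            if name == "log_range":
                lo = np.log(max(bundle.mesh.cutoff_km / 2.0, 1e-3))
                bounds.append((lo, np.log(4.0 * extent)))
            elif name == "trho":
                bounds.append((-4.0, 4.0))
            elif name == "log_phi":
                bounds.append((-5.0, 8.0))
            else:  # log sds / sigmas
                bounds.append((-8.0, 4.0))
        return bounds

    def _fit_sub(
        self,
        part: str,
        bundle: DesignBundle,
        seed: int,
        opts: FitOptions,
        start: SubModelFit | None = None,
    ) -> SubModelFit:
        """Outer quasi-Newton over the working-scale hyperparameters of the
        profiled Laplace marginal; fixed effects are profiled in the inner
        Newton (and counted as outer parameters in the df bookkeeping)."""
        warm: dict = {}

        def objective(hv):
            val, _, _ = profile_laplace_nll(hv, bundle, warm, opts)
            return val

        x0_full = self._initial_outer(bundle)
        h0 = x0_full[bundle.p :]
        if start is not None and start.bundle.hyper_names == bundle.hyper_names:
            h0 = start.outer[start.bundle.p :].copy()
        hbounds = self._bounds(bundle)[bundle.p :]
        rng = np.random.default_rng(seed)
        if h0.size == 0:
            final, beta, u = profile_laplace_nll(h0, bundle, warm, opts)
            hx = h0
            converged, message = True, "no hyperparameters; inner Newton only"
        else:
            res = None
            for attempt in range(3):
                start = h0 if attempt == 0 else h0 + 0.3 * rng.standard_normal(h0.size)
                res = minimize(
                    objective,
                    start,
                    method="L-BFGS-B",
                    bounds=hbounds,
                    options={
                        "eps": opts.fd_eps,
                        "maxiter": opts.outer_maxit,
                        "gtol": opts.outer_gtol,
                        "ftol": 1e-11,
                    },
                )
                if res.success or res.status == 0:
                    break
                logger.warning("%s sub-model attempt %d: %s", part, attempt, res.message)
            hx = res.x
            converged, message = bool(res.success), str(res.message)
            final, beta, u = profile_laplace_nll(hx, bundle, warm, opts)
        fit = SubModelFit(
            part=part,
            bundle=bundle,
            outer=np.concatenate([beta, hx]),
            latent=u,
            marginal_nll=final,
            converged=converged,
            message=message,
            n_obs=bundle.n,
        )
        self._joint_precision(fit)
        if opts.compute_se == "full" and hx.size:
            self._hyper_covariance(fit, opts)
        if not converged:
            logger.warning("%s sub-model did not converge: %s", part, message)
        return fit

    @staticmethod
    def _joint_precision(fit: SubModelFit) -> None:
        """Gaussian approximation precision over (beta, latent) at the mode."""
        b = fit.bundle
        beta, hypers = b.split_outer(fit.outer)
        phi = b.phi(hypers)
        eta = b.x @ beta + b.offset
        if fit.latent.size:
            eta = eta + b.z @ fit.latent
        w = b.family.d2(b.y, eta, phi)
        xw = b.x * w[:, None]
        j11 = sp.csc_matrix(b.x.T @ xw)
        if fit.latent.size:
            q, _ = b.prior_precision(hypers)
            j22 = q + b.z.T @ sp.diags(w) @ b.z
            j12 = sp.csc_matrix(xw.T @ b.z)
            j = sp.bmat([[j11, j12], [j12.T, j22]], format="csc")
        else:
            j = j11
        fit.joint_precision = j
        lu = splu_factor(j)
        p = b.p
        cols = np.zeros((j.shape[0], p))
        cols[np.arange(p), np.arange(p)] = 1.0
        cov_cols = lu.solve(cols)
        fit.beta_se = np.sqrt(np.maximum(np.diag(cov_cols[:p, :p]), 0.0))

    def _hyper_covariance(self, fit: SubModelFit, opts: FitOptions) -> None:
        """FD Hessian of the profiled marginal over the working-scale hypers.

        Profiling the fixed effects makes this the correct marginal
        curvature for Wald intervals on the hyperparameters.
        """
        b = fit.bundle
        warm = {"beta": fit.beta.copy(), "u": fit.latent.copy()}

        def f(hv):
            val, _, _ = profile_laplace_nll(hv, b, warm, opts)
            return val

        x = fit.outer[b.p :]
        d = x.size
        h = opts.hessian_step
        hess = np.zeros((d, d))
        f0 = fit.marginal_nll
        fp = np.zeros(d)
        fm = np.zeros(d)
        for i in range(d):
            ei = np.zeros(d)
            ei[i] = h
            fp[i] = f(x + ei)
            fm[i] = f(x - ei)
            hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h**2
        for i in range(d):
            for j in range(i + 1, d):
                ei = np.zeros(d)
                ej = np.zeros(d)
                ei[i] = h
                ej[j] = h
                fpp = f(x + ei + ej)
                fmm = f(x - ei - ej)
                hess[i, j] = hess[j, i] = (
                    fpp + fmm - fp[i] - fm[i] - fp[j] - fm[j] + 2.0 * f0
                ) / (2.0 * h**2)
        try:
            cov = np.linalg.inv(hess)
            if np.any(np.diag(cov) < 0):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            logger.warning("outer Hessian not positive definite; using pseudo-inverse")
            cov = np.linalg.pinv(hess)
        fit.hyper_cov = cov
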