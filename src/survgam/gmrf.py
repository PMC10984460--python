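"""Sparse precision matrices for Matern (nu = 1) spatial and
spatio-temporal Gaussian Markov random fields.

The SPDE construction gives a GMRF on mesh vertices whose correlation
approximates a Matern covariance with smoothness nu = 1; the "range" is the
distance at which correlation drops to ~0.13.  Spatio-temporal fields
combine the spatial precision with an AR1, random-walk, or iid structure
across years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import SpdeStructures

VALID_STRUCTURES = ("iid", "RW", "AR1")


@dataclass
class FieldPrecision:
    """Sparse SPD precision over mesh vertices (x years when temporal)."""

    q: sp.csc_matrix
    range_km: float
    sigma: float
    structure: str = "spatial"  # "spatial", "iid", "RW", "AR1"
    rho: float | None = None
    n_years: int = 1

    @property
    def n(self) -> int:
        return self.q.shape[0]


def spde_precision(spde: SpdeStructures, range_km: float, sigma: float) -> FieldPrecision:
    """Matern nu=1 precision Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^-1 G).

    ``kappa = sqrt(8 nu) / range`` and ``tau`` is set so the stationary
    marginal standard deviation equals ``sigma``
    (``sigma^2 = 1 / (4 pi kappa^2 tau^2)`` in two dimensions).
    """
    if range_km <= 0 or sigma <= 0:
        raise ValueError(f"range_km and sigma must be > 0 (got {range_km}, {sigma})")
    kappa = np.sqrt(8.0) / range_km
    tau2 = 1.0 / (4.0 * np.pi * kappa**2 * sigma**2)
    c = spde.c
    g = spde.g
    cinv = sp.diags(1.0 / c.diagonal())
    q = tau2 * (kappa**4 * c + 2.0 * kappa**2 * g + g @ cinv @ g)
    q = ((q + q.T) * 0.5).tocsc()
    return FieldPrecision(q=q, range_km=range_km, sigma=sigma)


def _ar1_precision(rho: float, n: int) -> sp.csc_matrix:
    """Unit-marginal-variance AR1 precision (stationary scaling)."""
    main = np.full(n, 1.0 + rho**2)
    main[0] = 1.0
    main[-1] = 1.0
    off = np.full(n - 1, -rho)
    q = sp.diags([off, main, off], [-1, 0, 1]) / (1.0 - rho**2)
    return q.tocsc()


def _rw_precision(n: int) -> sp.csc_matrix:
    """First-difference precision with a proper (unit) first-year block."""
    d = sp.diags([np.full(n - 1, -1.0), np.ones(n - 1)], [0, 1], shape=(n - 1, n))
    q = d.T @ d + sp.coo_matrix(([1.0], ([0], [0])), shape=(n, n))
    return q.tocsc()


def spacetime_precision(
    q_spatial: FieldPrecision, structure: str, rho: float | None, n_years: int
) -> FieldPrecision:
    """Kronecker space-time precision over vertices x years.

    AR1 uses the stationary-scaled tridiagonal AR1 precision (constant
    marginal variance each year); iid is block-diagonal; RW is the
    first-difference precision with the first year anchored at the
    stationary spatial distribution to keep the density proper.
    """
    if structure not in VALID_STRUCTURES:
        raise ValueError(f"structure must be one of {VALID_STRUCTURES}, got {structure!r}")
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    qs = q_spatial.q
    if structure == "AR1":
        if rho is None or not abs(rho) < 1:
            raise ValueError(f"AR1 requires |rho| < 1, got {rho}")
        qt = _ar1_precision(rho, n_years)
    elif structure == "RW":
        qt = _rw_precision(n_years)
    else:
        qt = sp.eye(n_years, format="csc")
    q = sp.kron(qt, qs, format="csc")
    return FieldPrecision(
        q=q,
        range_km=q_spatial.range_km,
        sigma=q_spatial.sigma,
        structure=structure,
        rho=rho if structure == "AR1" else None,
        n_years=n_years,
    )


# ---------------------------------------------------------------------------
# sparse SPD helpers


def splu_factor(q: sp.spmatrix) -> spla.SuperLU:
    """Sparse LU of an SPD matrix.

    Symmetric mode without diagonal pivoting is Cholesky-like and markedly
    faster on these precisions; fall back to the default (pivoted) path if
    a zero pivot is hit.
    """
    q = sp.csc_matrix(q)
    try:
        return spla.splu(
            q,
            permc_spec="MMD_AT_PLUS_A",
            diag_pivot_thresh=0.0,
            options={"SymmetricMode": True},
        )
    except RuntimeError:
        return spla.splu(q)


def logdet_spd(q: sp.spmatrix, factor: spla.SuperLU | None = None) -> float:
    """log-determinant of a sparse SPD matrix via sparse LU."""
    lu = factor if factor is not None else splu_factor(q)
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def sample_gmrf(
    q: sp.spmatrix, rng: np.random.Generator, n_draws: int = 1, mean: np.ndarray | None = None
) -> np.ndarray:
    """Draw from N(mean, Q^{-1}) via dense Cholesky of the precision.

    Returns an (n_draws, dim) array.  Dense factorization is deliberate:
    the latent dimensions used in this package (<= a few thousand) make it
    both simple and fast; huge meshes are out of scope.
    """
    qd = np.asarray(sp.csc_matrix(q).todense())
    chol = np.linalg.cholesky(qd)  # Q = L L'
    z = rng.standard_normal((qd.shape[0], n_draws))
    # x = L^-T z has covariance Q^-1
    from scipy.linalg import solve_triangular

    x = solve_triangular(chol.T, z, lower=False)
    out = x.T
    if mean is not None:
        out = out + np.asarray(mean)[None, :]
    return out


def matern_nu1_correlation(dist: np.ndarray, range_km: float) -> np.ndarray:
    """Closed-form Matern nu=1 correlation, r(h) = kappa h K1(kappa h)."""
    from scipy.special import kv

    dist = np.asarray(dist, dtype=float)
    kappa = np.sqrt(8.0) / range_km
    x = kappa * dist
    out = np.ones_like(x)
    pos = x > 0
    out[pos] = x[pos] * kv(1, x[pos])
    return out
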