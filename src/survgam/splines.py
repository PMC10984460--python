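"""Penalized B-spline (P-spline) smoothers in mixed-model form.

Classic P-splines: a cubic B-spline basis on equally spaced knots spanning
the covariate range (extended beyond it, unclamped) with a second-order
difference penalty on the coefficients.  Because the knots are uniform, the
penalty null space corresponds exactly to {constant, linear-in-x}, so the
basis splits cleanly into (i) an unpenalized linear column (the constant is
absorbed by the model intercept) and (ii) penalized columns whose
coefficients are iid Gaussian with a smoothing variance estimated as a
hyperparameter.  The reparameterization spans the same function space as
the raw basis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline


class DegenerateCovariateError(ValueError):
    pass


@dataclass
class SplineBasis:
    """Cubic P-spline basis for one covariate, mixed-model parameterization.

    Attributes
    ----------
    name : str
        Covariate name.
    knots : ndarray
        Full (extended) uniform knot vector.
    penalty : (k, k) ndarray
        Second-order difference penalty on raw B-spline coefficients.
    x_lin : (n,) ndarray
        Scaled linear column at the data (exactly linear in the covariate).
    z_pen : (n, k-2) ndarray
        Penalized columns at the data (iid-Gaussian coefficients).
    """

    name: str
    knots: np.ndarray
    penalty: np.ndarray
    x_lin: np.ndarray
    z_pen: np.ndarray
    lin_coef: np.ndarray
    u_pen: np.ndarray
    lin_scale: float
    lo: float
    hi: float

    @property
    def n_pen(self) -> int:
        return self.z_pen.shape[1]

    @property
    def n_basis(self) -> int:
        return len(self.knots) - 4

    def raw_basis(self, x: np.ndarray) -> np.ndarray:
        """Raw B-spline design matrix at new covariate values.

        Values outside the observed range are clamped (constant
        extrapolation) so predictions stay defined on grid cells whose
        covariates exceed the data range; such cells should be flagged by
        the caller.
        """
        x = np.clip(np.asarray(x, dtype=float).ravel(), self.lo, self.hi)
        k = self.n_basis
        design = np.empty((x.size, k))
        for j in range(k):
            coef = np.zeros(k)
            coef[j] = 1.0
            design[:, j] = BSpline(self.knots, coef, 3)(x)
        return design

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (linear column, penalized columns) at new values."""
        b = self.raw_basis(x)
        return (b @ self.lin_coef) / self.lin_scale, b @ self.u_pen


def build_spline(values: np.ndarray, n_knots: int = 8, name: str = "x") -> SplineBasis:
    """Build a cubic P-spline basis with ``n_knots`` equally spaced knots
    spanning the covariate range.

    The raw basis has ``n_knots + 2`` functions; two unpenalized null-space
    directions (constant, linear) plus ``n_knots`` penalized columns.
    """
    x = np.asarray(values, dtype=float)
    if n_knots < 4:
        raise ValueError("n_knots must be >= 4")
    uniq = np.unique(x)
    if uniq.size < n_knots:
        raise DegenerateCovariateError(
            f"covariate {name!r} has {uniq.size} distinct values; need >= {n_knots}"
        )
    lo, hi = float(x.min()), float(x.max())
    h = (hi - lo) / (n_knots - 1)
    if h <= 0:
        raise DegenerateCovariateError(f"covariate {name!r} is constant")
    knots = lo + h * np.arange(-3, n_knots + 3)
    k = n_knots + 2
    d = np.diff(np.eye(k), n=2, axis=0)
    pen = d.T @ d
    # uniform knots: the penalty null space {1, index} maps exactly to
    # {constant, linear in x} (Greville abscissae are uniform)
    idx = np.arange(k, dtype=float)
    lin_coef = idx - idx.mean()
    lin_coef /= np.linalg.norm(lin_coef)
    w, u = np.linalg.eigh(pen)
    pos = w > 1e-10
    u_pen = u[:, pos] / np.sqrt(w[pos])  # raw coefficients iid N(0, sigma_f^2)
    basis = SplineBasis(
        name=name,
        knots=knots,
        penalty=pen,
        x_lin=np.zeros(x.size),
        z_pen=np.zeros((x.size, int(pos.sum()))),
        lin_coef=lin_coef,
        u_pen=u_pen,
        lin_scale=1.0,
        lo=lo,
        hi=hi,
    )
    x_lin_raw = basis.raw_basis(x) @ lin_coef
    basis.lin_scale = float(np.std(x_lin_raw)) or 1.0
    basis.x_lin, basis.z_pen = basis.evaluate(x)
    return basis
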