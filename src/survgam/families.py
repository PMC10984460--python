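"""Observation families for the two-part model.

Each family exposes the negative log-likelihood and its first two
derivatives with respect to the linear predictor eta (link scale), which is
all the Laplace machinery needs.  The Gamma family is parameterized by its
mean mu = exp(eta) and shape phi, so that Var(Y) = mu^2 / phi.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, gammaln


class LinearPredictorOverflow(FloatingPointError):
    def __init__(self, rows):
        self.rows = list(rows)
        super().__init__(f"non-finite linear predictor at rows {self.rows[:10]}")


def _check_eta(eta: np.ndarray) -> None:
    bad = np.nonzero(~np.isfinite(eta))[0]
    if bad.size:
        raise LinearPredictorOverflow(bad)


class BernoulliLogit:
    """Occurrence sub-model: Z ~ Bernoulli(pi), logit link."""

    name = "bernoulli-logit"
    n_shape_params = 0

    @staticmethod
    def nll(y, eta, phi=None):
        _check_eta(eta)
        # log(1 + e^eta) - y*eta, computed stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta))

    @staticmethod
    def d1(y, eta, phi=None):
        return expit(eta) - y

    @staticmethod
    def d2(y, eta, phi=None):
        p = expit(eta)
        return np.maximum(p * (1.0 - p), 1e-12)

    @staticmethod
    def mean(eta, phi=None):
        return expit(eta)


class GammaLog:
    """Positive-biomass sub-model: Y ~ Gamma(mean mu, shape phi), log link.

    Density f(y) = (phi/mu)^phi y^(phi-1) exp(-phi y / mu) / Gamma(phi);
    phi = 1 recovers the exponential distribution with mean mu.
    """

    name = "gamma-log"
    n_shape_params = 1

    @staticmethod
    def nll(y, eta, phi):
        _check_eta(eta)
        if phi <= 0:
            raise ValueError(f"Gamma shape must be > 0, got {phi}")
        with np.errstate(over="ignore"):  # inf nll is handled by line search
            mu_inv_y = y * np.exp(-eta)
        ll = (
            phi * (np.log(phi) - eta)
            + (phi - 1.0) * np.log(y)
            - phi * mu_inv_y
            - gammaln(phi)
        )
        return float(-np.sum(ll))

    @staticmethod
    def d1(y, eta, phi):
        return phi * (1.0 - y * np.exp(-eta))

    @staticmethod
    def d2(y, eta, phi):
        return np.maximum(phi * y * np.exp(-eta), 1e-12)

    @staticmethod
    def mean(eta, phi=None):
        return np.exp(eta)


class GaussianIdentity:
    """Gaussian test family (identity link, unit error variance).

    Used only to validate the Laplace approximation against the exact
    closed-form Gaussian marginal likelihood; not part of the delta model.
    """

    name = "gaussian"
    n_shape_params = 0

    @staticmethod
    def nll(y, eta, phi=None):
        _check_eta(eta)
        r = y - eta
        return float(0.5 * np.sum(r * r) + 0.5 * y.size * np.log(2.0 * np.pi))

    @staticmethod
    def d1(y, eta, phi=None):
        return eta - y

    @staticmethod
    def d2(y, eta, phi=None):
        return np.ones_like(np.asarray(eta, dtype=float))

    @staticmethod
    def mean(eta, phi=None):
        return np.asarray(eta, dtype=float)


FAMILIES = {f.name: f for f in (BernoulliLogit, GammaLog, GaussianIdentity)}
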