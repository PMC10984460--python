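"""Covariate screening, information-criterion comparison, k-fold
cross-validated predictive density, and residual validation."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gamma as gamma_dist, norm, spearmanr

from .data import SurveyDataset
from .model import (
    DeltaGammaModel,
    DeltaGammaResults,
    DeltaModelSpec,
    FitOptions,
)

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# collinearity screening


@dataclass
class ScreenResult:
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    threshold: float
    passed: bool

    @property
    def max_offdiag(self) -> float:
        m = np.maximum(np.abs(self.pearson.to_numpy()), np.abs(self.spearman.to_numpy()))
        np.fill_diagonal(m, 0.0)
        return float(m.max()) if m.size else 0.0


def pearson_screen(table: pd.DataFrame, threshold: float = 0.6) -> ScreenResult:
    """Pairwise correlation screen against |R| < threshold.

    Both Pearson and Spearman matrices are computed and the screen uses the
    larger magnitude of the two (conservative reading of a "Pearson's rank
    correlation" screen).
    """
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 covariates and >= 3 rows")
    stds = table.std(ddof=0)
    const = stds.index[stds == 0].tolist()
    if const:
        raise UndefinedCorrelationError(f"constant column(s): {const}")
    pear = table.corr(method="pearson")
    spear = table.corr(method="spearman")
    res = ScreenResult(pearson=pear, spearman=spear, threshold=threshold, passed=True)
    res.passed = res.max_offdiag < threshold
    return res


def vif(table: pd.DataFrame) -> pd.Series:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    covariate j on the others (with intercept).  Perfect collinearity is
    reported as ``inf`` rather than raised."""
    if table.shape[1] < 2 or table.shape[0] < 3:
        raise ValueError("need >= 2 covariates and >= 3 rows")
    out = {}
    x = table.to_numpy(dtype=float)
    n, p = x.shape
    for j in range(p):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            logger.warning("covariate %r is perfectly collinear (VIF = inf)", table.columns[j])
            out[table.columns[j]] = np.inf
        else:
            out[table.columns[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


# ---------------------------------------------------------------------------
# AIC weights


@dataclass
class ModelComparison:
    """Table-2-style comparison: AIC/weights, optionally ELPD.

    Sign conventions (documented rather than reverse-engineered): the best
    model has delta = 0; worse models have negative delta_aic
    (AIC_best - AIC_m) and negative delta_elpd (ELPD_m - ELPD_best, larger
    ELPD better).
    """

    table: pd.DataFrame

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def aic_and_weights(fits: list[DeltaGammaResults], labels: list[str] | None = None) -> ModelComparison:
    """Akaike weights over candidate fits (AIC = 2 nll + 2 df).

    Non-converged fits are excluded with a logged warning.
    """
    rows = []
    for i, fit in enumerate(fits):
        label = labels[i] if labels else fit.spec.label
        if not fit.converged:
            logger.warning("excluding non-converged fit %r from AIC comparison", label)
            continue
        rows.append({"label": label, "df": fit.df, "nll": fit.marginal_nll, "aic": fit.aic})
    if not rows:
        raise ValueError("no converged fits to compare")
    df = pd.DataFrame(rows)
    best = df["aic"].min()
    df["delta_aic"] = best - df["aic"]
    rel = np.exp(-0.5 * (df["aic"] - best))
    df["weight"] = rel / rel.sum()
    return ModelComparison(table=df.sort_values("aic").reset_index(drop=True))


def attach_elpd(comparison: ModelComparison, elpds: dict[str, float]) -> ModelComparison:
    """Add ELPD and delta-ELPD columns to an AIC comparison table."""
    df = comparison.table.copy()
    df["elpd"] = df["label"].map(elpds)
    best = df["elpd"].max()
    df["delta_elpd"] = df["elpd"] - best
    return ModelComparison(table=df)


# ---------------------------------------------------------------------------
# k-fold cross-validation


@dataclass
class CvResult:
    k: int
    seed: int
    fold_of_row: np.ndarray
    fold_elpd: list[float]
    elpd: float
    n_scored: int
    skipped_folds: list[int] = field(default_factory=list)


def _held_out_lpd(fit: DeltaGammaResults, held: pd.DataFrame) -> np.ndarray:
    """Log predictive density of held-out tows under the delta model at
    plug-in estimates (latent fields at their predictive modes)."""
    offset = np.log(held["swept_km2"].to_numpy(dtype=float))
    eta_occ = fit.occurrence.linear_predictor(held, offset)
    pi = np.clip(expit(eta_occ), 1e-12, 1.0 - 1e-12)
    y = held["biomass_kg"].to_numpy(dtype=float)
    lpd = np.where(y <= 0, np.log1p(-pi), 0.0)
    posmask = y > 0
    if posmask.any():
        eta_pos = fit.positive.linear_predictor(held[posmask], offset[posmask])
        mu = np.exp(eta_pos)
        phi = fit.positive.hypers["phi"]
        gpdf = gamma_dist.logpdf(y[posmask], a=phi, scale=mu / phi)
        lpd[posmask] = np.log(pi[posmask]) + gpdf
    return lpd


def kfold_elpd(
    dataset: SurveyDataset,
    spec: DeltaModelSpec,
    k: int = 4,
    seed: int = 0,
    mesh_cutoff_km: float = 20.0,
    options: FitOptions | None = None,
    start: DeltaGammaResults | None = None,
) -> CvResult:
    """k-fold expected log pointwise predictive density (sum over tows).

    Rows are randomly partitioned into k folds of near-equal size; each fold
    is scored under the model fitted to the remaining folds.  Folds whose
    training data lack enough positive tows are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    n = dataset.n
    rng = np.random.default_rng(seed)
    fold = np.tile(np.arange(k), int(np.ceil(n / k)))[:n]
    rng.shuffle(fold)
    opts = options or FitOptions(compute_se="none")
    if opts.compute_se != "none":
        opts = FitOptions(**{**opts.__dict__, "compute_se": "none"})
    fold_scores: list[float] = []
    skipped: list[int] = []
    n_scored = 0
    for f in range(k):
        train = dataset.subset(fold != f)
        held = dataset.tows[fold == f]
        train_years = set(train.tows["year"].unique())
        scoreable = held[held["year"].isin(train_years)]
        if len(scoreable) < len(held):
            logger.warning(
                "fold %d: dropping %d held-out tows from years absent in training",
                f,
                len(held) - len(scoreable),
            )
        try:
            model = DeltaGammaModel(train, spec, mesh_cutoff_km=mesh_cutoff_km)
            fit = model.fit(seed=seed, options=opts, start=start)
        except Exception as exc:  # insufficient positives, non-convergence
            logger.warning("fold %d skipped: %s", f, exc)
            skipped.append(f)
            continue
        lpd = _held_out_lpd(fit, scoreable)
        fold_scores.append(float(np.sum(lpd)))
        n_scored += len(scoreable)
    return CvResult(
        k=k,
        seed=seed,
        fold_of_row=fold,
        fold_elpd=fold_scores,
        elpd=float(np.sum(fold_scores)),
        n_scored=n_scored,
        skipped_folds=skipped,
    )


# ---------------------------------------------------------------------------
# randomized quantile residuals and spatial check


def quantile_residuals(fit: DeltaGammaResults, dataset: SurveyDataset, seed: int = 0) -> pd.DataFrame:
    """Randomized quantile residuals for the delta model.

    Zeros get a uniform draw on (0, 1 - pi); positives map through
    (1 - pi) + pi * GammaCDF(y).  If the model is correct the residuals are
    standard normal and spatially unstructured.
    """
    rng = np.random.default_rng(seed)
    tows = dataset.tows
    offset = np.log(tows["swept_km2"].to_numpy(dtype=float))
    pi = np.clip(expit(fit.occurrence.linear_predictor(tows, offset)), 1e-10, 1 - 1e-10)
    y = tows["biomass_kg"].to_numpy(dtype=float)
    v = np.empty(len(tows))
    zero = y <= 0
    v[zero] = rng.uniform(0.0, 1.0 - pi[zero])
    if (~zero).any():
        eta_pos = fit.positive.linear_predictor(tows[~zero], offset[~zero])
        mu = np.exp(eta_pos)
        phi = fit.positive.hypers["phi"]
        cdf = gamma_dist.cdf(y[~zero], a=phi, scale=mu / phi)
        v[~zero] = (1.0 - pi[~zero]) + pi[~zero] * cdf
    v = np.clip(v, 1e-10, 1 - 1e-10)
    return pd.DataFrame(
        {
            "tow_id": tows["tow_id"],
            "x": tows["x"],
            "y": tows["y"],
            "year": tows["year"],
            "residual": norm.ppf(v),
        }
    )


def moran_statistic(values: np.ndarray, coords: np.ndarray, n_neighbors: int = 8) -> dict:
    """Moran's I with k-nearest-neighbour weights, plus its null moments.

    Under no spatial autocorrelation E[I] = -1/(n-1); the z-score uses the
    randomization variance approximation via permutation-free moments.
    """
    from scipy.spatial import cKDTree

    values = np.asarray(values, dtype=float)
    n = values.size
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=n_neighbors + 1)
    rows = np.repeat(np.arange(n), n_neighbors)
    cols = idx[:, 1:].ravel()
    w = np.ones(rows.size)
    zc = values - values.mean()
    s0 = w.sum()
    num = np.sum(w * zc[rows] * zc[cols])
    den = np.sum(zc**2)
    i_obs = (n / s0) * (num / den)
    e_i = -1.0 / (n - 1)
    return {"I": float(i_obs), "expected": float(e_i), "n": n}
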