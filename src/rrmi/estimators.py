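"""Analysis models and pooling: log binomial, modified Poisson, Rubin's rules.

The analysis model is always ``log P(Y=1) = b0 + b1*X1 + b2*X2``. Binary
exposure scenarios are analysed with the log binomial model, falling
back to modified Poisson regression (Poisson working model, HC0 robust
variance) when the log binomial fit fails to converge; continuous
exposure scenarios use modified Poisson throughout, since log binomial
non-convergence is endemic with unbounded covariates. Multiply-imputed
analyses are combined with Rubin's rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, t as t_dist

from . import _glm
from ._glm import FitError
from .datagen import SimDataset
from .fcs import ImputationSet

LOG_BINOMIAL = "log_binomial"
MODIFIED_POISSON = "modified_poisson"


@dataclass
class FitResult:
    """A single-dataset fit of the three-parameter analysis model."""

    estimates: np.ndarray  # (intercept, b1, b2)
    std_errors: np.ndarray
    converged: bool
    estimator: str
    n_used: int

    def ci(self, confidence: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = norm.ppf(0.5 + confidence / 2.0)
        return self.estimates - z * self.std_errors, self.estimates + z * self.std_errors


@dataclass
class PooledResult:
    """Rubin's-rules combination of m single-dataset fits."""

    estimates: np.ndarray
    total_variance: np.ndarray
    dof: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    m_used: int

    @property
    def std_errors(self) -> np.ndarray:
        return np.sqrt(self.total_variance)


def _design(data: SimDataset, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    if rows is None:
        rows = np.ones(data.n, dtype=bool)
    X = np.column_stack(
        [np.ones(int(rows.sum())), data.x1[rows].astype(float), data.x2[rows].astype(float)]
    )
    return X, data.y[rows].astype(float)


def _require_complete(data: SimDataset) -> None:
    if data.miss_y.any() or data.miss_x2.any():
        raise ValueError("analysis model requires a complete dataset")


def fit_log_binomial(data: SimDataset) -> FitResult:
    """Fit the log binomial model; ``converged=False`` flags boundary/failed fits."""
    _require_complete(data)
    X, y = _design(data)
    beta, cov, converged = _glm.fit_log_binomial_irls(X, y)
    return FitResult(beta, np.sqrt(np.diag(cov)), converged, LOG_BINOMIAL, data.n)


def fit_modified_poisson(data: SimDataset) -> FitResult:
    """Fit modified Poisson regression (log link, HC0 sandwich variance)."""
    _require_complete(data)
    X, y = _design(data)
    beta, cov, converged = _glm.fit_poisson_hc0(X, y)
    return FitResult(beta, np.sqrt(np.diag(cov)), converged, MODIFIED_POISSON, data.n)


def choose_analysis(
    data: SimDataset, exposure_type: str, fit_lb: FitResult | None = None
) -> FitResult:
    """Route one completed dataset to the appropriate analysis model.

    Binary exposures: the log binomial fit (reusing ``fit_lb`` when
    supplied), with per-dataset fallback to modified Poisson on
    non-convergence. Continuous exposures: always modified Poisson.
    """
    if exposure_type == "continuous":
        return fit_modified_poisson(data)
    if fit_lb is None:
        try:
            fit_lb = fit_log_binomial(data)
        except FitError:
            fit_lb = None
    if fit_lb is not None and fit_lb.converged:
        return fit_lb
    return fit_modified_poisson(data)


def delete_imputed_outcomes(imp: ImputationSet) -> ImputationSet:
    """MID: drop rows whose outcome was imputed from every completed dataset.

    Rows retained keep any imputed covariate values; only outcome
    imputation triggers deletion.
    """
    keep = ~imp.imputed_y_mask
    if not keep.any():
        raise ValueError("deleting imputed outcomes would remove every row")
    completed = []
    for ds in imp.completed:
        completed.append(
            SimDataset(
                ds.y[keep].copy(),
                ds.x1[keep].copy(),
                ds.x2[keep].copy(),
                np.zeros(int(keep.sum()), dtype=bool),
                np.zeros(int(keep.sum()), dtype=bool),
            )
        )
    return ImputationSet(
        completed=completed,
        imputed_y_mask=np.zeros(int(keep.sum()), dtype=bool),
        method_label=imp.method_label + "+deletion",
    )


def pool_rubin(
    fits: list[FitResult],
    confidence: float = 0.95,
    small_sample_dof: bool = False,
    complete_dof: float | None = None,
) -> PooledResult:
    """Combine m fits with Rubin's rules.

    Pooled estimate = mean of estimates; within-variance ``W`` = mean
    squared SE; between-variance ``B`` = sample variance of estimates;
    total ``T = W + (1 + 1/m) B``; degrees of freedom
    ``(m-1)(1 + W/((1+1/m)B))^2`` (infinite when B = 0). With
    ``small_sample_dof`` the Barnard-Rubin adjustment combines this with
    the observed-data degrees of freedom ``complete_dof``.
    """
    m = len(fits)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 fits")
    est = np.array([f.estimates for f in fits])
    se = np.array([f.std_errors for f in fits])
    qbar = est.mean(axis=0)
    W = (se**2).mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore"):
        r = (1.0 + 1.0 / m) * B / W
        dof = np.where(B > 0.0, (m - 1) * (1.0 + 1.0 / np.where(r > 0, r, np.inf)) ** 2, np.inf)
    if small_sample_dof:
        if complete_dof is None:
            raise ValueError("small_sample_dof requires complete_dof")
        gamma = np.where(T > 0, (1.0 + 1.0 / m) * B / T, 0.0)
        nu_obs = (complete_dof + 1.0) / (complete_dof + 3.0) * complete_dof * (1.0 - gamma)
        dof = 1.0 / (1.0 / dof + 1.0 / nu_obs)
    alpha = 1.0 - confidence
    q = np.where(np.isinf(dof), norm.ppf(1.0 - alpha / 2.0), t_dist.ppf(1.0 - alpha / 2.0, np.where(np.isinf(dof), 1.0, dof)))
    half = q * np.sqrt(T)
    return PooledResult(qbar, T, dof, qbar - half, qbar + half, m)


def cca_fit(data: SimDataset, exposure_type: str, min_rows: int = 10) -> FitResult:
    """Complete case analysis: restrict to rows with both Y and X2 observed."""
    keep = data.complete_rows
    if int(keep.sum()) < min_rows:
        raise FitError(f"only {int(keep.sum())} complete rows: CCA infeasible")
    sub = SimDataset(
        data.y[keep].copy(),
        data.x1[keep].copy(),
        data.x2[keep].copy(),
        np.zeros(int(keep.sum()), dtype=bool),
        np.zeros(int(keep.sum()), dtype=bool),
    )
    return choose_analysis(sub, exposure_type)
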