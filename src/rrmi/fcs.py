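"""Fully conditional specification (chained equations) imputation.

Missing Y is imputed from a logistic regression on (X1, X2); missing X2
from a logistic regression on (Y, X1) when binary, or a Bayesian linear
regression when continuous. Each of the m imputations runs its own
chain: missing cells are first filled with random draws from the
observed margin, then a fixed number of sweeps re-imputes each
incomplete variable in turn from the current completed data, drawing
model parameters from (an approximation to) their posterior so that
imputations are proper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._glm import FitError, fit_logistic
from .config import ScenarioSpec
from .datagen import SimDataset

_RIDGE_RETRY = 1e-4


class ImputationFailure(RuntimeError):
    """A replicate's imputation could not be completed (caller flags it)."""


@dataclass
class ImputationSet:
    """m completed copies of one dataset plus the record of imputed outcomes."""

    completed: list[SimDataset]
    imputed_y_mask: np.ndarray
    method_label: str

    @property
    def m(self) -> int:
        return len(self.completed)


def _draw_coefficients(beta: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # multivariate normal draw via cholesky; cov is tiny (<=3x3)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    return beta + L @ rng.standard_normal(len(beta))


def draw_logistic_imputation(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Posterior-draw logistic imputation of a binary variable.

    Fits the logistic MLE on observed rows, draws a coefficient vector
    from the asymptotic normal posterior (MLE mean, inverse observed
    information covariance), and imputes each missing row as
    Bernoulli(expit(x . theta*)). On separation, one retry with a small
    ridge on the information; persistent failure raises
    :class:`ImputationFailure`.
    """
    if X_mis.shape[0] == 0:
        return np.empty(0)
    try:
        beta, cov, _ = fit_logistic(X_obs, y_obs)
    except FitError:
        try:
            beta, cov, _ = fit_logistic(X_obs, y_obs, ridge=_RIDGE_RETRY)
        except FitError as exc:
            raise ImputationFailure("logistic imputation model failed") from exc
    theta = _draw_coefficients(beta, cov, rng)
    p = expit(X_mis @ theta)
    return (rng.random(X_mis.shape[0]) < p).astype(float)


def draw_linear_imputation(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bayesian linear-regression imputation of a continuous variable.

    Under the Jeffreys prior (flat on coefficients, 1/sigma^2 on the
    variance): sigma^2 is drawn from RSS/chi2(n-p), coefficients from
    N(beta_hat, sigma*^2 (X'X)^-1), and missing rows are imputed as
    x . theta* + sigma* eps with standard-normal eps.
    """
    if X_mis.shape[0] == 0:
        return np.empty(0)
    n, p = X_obs.shape
    if n < p + 2:
        raise ImputationFailure(f"linear imputation needs >= {p + 2} observed rows")
    xtx = X_obs.T @ X_obs
    try:
        L = np.linalg.cholesky(xtx)
    except np.linalg.LinAlgError as exc:
        raise ImputationFailure("singular design in linear imputation") from exc
    beta_hat = np.linalg.solve(L.T, np.linalg.solve(L, X_obs.T @ y_obs))
    resid = y_obs - X_obs @ beta_hat
    rss = float(resid @ resid)
    df = n - p
    sigma2 = rss / rng.chisquare(df) if rss > 0.0 else 0.0
    xtx_inv = np.linalg.inv(L).T @ np.linalg.inv(L)
    if sigma2 > 0.0:
        Lc = np.linalg.cholesky(sigma2 * xtx_inv + 1e-14 * np.eye(p))
        theta = beta_hat + Lc @ rng.standard_normal(p)
    else:
        theta = beta_hat
    return X_mis @ theta + np.sqrt(sigma2) * rng.standard_normal(X_mis.shape[0])


def _impute_x2(y, x1, x2, miss_x2, binary: bool, rng) -> np.ndarray:
    obs = ~miss_x2
    X_obs = np.column_stack([np.ones(int(obs.sum())), y[obs], x1[obs]])
    X_mis = np.column_stack([np.ones(int(miss_x2.sum())), y[miss_x2], x1[miss_x2]])
    if binary:
        return draw_logistic_imputation(X_obs, x2[obs], X_mis, rng)
    return draw_linear_imputation(X_obs, x2[obs], X_mis, rng)


def _impute_y(y, x1, x2, miss_y, rng) -> np.ndarray:
    obs = ~miss_y
    X_obs = np.column_stack([np.ones(int(obs.sum())), x1[obs], x2[obs]])
    X_mis = np.column_stack([np.ones(int(miss_y.sum())), x1[miss_y], x2[miss_y]])
    return draw_logistic_imputation(X_obs, y[obs], X_mis, rng)


def fcs_impute(
    data: SimDataset,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    order: str = "outcome_last",
    max_retries: int = 3,
) -> ImputationSet:
    """Produce m completed datasets by chained-equations imputation.

    Each chain starts from a random fill (sampling with replacement
    from the observed margin of the same variable) and runs
    ``spec.cycles`` sweeps. With ``order="outcome_last"`` (default) a
    sweep re-imputes X2 from (Y, X1) and then Y from (X1, X2);
    ``order="outcome_first"`` swaps the two. A chain whose model fit
    fails is restarted up to ``max_retries`` times before the replicate
    is abandoned with :class:`ImputationFailure`.
    """
    if order not in ("outcome_last", "outcome_first"):
        raise ValueError("order must be 'outcome_last' or 'outcome_first'")
    miss_y, miss_x2 = data.miss_y, data.miss_x2
    y_obs_pool = data.y[~miss_y]
    x2_obs_pool = data.x2[~miss_x2]
    if miss_y.any() and y_obs_pool.size == 0:
        raise ImputationFailure("no observed outcomes to start from")
    if miss_x2.any() and x2_obs_pool.size == 0:
        raise ImputationFailure("no observed X2 values to start from")
    binary_x2 = spec.exposure_type == "binary"

    completed: list[SimDataset] = []
    for _chain in range(spec.m):
        for attempt in range(max_retries + 1):
            y = data.y.copy()
            x2 = data.x2.copy()
            if miss_y.any():
                y[miss_y] = rng.choice(y_obs_pool, size=int(miss_y.sum()), replace=True)
            if miss_x2.any():
                x2[miss_x2] = rng.choice(x2_obs_pool, size=int(miss_x2.sum()), replace=True)
            try:
                for _cycle in range(spec.cycles):
                    if order == "outcome_first":
                        if miss_y.any():
                            y[miss_y] = _impute_y(y, data.x1, x2, miss_y, rng)
                        if miss_x2.any():
                            x2[miss_x2] = _impute_x2(y, data.x1, x2, miss_x2, binary_x2, rng)
                    else:
                        if miss_x2.any():
                            x2[miss_x2] = _impute_x2(y, data.x1, x2, miss_x2, binary_x2, rng)
                        if miss_y.any():
                            y[miss_y] = _impute_y(y, data.x1, x2, miss_y, rng)
                break
            except ImputationFailure:
                if attempt == max_retries:
                    raise
        completed.append(
            SimDataset(
                y,
                data.x1.copy(),
                x2,
                np.zeros(data.n, dtype=bool),
                np.zeros(data.n, dtype=bool),
            )
        )
    return ImputationSet(completed=completed, imputed_y_mask=miss_y.copy(), method_label="FCS")
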