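"""Small dense GLM fitting kernels used throughout the package.

Hand-rolled Newton/Fisher-scoring fits for the three models the
pipeline needs at volume (hundreds of thousands of three-column fits):
logistic regression, the log binomial model with step-halving to keep
fitted probabilities below one, and Poisson regression with an HC0
sandwich covariance. Designs are tiny (n x 3), so everything is plain
numpy with explicit solves.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

_EPS = 1e-10


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (separation, singularity, ...)."""


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    return np.linalg.solve(c.T, np.linalg.solve(c, b))


def _inv_spd(A: np.ndarray) -> np.ndarray:
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise FitError("singular information matrix") from exc
    ic = np.linalg.inv(c)
    return ic.T @ ic


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Logistic MLE by Newton-Raphson.

    Returns ``(beta, cov, converged)`` with ``cov`` the inverse observed
    information (plus any ridge). A ridge > 0 stabilises separated data.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if 0.0 < ybar < 1.0:
        beta[0] = np.log(ybar / (1.0 - ybar))
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        info = (X.T * w) @ X
        if ridge > 0.0:
            info = info + ridge * np.eye(p)
        score = X.T @ (y - mu) - (ridge * beta if ridge > 0.0 else 0.0)
        try:
            step = _solve_spd(info, score)
        except FitError:
            if ridge == 0.0:
                raise
            raise FitError("singular information despite ridge")
        beta = beta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 50.0:
        raise FitError("logistic fit diverged (likely separation)")
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    info = (X.T * w) @ X
    if ridge > 0.0:
        info = info + ridge * np.eye(p)
    return beta, _inv_spd(info), converged


def _binomial_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    mu = np.exp(eta)
    mu = np.clip(mu, _EPS, 1.0 - _EPS)
    return float(y @ np.log(mu) + (1.0 - y) @ np.log1p(-mu))


def fit_log_binomial_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
    boundary_tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Log binomial (binomial family, log link) fit by Fisher scoring.

    Starts at intercept ``log(mean y)``, slopes 0. Steps are halved
    until all fitted probabilities stay strictly below one and the
    log-likelihood does not decrease. Convergence requires the relative
    deviance change below ``tol`` within ``max_iter`` iterations with
    every fitted probability at most ``1 - boundary_tol``; otherwise
    ``converged`` is False (estimates retained for fallback logic).

    Returns ``(beta, cov, converged)``; ``cov`` is the inverse expected
    information at the final iterate.
    """
    n, p = X.shape
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        raise FitError("outcome is constant: log binomial MLE undefined")
    beta = np.zeros(p)
    beta[0] = np.log(ybar)
    eta = X @ beta
    if eta.max() >= 0.0:
        # shift the start strictly inside the valid region
        beta[0] -= eta.max() + 1e-3
        eta = X @ beta
    ll = _binomial_loglik(y, eta)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(eta)
        mu_c = np.minimum(mu, 1.0 - _EPS)
        w = mu_c / (1.0 - mu_c)  # expected information weight for log link
        score = X.T @ ((y - mu_c) / (1.0 - mu_c))
        info = (X.T * (w + _EPS)) @ X
        step = _solve_spd(info, score)
        scale = 1.0
        for _half in range(60):
            cand = beta + scale * step
            eta_c = X @ cand
            if eta_c.max() < -1e-12:
                ll_c = _binomial_loglik(y, eta_c)
                if ll_c >= ll - 1e-12:
                    break
            scale *= 0.5
        else:
            break  # stuck on the boundary
        rel = abs(ll_c - ll) / (abs(ll) + 1e-12)
        beta, eta, ll = cand, eta_c, ll_c
        if rel < tol:
            converged = True
            break
    mu = np.exp(X @ beta)
    if mu.max() > 1.0 - boundary_tol:
        converged = False
    mu_c = np.minimum(mu, 1.0 - _EPS)
    w = mu_c / (1.0 - mu_c)
    info = (X.T * w) @ X
    cov = _inv_spd(info)
    return beta, cov, converged


def fit_poisson_hc0(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Poisson (log link) MLE with HC0 sandwich covariance.

    The sandwich ``A^-1 B A^-1`` uses the Fisher information
    ``A = X' diag(mu) X`` and the outer-product-of-scores
    ``B = X' diag((y - mu)^2) X``, correcting the Poisson variance
    misspecification when ``y`` is binary (modified Poisson regression).
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0.0:
        raise FitError("outcome has no events: Poisson MLE undefined")
    beta[0] = np.log(ybar)
    converged = False
    for _ in range(max_iter):
        mu = np.exp(X @ beta)
        info = (X.T * mu) @ X
        score = X.T @ (y - mu)
        step = _solve_spd(info, score)
        beta = beta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    mu = np.exp(X @ beta)
    A_inv = _inv_spd((X.T * mu) @ X)
    r2 = (y - mu) ** 2
    B = (X.T * r2) @ X
    cov = A_inv @ B @ A_inv
    return beta, cov, converged
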