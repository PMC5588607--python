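"""Multivariate normal imputation by data augmentation.

The three analysis variables (Y, X1, X2) are modelled jointly as
multivariate normal, binary variables entering as raw 0/1. Starting
values come from EM under ignorable missingness; imputations from the
data-augmentation chain, alternating an I-step (draw each row's missing
coordinates from their conditional normal) and a P-step (draw mean and
covariance from the normal-inverse-Wishart posterior under the Jeffreys
prior). The first imputation is taken after a burn-in, subsequent ones
at a fixed spacing. Continuous imputed values of binary variables are
converted to 0/1 by adaptive rounding (or simple rounding as a
sensitivity option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .config import ScenarioSpec
from .datagen import SimDataset
from .fcs import ImputationSet

_EM_TOL = 1e-8
_EM_MAX_ITER = 1000


@dataclass
class NormalParams:
    """Mean and covariance of the trivariate imputation model (Y, X1, X2)."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = 0.5 * (self.sigma + self.sigma.T)

    def is_pd(self) -> bool:
        return bool(np.all(np.linalg.eigvalsh(self.sigma) > 0.0))


def _data_matrix(data: SimDataset) -> tuple[np.ndarray, np.ndarray]:
    Z = np.column_stack([data.y, data.x1, data.x2]).astype(float)
    M = np.column_stack([data.miss_y, np.zeros(data.n, dtype=bool), data.miss_x2])
    return Z, M


def _patterns(M: np.ndarray):
    """Group rows by missingness pattern; yields (rows, obs_idx, mis_idx)."""
    keys = M @ (1 << np.arange(M.shape[1]))
    for key in np.unique(keys):
        rows = np.flatnonzero(keys == key)
        mis = np.flatnonzero(M[rows[0]])
        obs = np.flatnonzero(~M[rows[0]])
        yield rows, obs, mis


def em_start(data: SimDataset, max_iter: int = _EM_MAX_ITER, tol: float = _EM_TOL) -> NormalParams:
    """EM estimate of (mu, Sigma) under the multivariate normal model.

    Converged when successive observed-data log-likelihoods differ by
    less than ``tol``. A covariance that loses positive definiteness
    restarts the iteration with an inflated diagonal.
    """
    Z, M = _data_matrix(data)
    n, p = Z.shape
    for j in range(p):
        if int((~M[:, j]).sum()) < 2:
            raise ValueError("each variable must be observed at least twice")

    # start from available-case moments
    mu = np.array([Z[~M[:, j], j].mean() for j in range(p)])
    sigma = np.diag([max(Z[~M[:, j], j].var(), 1e-6) for j in range(p)])

    if not M.any():
        mu = Z.mean(axis=0)
        d = Z - mu
        return NormalParams(mu, d.T @ d / n)

    ll_prev = -np.inf
    inflate = 0.0
    it = 0
    while it < max_iter:
        it += 1
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        ok = True
        for rows, obs, mis in _patterns(M):
            Zr = Z[rows]
            if mis.size == 0:
                T1 += Zr.sum(axis=0)
                T2 += Zr.T @ Zr
                S_oo = sigma
                d = Zr - mu
                try:
                    c = np.linalg.cholesky(S_oo)
                except np.linalg.LinAlgError:
                    ok = False
                    break
                sol = np.linalg.solve(c, d.T)
                ll += -0.5 * (
                    len(rows) * (p * np.log(2 * np.pi) + 2 * np.log(np.diag(c)).sum())
                    + (sol**2).sum()
                )
                continue
            S_oo = sigma[np.ix_(obs, obs)]
            S_mo = sigma[np.ix_(mis, obs)]
            S_mm = sigma[np.ix_(mis, mis)]
            try:
                c = np.linalg.cholesky(S_oo)
            except np.linalg.LinAlgError:
                ok = False
                break
            d_obs = Zr[:, obs] - mu[obs]
            reg = np.linalg.solve(c.T, np.linalg.solve(c, S_mo.T)).T  # S_mo S_oo^-1
            cond_mean = mu[mis] + d_obs @ reg.T
            C = S_mm - reg @ S_mo.T
            Ez = np.empty((len(rows), p))
            Ez[:, obs] = Zr[:, obs]
            Ez[:, mis] = cond_mean
            T1 += Ez.sum(axis=0)
            T2 += Ez.T @ Ez
            T2[np.ix_(mis, mis)] += len(rows) * C
            sol = np.linalg.solve(c, d_obs.T)
            ll += -0.5 * (
                len(rows) * (obs.size * np.log(2 * np.pi) + 2 * np.log(np.diag(c)).sum())
                + (sol**2).sum()
            )
        if not ok:
            sigma = sigma + (10.0 ** max(inflate, 0.0)) * 1e-4 * np.eye(p)
            inflate += 1.0
            ll_prev = -np.inf
            continue
        mu = T1 / n
        sigma = T2 / n - np.outer(mu, mu)
        sigma = 0.5 * (sigma + sigma.T)
        if abs(ll - ll_prev) < tol:
            break
        ll_prev = ll
    return NormalParams(mu, sigma)


def _istep(
    Z: np.ndarray,
    patterns: list,
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Draw missing coordinates from their conditional normals, in place.

    ``patterns`` is the precomputed list of (row-index array, observed
    columns, missing columns) triples; row groups never change along
    the chain, only (mu, sigma) do.
    """
    for rows, obs, mis in patterns:
        if mis.size == 0:
            continue
        if obs.size == 0:
            L = np.linalg.cholesky(sigma)
            Z[rows[:, None], mis] = mu + rng.standard_normal((len(rows), mis.size)) @ L.T
            continue
        S_oo = sigma[np.ix_(obs, obs)]
        S_mo = sigma[np.ix_(mis, obs)]
        S_mm = sigma[np.ix_(mis, mis)]
        c = np.linalg.cholesky(S_oo)
        reg = np.linalg.solve(c.T, np.linalg.solve(c, S_mo.T)).T
        cond_mean = mu[mis] + (Z[rows[:, None], obs] - mu[obs]) @ reg.T
        C = S_mm - reg @ S_mo.T
        Lc = np.linalg.cholesky(0.5 * (C + C.T) + 1e-12 * np.eye(mis.size))
        Z[rows[:, None], mis] = cond_mean + rng.standard_normal((len(rows), mis.size)) @ Lc.T


def _invwishart_draw(S: np.ndarray, df: int, rng: np.random.Generator) -> np.ndarray:
    """Bartlett-decomposition draw from InverseWishart(df, S).

    If W ~ Wishart(df, S^-1) then W^-1 ~ IW(df, S); with S = LL' and a
    Bartlett factor A, W^-1 = (L A^-T)(L A^-T)'.
    """
    p = S.shape[0]
    L = np.linalg.cholesky(S)
    A = np.zeros((p, p))
    for i in range(p):
        A[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    T = L @ np.linalg.inv(A).T
    return T @ T.T


def _pstep(Z: np.ndarray, rng: np.random.Generator) -> NormalParams:
    """Draw (mu, Sigma) from the Jeffreys-prior posterior given completed data."""
    n, p = Z.shape
    if n <= p:
        raise ValueError("P-step needs n > number of variables")
    zbar = Z.mean(axis=0)
    d = Z - zbar
    S = d.T @ d
    sigma = _invwishart_draw(S, n - 1, rng)
    L = np.linalg.cholesky(sigma / n)
    mu = zbar + L @ rng.standard_normal(p)
    return NormalParams(mu, sigma)


def da_impute(
    data: SimDataset, spec: ScenarioSpec, rng: np.random.Generator
) -> ImputationSet:
    """Run the data-augmentation chain, returning continuous-valued imputations.

    The chain starts at the EM estimate, runs ``spec.burn_in``
    iterations before the first imputation and ``spec.between``
    iterations between subsequent ones. Originally-missing cells carry
    the continuous I-step draws; observed cells are untouched.
    """
    Z, M = _data_matrix(data)
    params = em_start(data)
    patterns = list(_patterns(M))
    completed: list[SimDataset] = []
    n_iters = [spec.burn_in] + [spec.between] * (spec.m - 1)
    for steps in n_iters:
        for _ in range(steps):
            _istep(Z, patterns, params.mu, params.sigma, rng)
            params = _pstep(Z, rng)
        completed.append(
            SimDataset(
                Z[:, 0].copy(),
                Z[:, 1].copy(),
                Z[:, 2].copy(),
                np.zeros(data.n, dtype=bool),
                np.zeros(data.n, dtype=bool),
            )
        )
    return ImputationSet(completed=completed, imputed_y_mask=data.miss_y.copy(), method_label="MVNI")


def adaptive_round(values: np.ndarray, completed_variable: np.ndarray) -> np.ndarray:
    """Adaptive rounding of continuous imputations of a binary variable.

    With ``w = mean(completed_variable)`` (observed 0/1 plus imputed
    reals of one dataset's column), the threshold is
    ``c = w - Phi^{-1}(w) * sqrt(w (1 - w))``; values at or above ``c``
    round to 1. A degenerate mean (outside (0,1)) yields a constant
    column.
    """
    w = float(np.mean(completed_variable))
    if w <= 0.0:
        return np.zeros(len(values))
    if w >= 1.0:
        return np.ones(len(values))
    c = w - norm.ppf(w) * np.sqrt(w * (1.0 - w))
    return (np.asarray(values) >= c).astype(float)


def simple_round(values: np.ndarray) -> np.ndarray:
    """Round to 1 at or above 0.5, else 0 (ties go up)."""
    return (np.asarray(values) >= 0.5).astype(float)


def mvni_impute(
    data: SimDataset,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    rounding: str = "adaptive",
) -> ImputationSet:
    """MVNI with rounding of binary variables, ready for analysis.

    Y is always rounded (it is binary by construction); X2 is rounded
    when the scenario's exposures are binary. Thresholds use each
    imputed dataset's own completed column.
    """
    if rounding not in ("adaptive", "simple"):
        raise ValueError("rounding must be 'adaptive' or 'simple'")
    imp = da_impute(data, spec, rng)
    round_x2 = spec.exposure_type == "binary"
    for ds in imp.completed:
        if data.miss_y.any():
            vals = ds.y[data.miss_y]
            ds.y[data.miss_y] = (
                adaptive_round(vals, ds.y) if rounding == "adaptive" else simple_round(vals)
            )
        if round_x2 and data.miss_x2.any():
            vals = ds.x2[data.miss_x2]
            ds.x2[data.miss_x2] = (
                adaptive_round(vals, ds.x2) if rounding == "adaptive" else simple_round(vals)
            )
    return imp
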