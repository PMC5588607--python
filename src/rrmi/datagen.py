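"""Data generation: log binomial outcome model, exposure laws, MAR missingness.

Complete datasets follow ``log P(Y=1 | X1, X2) = b0 + b1*X1 + b2*X2``.
Binary exposures each have marginal prevalence 0.50 and a confounding
association expressed as the risk ratio ``RR(X1, X2)``; continuous
exposures are bivariate normal with mean 0, common variance and a given
correlation. Because the log link does not bound probabilities,
exposure pairs yielding ``exp(eta) > 1`` are redrawn until valid, which
truncates the effective exposure law; the intercept calibration accounts
for that truncation. Missingness in Y and X2 is missing-at-random,
driven by the always-observed X1 through logistic models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .config import ScenarioSpec

_MAX_RESAMPLE_ATTEMPTS = 10_000
_PROB_EPS = 1e-12


class CalibrationError(RuntimeError):
    """Raised when no intercept satisfies the target prevalence."""


class ResamplingError(RuntimeError):
    """Raised when invalid-probability resampling fails to terminate."""


@dataclass
class SimDataset:
    """One simulated dataset: outcome, two exposures, missingness masks.

    Values in ``y``/``x2`` are retained even where the corresponding
    mask is set; consumers honouring the missingness must index through
    ``~miss_y`` / ``~miss_x2``. ``x1`` is always fully observed.
    """

    y: np.ndarray
    x1: np.ndarray
    x2: np.ndarray
    miss_y: np.ndarray
    miss_x2: np.ndarray
    first_invalid_frac: float | None = None

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.x1) == len(self.x2) == len(self.miss_y) == len(self.miss_x2) == n):
            raise ValueError("all columns and masks must share one length")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def complete_rows(self) -> np.ndarray:
        """Boolean mask of rows with both Y and X2 observed."""
        return ~(self.miss_y | self.miss_x2)

    def copy(self) -> "SimDataset":
        return SimDataset(
            self.y.copy(),
            self.x1.copy(),
            self.x2.copy(),
            self.miss_y.copy(),
            self.miss_x2.copy(),
            self.first_invalid_frac,
        )

    def to_frame(self) -> pd.DataFrame:
        """Observed-data view: masked cells become NaN."""
        y = self.y.astype(float).copy()
        x2 = self.x2.astype(float).copy()
        y[self.miss_y] = np.nan
        x2[self.miss_x2] = np.nan
        return pd.DataFrame({"y": y, "x1": self.x1.astype(float), "x2": x2})

    def to_csv(self, path) -> None:
        """Write observed data as CSV with empty fields for missing cells."""
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated intercepts with their achieved rates."""

    beta0: float
    alpha: float
    achieved_prevalence: float
    achieved_missing_prop: float


def binary_cell_probs(assoc: float) -> tuple[np.ndarray, np.ndarray]:
    """Joint law of binary (X1, X2) with marginals 0.50 and RR(X1,X2)=assoc.

    X2's conditional prevalences solve ``p1/p0 = assoc`` with
    ``(p0 + p1)/2 = 0.5``, i.e. ``p0 = 1/(1+assoc)``, ``p1 = assoc/(1+assoc)``,
    preserving the 0.50 marginal for X2.

    Returns
    -------
    cells : ndarray of shape (4, 2)
        The (x1, x2) values of the four cells.
    probs : ndarray of shape (4,)
        The corresponding joint probabilities.
    """
    p0 = 1.0 / (1.0 + assoc)
    p1 = assoc / (1.0 + assoc)
    cells = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
    probs = np.array([0.5 * (1 - p0), 0.5 * p0, 0.5 * (1 - p1), 0.5 * p1])
    return cells, probs


def _linpred_sd(spec: ScenarioSpec) -> float:
    """SD of s = b1*X1 + b2*X2 for bivariate-normal exposures."""
    v = spec.exposure_var * (
        spec.beta1**2 + spec.beta2**2 + 2.0 * spec.assoc * spec.beta1 * spec.beta2
    )
    return math.sqrt(max(v, 0.0))


def _trunc_prevalence(beta0: float, sd: float) -> float:
    # E[exp(b0+s) | s <= -b0] for s ~ N(0, sd^2): truncated-lognormal mean
    v = sd * sd
    denom = norm.cdf(-beta0 / sd)
    if denom <= 0.0:
        return math.inf
    return math.exp(beta0 + v / 2.0) * norm.cdf((-beta0 - v) / sd) / denom


def solve_beta0(spec: ScenarioSpec) -> CalibrationResult:
    """Calibrate the model intercept ``b0`` to the target outcome prevalence.

    Binary exposures: closed form, ``b0 = log(prev / sum_cells
    P(x1,x2) exp(b1 x1 + b2 x2))``; an error is raised if any cell's
    success probability would exceed one (infeasible scenario).
    Continuous exposures: the post-resampling prevalence has the closed
    form ``exp(b0 + v/2) * Phi((-b0 - v)/sd) / Phi(-b0/sd)`` where
    ``v`` is the variance of the linear predictor without intercept;
    ``b0`` is found by root-finding on that expression, so the
    calibration targets the truncated (resampled) exposure law.

    The returned :class:`CalibrationResult` carries ``alpha = nan``;
    use :func:`solve_alpha` or :func:`calibrate` for the missingness
    intercept.
    """
    prev = spec.prevalence
    if spec.exposure_type == "binary":
        cells, probs = binary_cell_probs(spec.assoc)
        eta = cells @ np.array([spec.beta1, spec.beta2])
        denom = float(probs @ np.exp(eta))
        beta0 = math.log(prev / denom)
        if beta0 + eta.max() > 0.0:
            raise CalibrationError(
                f"prevalence {prev} infeasible: cell success probability "
                f"{math.exp(beta0 + eta.max()):.3f} exceeds 1"
            )
        return CalibrationResult(beta0, math.nan, prev, math.nan)

    sd = _linpred_sd(spec)
    if sd < 1e-12:  # null effects: intercept-only model
        return CalibrationResult(math.log(prev), math.nan, prev, math.nan)
    try:
        beta0 = brentq(lambda b0: _trunc_prevalence(b0, sd) - prev, -40.0, 10.0, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(f"no intercept attains prevalence {prev}") from exc
    return CalibrationResult(beta0, math.nan, _trunc_prevalence(beta0, sd), math.nan)


def first_draw_invalid_rate(
    spec: ScenarioSpec,
    beta0: float,
    rng: np.random.Generator | None = None,
    n: int = 1_000_000,
) -> float:
    """Fraction of first-draw success probabilities exceeding one.

    Analytic (``Phi(b0/sd)``) when no ``rng`` is given, otherwise a
    Monte Carlo estimate from ``n`` fresh exposure pairs.
    """
    if spec.exposure_type == "binary":
        cells, probs = binary_cell_probs(spec.assoc)
        eta = beta0 + cells @ np.array([spec.beta1, spec.beta2])
        if rng is None:
            return float(probs[eta > 0].sum())
        x1, x2 = _draw_binary_exposures(spec, rng, n)
        return float(np.mean(beta0 + spec.beta1 * x1 + spec.beta2 * x2 > 0))
    sd = _linpred_sd(spec)
    if rng is None:
        return 0.0 if sd < 1e-12 else float(norm.cdf(beta0 / sd))
    x1, x2 = _draw_normal_exposures(spec, rng, n)
    return float(np.mean(beta0 + spec.beta1 * x1 + spec.beta2 * x2 > 0))


def _draw_binary_exposures(spec: ScenarioSpec, rng: np.random.Generator, n: int):
    p0 = 1.0 / (1.0 + spec.assoc)
    p1 = spec.assoc / (1.0 + spec.assoc)
    x1 = (rng.random(n) < 0.5).astype(float)
    x2 = (rng.random(n) < np.where(x1 == 1.0, p1, p0)).astype(float)
    return x1, x2


def _draw_normal_exposures(spec: ScenarioSpec, rng: np.random.Generator, n: int):
    var = spec.exposure_var
    rho = spec.assoc
    z = rng.standard_normal((n, 2))
    x1 = math.sqrt(var) * z[:, 0]
    x2 = math.sqrt(var) * (rho * z[:, 0] + math.sqrt(1.0 - rho * rho) * z[:, 1])
    return x1, x2


def generate_complete(
    spec: ScenarioSpec, beta0: float, rng: np.random.Generator
) -> SimDataset:
    """Draw one complete dataset of size ``spec.n`` from the calibrated model.

    Exposure pairs with ``exp(b0 + b1 x1 + b2 x2) > 1`` are redrawn
    row-wise (bounded attempts) so every emitted success probability is
    valid; the fraction of invalid first draws is recorded on the
    returned dataset.
    """
    n = spec.n
    draw = _draw_binary_exposures if spec.exposure_type == "binary" else _draw_normal_exposures
    x1, x2 = draw(spec, rng, n)
    eta = beta0 + spec.beta1 * x1 + spec.beta2 * x2
    invalid = eta > 0.0
    first_invalid = float(invalid.mean())
    attempts = 0
    while invalid.any():
        attempts += 1
        if attempts > _MAX_RESAMPLE_ATTEMPTS:
            raise ResamplingError(
                f"invalid-probability resampling did not terminate within "
                f"{_MAX_RESAMPLE_ATTEMPTS} attempts"
            )
        k = int(invalid.sum())
        nx1, nx2 = draw(spec, rng, k)
        x1[invalid] = nx1
        x2[invalid] = nx2
        eta[invalid] = beta0 + spec.beta1 * nx1 + spec.beta2 * nx2
        invalid = eta > 0.0
    y = (rng.random(n) < np.exp(eta)).astype(float)
    masks = np.zeros(n, dtype=bool)
    return SimDataset(y, x1, x2, masks.copy(), masks.copy(), first_invalid)


def solve_alpha(spec: ScenarioSpec) -> float:
    """Calibrate the missingness intercept ``alpha`` to the target rate.

    Solves ``E[expit(alpha + lam * W)] = missing_prop`` where ``W`` is
    X1 for binary exposures (two-point law at 0/1) and the standardised
    exposure ``Z1 = X1/sd(X1)`` for continuous exposures (standard
    normal, integrated by Gauss-Hermite quadrature). By the symmetry of
    the exposure laws the same ``alpha`` calibrates the second equation
    of the opposite mechanism.
    """
    mp = spec.missing_prop
    lam = 0.0 if spec.mechanism == "mcar" else spec.lam
    if lam == 0.0:
        return float(logit(mp))
    if spec.exposure_type == "binary":
        f = lambda a: 0.5 * expit(a) + 0.5 * expit(a + lam) - mp
    else:
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        z = math.sqrt(2.0) * nodes
        w = weights / math.sqrt(math.pi)
        f = lambda a: float(w @ expit(a + lam * z)) - mp
    return float(brentq(f, -50.0, 50.0, xtol=1e-12))


def _missingness_probs(
    data: SimDataset, spec: ScenarioSpec, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row missingness probabilities (p_y, p_x2) under the mechanism."""
    if spec.exposure_type == "binary":
        w = data.x1
        w_flip = 1.0 - data.x1
    else:
        w = data.x1 / math.sqrt(spec.exposure_var)
        w_flip = -w
    lam = spec.lam
    mech = spec.mechanism
    if mech == "mcar":
        p = np.full(data.n, expit(alpha))
        return p, p.copy()
    if mech == "coordinated":
        p = expit(alpha + lam * w)
        return p, p.copy()
    if mech == "opposite":
        return expit(alpha + lam * w), expit(alpha + lam * w_flip)
    if mech == "y_only":
        return expit(alpha + lam * w), np.zeros(data.n)
    if mech == "x2_only":
        return np.zeros(data.n), expit(alpha + lam * w)
    raise ValueError(f"unknown mechanism {mech!r}")


def apply_missingness(
    data: SimDataset, spec: ScenarioSpec, alpha: float, rng: np.random.Generator
) -> SimDataset:
    """Impose the MAR mechanism, returning a copy with masks set.

    The two per-row indicators are drawn with independent uniforms
    (coordinated missingness shares the probability, not the draw)
    unless ``spec.coupled_missingness`` forces a single uniform per row.
    """
    if data.miss_y.any() or data.miss_x2.any():
        raise ValueError("missingness must be applied to a complete dataset")
    p_y, p_x2 = _missingness_probs(data, spec, alpha)
    out = data.copy()
    if spec.coupled_missingness and spec.mechanism == "coordinated":
        u = rng.random(data.n)
        out.miss_y = u < p_y
        out.miss_x2 = u < p_x2
    else:
        out.miss_y = rng.random(data.n) < p_y
        out.miss_x2 = rng.random(data.n) < p_x2
    return out


def calibrate(spec: ScenarioSpec, check_rng: np.random.Generator | None = None) -> CalibrationResult:
    """Calibrate both intercepts for a scenario.

    When ``check_rng`` is given, the achieved missingness proportion is
    verified on a large Monte Carlo draw; otherwise the analytic value
    (equal to the target by construction) is reported.
    """
    cal = solve_beta0(spec)
    alpha = solve_alpha(spec)
    achieved_mp = spec.missing_prop
    if check_rng is not None:
        big = spec.with_(n=200_000)
        ds = generate_complete(big, cal.beta0, check_rng)
        ds = apply_missingness(ds, big, alpha, check_rng)
        rates = []
        if spec.mechanism in ("coordinated", "opposite", "y_only", "mcar"):
            rates.append(ds.miss_y.mean())
        if spec.mechanism in ("coordinated", "opposite", "x2_only", "mcar"):
            rates.append(ds.miss_x2.mean())
        achieved_mp = float(np.mean(rates))
    return CalibrationResult(cal.beta0, alpha, cal.achieved_prevalence, achieved_mp)
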