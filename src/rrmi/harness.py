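"""Simulation orchestration: replicates, scenarios, grids, performance metrics.

One replicate generates a complete dataset, imposes missingness, runs
each requested method (MVNI, MVNI+deletion, FCS, FCS+deletion, CCA, and
optionally the complete-data fit), and records point estimates,
standard errors and 95% interval bounds for b1 and b2. A scenario
repeats that over independent replicates and summarises bias, average
and empirical standard error, coverage and mean square error per method
and parameter, with Monte Carlo standard errors.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import FitError
from .config import ScenarioSpec
from .datagen import CalibrationResult, apply_missingness, calibrate, generate_complete
from .estimators import (
    MODIFIED_POISSON,
    FitResult,
    cca_fit,
    choose_analysis,
    delete_imputed_outcomes,
    pool_rubin,
)
from .fcs import ImputationFailure, ImputationSet, fcs_impute
from .mvni import mvni_impute

ALL_METHODS = ("MVNI", "MVNI+deletion", "FCS", "FCS+deletion", "CCA")
PARAMS = ("beta1", "beta2")


@dataclass
class MethodRecord:
    """Per-replicate, per-method estimates for (b1, b2)."""

    est: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_fallback: int = 0  # imputed datasets analysed by modified Poisson fallback


@dataclass
class ScenarioSummary:
    """Tidy per-method, per-parameter performance table for one scenario."""

    spec: ScenarioSpec
    table: pd.DataFrame
    reps_completed: dict
    reps_flagged: dict

    def to_frame(self) -> pd.DataFrame:
        return self.table


def replicate_rng(seed: int, scenario_index: int, rep: int) -> np.random.Generator:
    """Deterministic child stream for one replicate of one scenario."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(scenario_index, rep)))


def _record_fit(fit: FitResult, confidence: float = 0.95) -> MethodRecord:
    lo, hi = fit.ci(confidence)
    return MethodRecord(
        fit.estimates[1:3].copy(), fit.std_errors[1:3].copy(), lo[1:3], hi[1:3],
        int(fit.estimator == MODIFIED_POISSON),
    )


def _analyse_imputations(imp: ImputationSet, exposure_type: str) -> MethodRecord:
    fits, n_fb = [], 0
    for ds in imp.completed:
        fit = choose_analysis(ds, exposure_type)
        n_fb += int(exposure_type == "binary" and fit.estimator == MODIFIED_POISSON)
        fits.append(fit)
    pooled = pool_rubin(fits)
    return MethodRecord(
        pooled.estimates[1:3].copy(),
        pooled.std_errors[1:3].copy(),
        pooled.ci_low[1:3].copy(),
        pooled.ci_high[1:3].copy(),
        n_fb,
    )


def run_replicate(
    spec: ScenarioSpec,
    calib: CalibrationResult,
    rng: np.random.Generator,
    methods: tuple[str, ...] = ALL_METHODS,
    rounding: str = "adaptive",
    order: str = "outcome_last",
    include_complete: bool = False,
) -> tuple[dict[str, MethodRecord], dict[str, str]]:
    """Run one replicate; returns per-method records and per-method failure flags.

    A failing method is flagged (not raised) so one replicate's
    pathology never aborts a scenario.
    """
    results: dict[str, MethodRecord] = {}
    flags: dict[str, str] = {}
    complete = generate_complete(spec, calib.beta0, rng)
    if include_complete:
        try:
            results["complete"] = _record_fit(choose_analysis(complete, spec.exposure_type))
        except FitError as exc:
            flags["complete"] = str(exc)
    data = apply_missingness(complete, spec, calib.alpha, rng)

    if "CCA" in methods:
        try:
            results["CCA"] = _record_fit(cca_fit(data, spec.exposure_type))
        except FitError as exc:
            flags["CCA"] = str(exc)

    if "FCS" in methods or "FCS+deletion" in methods:
        try:
            imp = fcs_impute(data, spec, rng, order=order)
        except ImputationFailure as exc:
            for name in ("FCS", "FCS+deletion"):
                if name in methods:
                    flags[name] = str(exc)
        else:
            _pool_pair(imp, spec, methods, "FCS", results, flags)

    if "MVNI" in methods or "MVNI+deletion" in methods:
        try:
            imp = mvni_impute(data, spec, rng, rounding=rounding)
        except (ImputationFailure, ValueError) as exc:
            for name in ("MVNI", "MVNI+deletion"):
                if name in methods:
                    flags[name] = str(exc)
        else:
            _pool_pair(imp, spec, methods, "MVNI", results, flags)

    return results, flags


def _pool_pair(imp, spec, methods, base, results, flags) -> None:
    if base in methods:
        try:
            results[base] = _analyse_imputations(imp, spec.exposure_type)
        except (FitError, ValueError) as exc:
            flags[base] = str(exc)
    name = base + "+deletion"
    if name in methods:
        try:
            results[name] = _analyse_imputations(
                delete_imputed_outcomes(imp), spec.exposure_type
            )
        except (FitError, ValueError) as exc:
            flags[name] = str(exc)


def summarize(
    results: list[dict[str, MethodRecord]],
    true_beta: tuple[float, float],
    spec: ScenarioSpec | None = None,
    flags: list[dict[str, str]] | None = None,
) -> pd.DataFrame:
    """Performance metrics per method and parameter across replicates.

    bias = mean(est) - true; avg_se = mean(reported SE);
    emp_se = SD(est) (ddof=1); coverage = fraction of CIs containing
    the truth; mse = mean((est - true)^2). Monte Carlo SEs:
    emp_se/sqrt(reps) for bias, sqrt(c(1-c)/reps) for coverage.
    """
    methods = sorted({name for r in results for name in r})
    n_flagged = {m: 0 for m in methods}
    if flags is not None:
        for f in flags:
            for name in f:
                n_flagged.setdefault(name, 0)
                n_flagged[name] += 1
    rows = []
    true = np.asarray(true_beta, dtype=float)
    for name in methods:
        recs = [r[name] for r in results if name in r]
        if len(recs) < 2:
            continue
        est = np.array([r.est for r in recs])
        se = np.array([r.se for r in recs])
        lo = np.array([r.ci_low for r in recs])
        hi = np.array([r.ci_high for r in recs])
        reps = len(recs)
        for j, pname in enumerate(PARAMS):
            bias = est[:, j].mean() - true[j]
            emp_se = est[:, j].std(ddof=1)
            cov = float(np.mean((lo[:, j] <= true[j]) & (true[j] <= hi[:, j])))
            row = {
                "method": name,
                "parameter": pname,
                "bias": bias,
                "avg_se": se[:, j].mean(),
                "emp_se": emp_se,
                "coverage": cov,
                "mse": float(np.mean((est[:, j] - true[j]) ** 2)),
                "mc_se_bias": emp_se / np.sqrt(reps),
                "mc_se_coverage": float(np.sqrt(cov * (1.0 - cov) / reps)),
                "reps_completed": reps,
                "reps_flagged": n_flagged.get(name, 0),
                "n_fallback_total": int(sum(r.n_fallback for r in recs)),
            }
            rows.append(row)
    df = pd.DataFrame(rows)
    if spec is not None and not df.empty:
        meta = {
            "exposure_type": spec.exposure_type,
            "prevalence": spec.prevalence,
            "beta1_true": spec.beta1,
            "beta2_true": spec.beta2,
            "assoc": spec.assoc,
            "mechanism": spec.mechanism,
            "lam": spec.lam,
            "n": spec.n,
            "m": spec.m,
        }
        for k, v in reversed(meta.items()):
            df.insert(0, k, v)
    return df


def run_scenario(
    spec: ScenarioSpec,
    methods: tuple[str, ...] = ALL_METHODS,
    rounding: str = "adaptive",
    order: str = "outcome_last",
    include_complete: bool = False,
    scenario_index: int = 0,
    progress: bool = False,
) -> ScenarioSummary:
    """Calibrate once, run all replicates, summarise.

    Replicate r uses the child stream ``SeedSequence(spec.seed,
    spawn_key=(scenario_index, r))`` so any single replicate is
    reproducible in isolation.
    """
    calib = calibrate(spec)
    all_results, all_flags = [], []
    for rep in range(spec.reps):
        rng = replicate_rng(spec.seed, scenario_index, rep)
        res, flg = run_replicate(
            spec, calib, rng, methods=methods, rounding=rounding,
            order=order, include_complete=include_complete,
        )
        all_results.append(res)
        all_flags.append(flg)
        if progress and (rep + 1) % 50 == 0:
            print(f"  [{spec.label()}] {rep + 1}/{spec.reps}", file=sys.stderr)
    table = summarize(all_results, spec.true_beta, spec=spec, flags=all_flags)
    completed = {m: int(sum(m in r for r in all_results)) for m in set().union(*map(set, all_results))} if all_results else {}
    flagged = {m: int(sum(m in f for f in all_flags)) for m in set().union(*map(set, all_flags))} if any(all_flags) else {}
    return ScenarioSummary(spec, table, completed, flagged)


def run_grid(
    specs: list[ScenarioSpec],
    methods: tuple[str, ...] = ALL_METHODS,
    rounding: str = "adaptive",
    order: str = "outcome_last",
    include_complete: bool = False,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every scenario in a grid; one tidy row per scenario x method x parameter.

    Per-scenario failures are logged to stderr and skipped, never fatal.
    """
    frames = []
    for idx, spec in enumerate(specs):
        if progress:
            print(f"scenario {idx + 1}/{len(specs)}: {spec.label()}", file=sys.stderr)
        try:
            summ = run_scenario(
                spec, methods=methods, rounding=rounding, order=order,
                include_complete=include_complete, scenario_index=idx, progress=progress,
            )
        except Exception as exc:  # noqa: BLE001 - grid must survive one bad scenario
            print(f"scenario {idx} failed: {exc}", file=sys.stderr)
            continue
        df = summ.table.copy()
        df.insert(0, "scenario", idx)
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
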