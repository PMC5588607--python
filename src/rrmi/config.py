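"""Scenario specification and simulation grids.

A :class:`ScenarioSpec` fully parameterises one simulation scenario:
the exposure distribution, the log binomial outcome model, the
missing-data mechanism, and the multiple-imputation settings. Grids of
scenarios can be built programmatically (:func:`study1_grid`,
:func:`study2_grid`) or loaded from a YAML/JSON config file
(:func:`load_grid`).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import yaml

EXPOSURE_TYPES = ("binary", "continuous")
MECHANISMS = ("coordinated", "opposite", "y_only", "x2_only", "mcar")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterisation of one simulation scenario.

    Parameters
    ----------
    exposure_type : {"binary", "continuous"}
        Binary exposures with marginal prevalence 0.50, or bivariate
        normal exposures with mean 0 and variance ``exposure_var``.
    prevalence : float
        Target overall outcome prevalence; the intercept ``b0`` is
        calibrated to hit it.
    beta1, beta2 : float
        Log conditional relative risks for X1 and X2.
    assoc : float
        Exposure association: for binary exposures the risk ratio
        RR(X1, X2) (>= 1); for continuous exposures the correlation
        (|assoc| < 1).
    mechanism : {"coordinated", "opposite", "y_only", "x2_only", "mcar"}
        Missing-data mechanism. "coordinated" and "opposite" put MAR
        missingness in both Y and X2 driven by X1; "y_only"/"x2_only"
        restrict missingness to a single variable; "mcar" ignores X1.
    lam : float
        Strength of the missingness dependence on X1 (0 = MCAR).
    missing_prop : float
        Target marginal missingness proportion per incomplete variable;
        the missingness intercept ``alpha`` is calibrated to hit it.
    n : int
        Rows per simulated dataset.
    reps : int
        Number of simulated datasets per scenario.
    m : int
        Number of imputations.
    cycles : int
        FCS sweeps per imputation.
    burn_in : int
        Data-augmentation iterations before the first MVNI imputation.
    between : int
        Data-augmentation iterations between successive MVNI imputations.
    exposure_var : float
        Variance of each continuous exposure.
    coupled_missingness : bool
        If True, the coordinated mechanism uses a single uniform draw
        per row for both missingness indicators (fully coupled masks);
        default False draws them independently with equal probabilities.
    seed : int
        Master seed; every replicate derives its own child stream.
    """

    exposure_type: str
    prevalence: float
    beta1: float
    beta2: float
    assoc: float
    mechanism: str
    lam: float
    missing_prop: float = 0.30
    n: int = 1000
    reps: int = 2000
    m: int = 20
    cycles: int = 20
    burn_in: int = 200
    between: int = 100
    exposure_var: float = 0.20
    coupled_missingness: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exposure_type not in EXPOSURE_TYPES:
            raise ValueError(f"exposure_type must be one of {EXPOSURE_TYPES}")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if not 0.0 < self.missing_prop < 1.0:
            raise ValueError("missing_prop must lie in (0, 1)")
        if self.n < 4:
            raise ValueError("n must be at least 4")
        if self.m < 2:
            raise ValueError("m must be at least 2 (Rubin pooling needs >= 2)")
        if self.exposure_type == "binary" and self.assoc < 1.0:
            raise ValueError("binary exposure association RR(X1,X2) must be >= 1")
        if self.exposure_type == "continuous" and not abs(self.assoc) < 1.0:
            raise ValueError("continuous exposure correlation must satisfy |assoc| < 1")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    @property
    def true_beta(self) -> tuple[float, float]:
        return (self.beta1, self.beta2)

    def with_(self, **kwargs) -> "ScenarioSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def label(self) -> str:
        b = f"{math.exp(self.beta1):.3g}/{math.exp(self.beta2):.3g}"
        return (
            f"{self.exposure_type}|prev={self.prevalence}|RR={b}"
            f"|assoc={self.assoc}|{self.mechanism}|lam={self.lam}"
        )


def study1_grid(**overrides) -> list[ScenarioSpec]:
    """The 32 binary-exposure scenarios.

    Cartesian product of prevalence {0.10, 0.30} x RR(X1,X2) {2, 3} x
    conditional RR {2, 3} x mechanism {coordinated, opposite} x
    lambda {1, 2}.
    """
    return [
        ScenarioSpec(
            exposure_type="binary",
            prevalence=prev,
            beta1=math.log(rr),
            beta2=math.log(rr),
            assoc=assoc,
            mechanism=mech,
            lam=lam,
            **overrides,
        )
        for prev, assoc, rr, mech, lam in itertools.product(
            (0.10, 0.30), (2.0, 3.0), (2.0, 3.0), ("coordinated", "opposite"), (1.0, 2.0)
        )
    ]


def study2_grid(**overrides) -> list[ScenarioSpec]:
    """The 32 continuous-exposure scenarios (correlation {0.30, 0.70})."""
    return [
        ScenarioSpec(
            exposure_type="continuous",
            prevalence=prev,
            beta1=math.log(rr),
            beta2=math.log(rr),
            assoc=corr,
            mechanism=mech,
            lam=lam,
            **overrides,
        )
        for prev, corr, rr, mech, lam in itertools.product(
            (0.10, 0.30), (0.30, 0.70), (2.0, 3.0), ("coordinated", "opposite"), (1.0, 2.0)
        )
    ]


def _as_list(value) -> list:
    return list(value) if isinstance(value, (list, tuple)) else [value]


def expand_grid(config: dict) -> list[ScenarioSpec]:
    """Expand a config mapping into the Cartesian product of scenarios.

    Grid axes (``exposure_type``, ``prevalence``, ``rr`` or
    ``beta1``/``beta2``, ``assoc``, ``mechanism``, ``lam``) may be
    scalars or lists; scalar MI settings (n, reps, m, ...) apply to
    every scenario.
    """
    scalar_keys = (
        "missing_prop",
        "n",
        "reps",
        "m",
        "cycles",
        "burn_in",
        "between",
        "exposure_var",
        "coupled_missingness",
        "seed",
    )
    fixed = {k: config[k] for k in scalar_keys if k in config}

    if "rr" in config:
        betas = [(math.log(r), math.log(r)) for r in _as_list(config["rr"])]
    else:
        betas = list(
            itertools.product(_as_list(config.get("beta1", 0.0)), _as_list(config.get("beta2", 0.0)))
        )

    specs = []
    for etype, prev, (b1, b2), assoc, mech, lam in itertools.product(
        _as_list(config["exposure_type"]),
        _as_list(config["prevalence"]),
        betas,
        _as_list(config["assoc"]),
        _as_list(config["mechanism"]),
        _as_list(config.get("lam", 0.0)),
    ):
        specs.append(
            ScenarioSpec(
                exposure_type=etype,
                prevalence=prev,
                beta1=b1,
                beta2=b2,
                assoc=assoc,
                mechanism=mech,
                lam=lam,
                **fixed,
            )
        )
    return specs


def load_grid(path: str | Path) -> list[ScenarioSpec]:
    """Load a scenario grid from a YAML (or JSON) config file."""
    text = Path(path).read_text()
    config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise ValueError(f"config {path} must be a mapping of scenario fields")
    return expand_grid(config)
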