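# Methods

This note documents the models, algorithms and numerical choices behind
`rrmi`, and what the synthetic data do and do not emulate.

## Data-generating model

Complete data follow the log binomial model
`log P(Y=1 | X1, X2) = β0 + β1 X1 + β2 X2`.

**Binary exposures.** `X1 ~ Bernoulli(0.5)`; `X2 | X1` is Bernoulli with
conditional prevalences `p0 = 1/(1+a)`, `p1 = a/(1+a)` where
`a = RR(X1, X2)` is the exposure association. This construction is the
unique one with `p1/p0 = a` and marginal prevalence
`(p0 + p1)/2 = 0.5`, so `X2` keeps a 0.50 margin whatever the
confounding strength (a = 2 gives p0 = 1/3, p1 = 2/3; a = 3 gives
0.25/0.75). The intercept is available in closed form:
`β0 = log(prev / Σ_cells P(x1,x2) exp(β1 x1 + β2 x2))`. A scenario whose
largest cell probability would exceed one is rejected as infeasible
(none of the study grids trigger this).

**Continuous exposures.** `(X1, X2)` are bivariate normal with mean 0,
variance 0.20 and correlation ρ ∈ {0.30, 0.70}. Because the log link is
unbounded, a draw can yield `exp(η) > 1`; such rows have their exposure
pair redrawn (bounded at 10⁴ attempts) so every emitted success
probability is valid. Resampling truncates the exposure law to
`{β1 x1 + β2 x2 ≤ −β0}`, and the intercept calibration targets that
truncated law. With `s = β1 X1 + β2 X2 ~ N(0, v)`,
`v = 0.20 (β1² + β2² + 2ρ β1 β2)`, the post-resampling prevalence has
the closed form

```
prev(β0) = exp(β0 + v/2) · Φ((−β0 − v)/√v) / Φ(−β0/√v),
```

a truncated-lognormal mean, and `β0` is found by Brent root-finding on
it. This is exact and deterministic; the test suite verifies it against
a fresh Monte Carlo sample (tolerance 3 Monte Carlo SEs, and in any case
below 1e-3). In the worst setting (prevalence 0.30, relative risks 3)
about 6.7% of first draws are invalid at ρ = 0.70 and 4.2% at ρ = 0.30 —
roughly 5.4% pooled over the two correlation settings.

**Missingness.** MAR mechanisms put logistic missingness in `Y` and
`X2` driven by the always-observed `X1` (standardised to
`Z1 = X1/√0.20` in the continuous case):

- *coordinated*: `logit P(miss) = α + λ W` for both variables — the two
  indicators share a per-row probability but are drawn with independent
  uniforms (a `coupled_missingness` switch forces a single uniform, i.e.
  perfectly coupled masks);
- *opposite*: `α + λ W` for `Y`, `α + λ(1 − X1)` (binary) or `α − λ Z1`
  (continuous) for `X2`;
- *y_only* / *x2_only*: one variable only; *mcar*: `λ = 0`.

`α` solves `E[expit(α + λ W)] = 0.30` with the expectation over the
design exposure law (two-point for binary `X1`; standard normal via
80-node Gauss–Hermite quadrature for `Z1`). By symmetry the same `α`
calibrates both equations of the opposite mechanism. One caveat: in the
heavily truncated continuous settings the realised `X1` is no longer
exactly `N(0, 0.2)`, so achieved missingness dips to ~26% when
prevalence 0.30 meets relative risks of 3 at ρ = 0.70. The calibration
deliberately stays on the design law — the mechanism definitions are
written in terms of the standard-normal `Z1` — and this shift is
documented and tested rather than corrected.

## Imputation

**FCS.** Each of the `m` imputations runs an independent chain: missing
cells start as draws with replacement from the observed margin of the
same variable (random initial fill avoids the degenerate first-cycle
logistic fits a mean fill can produce), then `cycles = 20` sweeps
re-impute `X2` from `(Y, X1)` and `Y` from `(X1, X2)`, outcome last by
default (outcome-first is available as a sensitivity option). Parameter
draws make the imputations proper: logistic models use the asymptotic
normal posterior at the MLE (mean = MLE, covariance = inverse observed
information — the standard choice in chained-equations software); the
linear model for continuous `X2` uses the Jeffreys prior, drawing
`σ² ~ RSS/χ²(n−p)` then `θ ~ N(θ̂, σ²(X'X)⁻¹)`. Separation or a
singular fit triggers one retry with a small ridge (1e-4) on the
information; a chain that still fails restarts from a fresh fill up to
three times before the replicate is flagged and excluded (counts
reported). At n = 1000 and prevalence ≥ 0.10 this is rare.

**MVNI.** `(Y, X1, X2)` enter a trivariate normal as raw 0/1 where
binary. Starting values are the EM MLE under ignorable missingness
(sufficient-statistics EM over the four missingness patterns, converged
when successive observed-data log-likelihoods differ by < 1e-8; a
covariance that loses positive definiteness restarts with an inflated
diagonal). Data augmentation alternates an I-step (each row's missing
coordinates drawn from their conditional normal) and a P-step
(`Σ ~ InvWishart(n−1, S)`, `μ | Σ ~ N(z̄, Σ/n)` — the Jeffreys-prior
posterior; the inverse-Wishart draw uses a Bartlett factorisation and is
cross-checked against scipy's sampler in tests). The first imputation is
taken after `burn_in = 200` iterations; later ones every
`between = 100` iterations. The spacing default is not dictated by the
study design, which specifies only that additional iterations separate
imputations; 100 keeps the lag-`between` autocorrelation of the mean
components well below 0.2 (tested) while costing half a burn-in per
imputation.

**Rounding.** Continuous imputed values of binary variables are rounded
per imputed dataset: adaptive rounding by default, with threshold
`c = ω̄ − Φ⁻¹(ω̄)·√(ω̄(1−ω̄))` where `ω̄` is that dataset's completed
column mean (each dataset supplies its own threshold; a degenerate mean
yields a constant column), or simple rounding at 0.5 as a sensitivity
option. Ties round to 1 (`≥`). `Y` is always rounded; `X2` as well when
binary — without this the downstream log binomial fits are unstable.

## Analysis and pooling

The log binomial model is fitted by Fisher scoring with start
`(log ȳ, 0, 0)` and step-halving so every iterate keeps all fitted
probabilities strictly below one; convergence requires a relative
deviance change < 1e-8 within 100 iterations. A fit whose maximum
fitted probability ends within 1e-6 of one is flagged non-converged
(deviance-based stopping stalls around 1e-9 short of a true boundary
MLE, so a tighter flag would never fire); flagged fits fall back to
modified Poisson, per dataset, before pooling, with fallback counts
reported. Continuous-exposure scenarios use modified Poisson throughout
— with unbounded covariates the log binomial fails often enough that a
single estimator keeps the Monte Carlo summaries interpretable. The
sandwich is plain HC0; at n = 1000 small-sample corrections are
immaterial.

Rubin's rules: pooled estimate = mean; total variance
`T = W̄ + (1 + 1/m) B`; degrees of freedom
`(m−1)(1 + W̄/((1+1/m)B))²`, infinite when `B = 0` (normal quantiles).
The classical large-sample dof is the default — appropriate at n = 1000
— with the Barnard–Rubin small-sample adjustment available behind a
documented switch (`small_sample_dof`, requiring the complete-data
dof).

## Randomness and determinism

One master seed per scenario; replicate `r` of scenario `s` uses the
child stream `SeedSequence(seed, spawn_key=(s, r))`, so any single
replicate is reproducible in isolation and identical configs produce
bit-identical outputs (tested).

## Problem sizes

Scenario summaries in the test suite use 200–500 replicates (against
reference values quoted with ~2000-replicate precision, compared within
3 Monte Carlo SEs). The acceptance script uses 200–500 replicates for
the imputation scenarios, whose per-replicate cost is dominated by the
MI chains, and 6000–10000 for the imputation-free complete-data and
complete-case grids: those targets are maxima of per-cell Monte Carlo
bias estimates over 16–64 cells, and at a few thousand replicates the
max is dominated by sampling noise rather than the bias it is meant to
measure, so the cheap fits are run at replication high enough for the
max to be informative. A full 2000-replicate run of one imputation
scenario with all five methods takes roughly half an hour on one CPU
(`run_grid` scales linearly in scenarios × replicates).

## What the generator does and does not emulate

It reproduces the study conditions exactly: two exposures, correctly
specified analysis model, MAR driven by a fully observed covariate, 30%
missingness per variable. It does not emulate auxiliary variables,
MNAR, more than two covariates, non-logistic missingness, or messy
real-data features (measurement error, nonlinearity, interactions).
Passing tests therefore demonstrate the *estimator properties under the
stated model*, not robustness on real data. Two known consequences of
the design itself: CCA is nearly unbiased in every scenario (missingness
depends only on `X1`), so CCA here is a pipeline sanity check, not a
general endorsement; and the max-over-scenarios CCA bias is a heavy-
tailed max statistic — in the sparsest cell (prevalence 0.10, exposure
association 3, relative risks 3, opposite λ = 2) the estimate
distribution has empirical SE near 0.9, so that summary moves by ±0.02
between seeds even at 2000 replicates.

## Known limitations

- The logistic posterior in FCS is the asymptotic normal approximation,
  not an exact Bayes draw; at n = 1000 the difference is negligible but
  it is untested at very small n.
- `em_start` and the DA chain treat binary variables as Gaussian by
  design (that is the method under study); the chain is not a valid
  sampler for the true joint law, which is precisely the misspecification
  whose cost the simulations measure.
- Log binomial non-convergence counts are reported but have no external
  reference to compare against.
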