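# rrmi

Monte Carlo evaluation of multiple imputation for **relative risk**
estimation from log binomial models under missing-at-random (MAR)
missingness.

## The problem

Adjusted relative risks for a binary outcome are usually estimated from a
log binomial model,

```
log P(Y = 1 | X1, X2) = β0 + β1 X1 + β2 X2,
```

so that `exp(β1)` and `exp(β2)` are conditional relative risks, or — when
the log binomial fit fails to converge — from modified Poisson regression
(a Poisson working model with a robust HC0 sandwich variance). When the
outcome `Y` and a covariate `X2` are partly missing, standard multiple
imputation (MI) imputes them either by **fully conditional specification**
(FCS: chained univariate models, logistic for the binary outcome) or under
a joint **multivariate normal model** (MVNI: data augmentation, then
rounding of binary variables). Both imputation models are misspecified
relative to a log binomial analysis model, and this package quantifies the
consequences: bias toward the null, overwide intervals, and collapsed
coverage, with the misspecification cost depending on outcome prevalence,
effect size and the missingness mechanism. It is aimed at biostatisticians
studying MI behaviour and at anyone needing a controlled testbed for
relative risk estimation with missing data.

`rrmi` implements, from scratch and fully tested:

- **datagen** — exposure laws (binary with marginal prevalence 0.50 and a
  confounding risk ratio, or bivariate normal with variance 0.20),
  closed-form/analytic calibration of `β0` to a target prevalence
  (accounting for resampling of invalid success probabilities) and of the
  missingness intercept `α` to a target 30% missingness, and coordinated /
  opposite / single-variable / MCAR logistic MAR mechanisms driven by the
  always-observed `X1`;
- **fcs** — chained-equations imputation with proper posterior draws
  (normal approximation for logistic models, Jeffreys-prior Bayesian
  linear regression for a continuous covariate);
- **mvni** — EM starting values, I-step/P-step data augmentation with a
  200-iteration burn-in, and adaptive or simple rounding of binary
  variables;
- **estimators** — log binomial IRLS with step-halving and boundary
  detection, modified Poisson with HC0 sandwich variance, complete case
  analysis (CCA), deletion of imputed outcomes (MID), and Rubin's-rules
  pooling;
- **harness** — the scenario grids (32 binary-exposure and 32
  continuous-exposure scenarios), per-replicate orchestration of the five
  methods (MVNI, MVNI+deletion, FCS, FCS+deletion, CCA), and performance
  summaries (bias, average and empirical SE, coverage, MSE, with Monte
  Carlo standard errors).

## Worked example

```bash
python examples/run_small_simulation.py
```

runs 50 replicates of the headline binary-exposure scenario (outcome
prevalence 0.30, conditional relative risks 3, RR(X1,X2) = 2, coordinated
missingness with λ = 2, 30% missing `Y` and `X2`, m = 20 imputations) and
prints:

```
       method parameter   bias  avg_se  emp_se  coverage   mse
          CCA     beta1 -0.010   0.168   0.173      0.96 0.030
          CCA     beta2 -0.021   0.207   0.233      0.90 0.054
          FCS     beta1  0.008   0.155   0.161      0.92 0.026
          FCS     beta2 -0.132   0.201   0.228      0.86 0.068
 FCS+deletion     beta1 -0.004   0.153   0.158      0.92 0.024
 FCS+deletion     beta2 -0.080   0.206   0.231      0.86 0.059
         MVNI     beta1  0.004   0.152   0.162      0.94 0.026
         MVNI     beta2 -0.341   0.170   0.181      0.42 0.149
MVNI+deletion     beta1  0.029   0.152   0.158      0.94 0.025
MVNI+deletion     beta2 -0.171   0.193   0.214      0.76 0.074
```

Bias is on the log relative risk scale (truth log 3 ≈ 1.099). MVNI's
bias of −0.34 for `β2` means the relative risk for the partly missing
exposure is estimated near 2.1 instead of 3, and its 95% intervals cover
the truth less than half the time; FCS attenuates far less; CCA is
near-unbiased here because missingness depends only on the fully observed
`X1`. The other examples (`calibrate_and_generate.py`,
`impute_and_pool.py`) walk through calibration and a single imputation
round.

A thin CLI wraps the harness for shell use:

```bash
rrmi calibrate --exposure-type binary --prevalence 0.3 --rr 3 --assoc 2 --lam 2
rrmi run --config examples/grid.yaml --reps 200 --out summary.csv
rrmi tables --study continuous --reps 200 --out table_continuous.csv
```

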