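"""Impute one incomplete dataset by FCS and MVNI and compare pooled estimates.

Runs the headline binary-exposure scenario once (true conditional
relative risks of 3, i.e. log RR = 1.0986) and prints the pooled log
relative risks from each method next to complete case analysis and the
fit to the pre-missingness data.
"""

import math

import numpy as np

from rrmi import (
    ScenarioSpec,
    apply_missingness,
    calibrate,
    cca_fit,
    choose_analysis,
    fcs_impute,
    generate_complete,
    mvni_impute,
    pool_rubin,
)

spec = ScenarioSpec(
    exposure_type="binary",
    prevalence=0.30,
    beta1=math.log(3),
    beta2=math.log(3),
    assoc=2.0,
    mechanism="coordinated",
    lam=2.0,
    n=1000,
    seed=0,
)
cal = calibrate(spec)
rng = np.random.default_rng(7)
complete = generate_complete(spec, cal.beta0, rng)
data = apply_missingness(complete, spec, cal.alpha, rng)

full_fit = choose_analysis(complete, spec.exposure_type)
print(f"true log RR = {math.log(3):.3f};  complete-data fit: "
      f"b1 = {full_fit.estimates[1]:.3f}, b2 = {full_fit.estimates[2]:.3f}")

for label, imputer in (("FCS", fcs_impute), ("MVNI", mvni_impute)):
    imp = imputer(data, spec, rng)
    fits = [choose_analysis(d, spec.exposure_type) for d in imp.completed]
    pooled = pool_rubin(fits)
    print(f"{label:5s} pooled: b1 = {pooled.estimates[1]:.3f} "
          f"[{pooled.ci_low[1]:.3f}, {pooled.ci_high[1]:.3f}], "
          f"b2 = {pooled.estimates[2]:.3f} "
          f"[{pooled.ci_low[2]:.3f}, {pooled.ci_high[2]:.3f}]")

cca = cca_fit(data, spec.exposure_type)
print(f"CCA   ({cca.n_used} complete rows): b1 = {cca.estimates[1]:.3f}, "
      f"b2 = {cca.estimates[2]:.3f}")
print()
print("On a single replicate MVNI's b2 typically sits well below the truth")
print("(imputation under a misspecified joint normal model); FCS less so.")
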