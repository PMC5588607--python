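"""Run a small Monte Carlo study and print the performance summary.

50 replicates of the headline binary-exposure scenario with all five
methods. Bias is on the log relative risk scale (truth log 3 = 1.099);
coverage is the fraction of nominal 95% intervals containing the truth.
"""

import math

from rrmi import ScenarioSpec, run_scenario

spec = ScenarioSpec(
    exposure_type="binary",
    prevalence=0.30,
    beta1=math.log(3),
    beta2=math.log(3),
    assoc=2.0,
    mechanism="coordinated",
    lam=2.0,
    n=1000,
    reps=50,
    seed=3,
)

summary = run_scenario(spec, progress=True)
cols = ["method", "parameter", "bias", "avg_se", "emp_se", "coverage", "mse"]
print(summary.table[cols].round(3).to_string(index=False))
print()
print("Reading the table: MVNI's bias for beta2 near -0.3 (relative risk")
print("estimated ~2.2 instead of 3) with collapsed coverage is the headline")
print("failure mode; FCS attenuates less; CCA is near-unbiased here because")
print("missingness depends only on the fully observed X1.")
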