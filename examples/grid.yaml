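# Scenario grid for the binary-exposure study design.
# Axes may be scalars or lists; the Cartesian product defines the grid.
exposure_type: binary
prevalence: [0.10, 0.30]
rr: [2, 3]            # conditional relative risks: beta1 = beta2 = log(rr)
assoc: [2, 3]         # RR(X1, X2)
mechanism: [coordinated, opposite]
lam: [1, 2]
missing_prop: 0.30
n: 1000
reps: 2000
m: 20
cycles: 20
burn_in: 200
between: 100
seed: 1
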