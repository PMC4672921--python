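"""Ask whether clinical parameters add diagnostic value beyond the score.

Builds a cohort where the molecular score is strong, a severity covariate is
weakly informative, and several covariates are pure noise; screens the
covariates individually, then runs the forward greedy logistic selection twice:
free, and with the molecular score forced in. Each accepted step reports the
mean test AUC over 50 stratified 1:1 train/test splits. With the score forced
in, further additions should move the cross-validated AUC only within noise.
"""

import numpy as np
import pandas as pd

import septikit as sk

rng = np.random.default_rng(5)
n = 150
y = np.zeros(2 * n, bool)
y[:n] = True
cov = pd.DataFrame({
    "molecular_score": rng.normal(0, 1, 2 * n) + 2.2 * y,
    "severity_score": rng.normal(0, 1, 2 * n) + 0.5 * y,
    "heart_rate": rng.normal(0, 1, 2 * n),
    "glucose": rng.normal(0, 1, 2 * n),
    "lactate": rng.normal(0, 1, 2 * n),
})

retained = sk.univariate_screen(cov, y, alpha=0.05)
print(f"univariate screen retained: {retained}")

trace = sk.forward_greedy_select(cov[retained], y, max_k=4, n_repeats=50, seed=2)
print("\nfree forward selection:")
for step, (param, auc, ci) in enumerate(trace.steps, 1):
    print(f"  step {step}: + {param:16s} CV AUC = {auc:.3f} ({ci[0]:.3f}-{ci[1]:.3f})")

forced = sk.forward_greedy_select(cov, y, max_k=4, forced_in=("molecular_score",),
                                  n_repeats=50, seed=2)
print("\nwith the molecular score forced in first:")
for step, (param, auc, ci) in enumerate(forced.steps, 1):
    print(f"  step {step}: + {param:16s} CV AUC = {auc:.3f} ({ci[0]:.3f}-{ci[1]:.3f})")
gain = forced.mean_aucs[-1] - forced.mean_aucs[0]
print(f"\nAUC gain from adding clinical parameters to the score: {gain:+.3f} "
      "(within split-to-split noise)")
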