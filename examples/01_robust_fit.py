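"""Fit a multiplicative regression with and without robustness.

Simulates the 3-coefficient study design (beta0 = (1, 1, 1), n = 200,
LPRE noise) with 10% gross upper outliers, then compares the classical
least-product-relative-error fit (gamma = 0) with the robust
gamma-likelihood fit at gamma = 0.5, including sandwich standard errors.
"""

import numpy as np

import relgamma as rg

cfg = rg.model1_config(n=200, delta=0.1, outlier_mu=5.0, seed=7)
data, mask = rg.simulate_dataset(cfg)
print(f"simulated n={data.n}, p={data.p}, outliers={mask.sum()}")

gre = rg.fit_relative_error(data, loss="lpre", gamma=0.0)
rob = rg.fit_relative_error(data, loss="lpre", gamma=0.5, method="mm")
cov = rg.sandwich_covariance("lpre", data, rob.beta, gamma=0.5)
ci = rg.wald_interval(cov, rob.beta, level=0.95)

print("\ntrue beta0:         ", cfg.beta0)
print("plain LPRE fit:     ", np.round(gre.beta, 3),
      " <- dragged off by the outliers")
print("gamma=0.5 fit:      ", np.round(rob.beta, 3),
      f" ({rob.n_iterations} MM iterations, monotone objective)")
print("standard errors:    ", np.round(cov.se, 3))
print("95% Wald intervals:")
for j in range(data.p):
    print(f"  beta_{j + 1}: [{ci[j, 0]:.3f}, {ci[j, 1]:.3f}]")
print("\nSquared coefficient error ||betahat - beta0||^2:")
print(f"  gamma=0   : {rg.mse(gre.beta, cfg.beta0):.4f}")
print(f"  gamma=0.5 : {rg.mse(rob.beta, cfg.beta0):.4f}  (smaller = the "
      "robust fit ignores the contaminated rows)")
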