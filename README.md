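# relgamma

Robust relative-error regression for multiplicative models via the
γ-likelihood.

## The problem

Positive outcomes whose errors matter *relatively* — electricity demand,
biomarker concentrations, stock prices — are naturally modelled
multiplicatively:

    y_i = exp(x_i' β) · ε_i,        ε_i > 0 i.i.d. with density h.

Relative-error criteria such as LPRE (least product relative error,
g(a,b) = ab) and LSRE (least squared-sum, g(a,b) = a² + b²) fit β by
minimizing Σ g(|y−t|/y, |y−t|/t) with t = exp(x'β); both are smooth,
convex, scale-free, and correspond exactly to maximum likelihood under a
noise density h(ε) ∝ ε⁻¹ exp(−ρ(ε)).  They are, however, badly damaged by
outliers — in particular responses driven to ~0 or to huge values, where
the relative-error loss diverges.

`relgamma` robustifies these fits with the negative γ-likelihood

    ℓ_{γ,n}(β) = −(1/γ) log( (1/n) Σ_i f(y_i|x_i;β)^γ )
                 + 1/(1+γ) log( (1/n) Σ_i ∫ f(y|x_i;β)^{1+γ} dy ),

where f(y|x;β) = h(y e^{−x'β}) e^{−x'β} and γ > 0 tunes robustness: γ→0
recovers the classical LPRE/LSRE fit, larger γ discounts low-density
observations.  The per-observation estimating contribution f^γ·s
*redescends* — it vanishes as y → 0 or ∞ — so gross outliers lose all
influence.  The package provides:

- **noise models** for LPRE (an index-0 generalized inverse Gaussian,
  constant 1/(2K₀(2)) with K₀(2) ≈ 0.1139), LSRE (constant ≈ 0.911411)
  and user-defined symmetric losses;
- a **monotone MM optimizer**: a Jensen majorizer for the first term and
  a quadratic-bound majorizer (B = (I − 11'/n)/2) for the second give a
  convex surrogate whose minimization provably never increases the
  objective; plus a faster MM→BFGS hybrid with a safe fallback;
- **sandwich inference**: the asymptotic covariance J⁻¹ΔJ⁻¹ of the
  estimator from closed-form (LPRE) or quadrature constants and plug-in
  design moments, with Wald intervals and z-standardization;
- a **simulator** for the validation study (equicorrelated Gaussian
  predictors, GIG noise, log-normal contamination) and a **replication
  harness** (median RPE/MSE with quartiles, z-score normality studies,
  γ-grid selection by held-out relative prediction error, periodic lagged
  designs for day-ahead forecasting).

## Worked example

From `examples/01_robust_fit.py` — n = 200, β₀ = (1,1,1), LPRE noise,
10% log-normal(5, 1) outliers:

```
true beta0:          [1. 1. 1.]
plain LPRE fit:      [-0.047  0.334  0.599]  <- dragged off by the outliers
gamma=0.5 fit:       [0.973 0.855 0.932]  (111 MM iterations, monotone objective)
standard errors:     [0.064 0.093 0.073]
95% Wald intervals:
  beta_1: [0.848, 1.099]
  beta_2: [0.672, 1.038]
  beta_3: [0.789, 1.074]

Squared coefficient error ||betahat - beta0||^2:
  gamma=0   : 1.7000
  gamma=0.5 : 0.0264
```

The classical fit is pulled far from the truth by twenty contaminated
rows; the γ = 0.5 fit recovers β₀ to within sampling error and every 95%
interval covers the true coefficient.  The other examples print the
noise-model constants (`02`), the median-MSE ordering across γ under
contamination (`03`), and γ-selection on a synthetic periodic series with
near-zero dropouts (`04`).

A thin CLI wraps the same library calls:

```bash
relgamma simulate --model model1 --delta 0.1 --seed 0 --out sim.csv
relgamma fit sim.csv --gamma 0.5 --se --out fit.json
relgamma replicate --gammas 0.01,0.5,10 -T 50 --delta 0.1 --out rep.json
```

## Layout

```
src/relgamma/     losses, noise, gre, objective, mm, inference,
                  simulate, experiments, data, cli
examples/         four narrative scripts (see above)
tests/            unit + property + end-to-end validation studies
docs/methods.md   modelling and numerical details
```
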