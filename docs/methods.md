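# Methods

## Model and loss family

The multiplicative regression model is `y_i = exp(x_i'β) ε_i` with
strictly positive i.i.d. noise `ε_i ~ h`.  A symmetric bivariate loss
`g(a,b) = g(b,a)` defines the relative-error criterion
`G(β) = Σ_i g(|y_i−t_i|/y_i, |y_i−t_i|/t_i)`, `t_i = exp(x_i'β)`.
Writing `ε = y/t`, each term is `ρ(ε) = g(|1−1/ε|, |1−ε|)`, so `G` is the
negative log-likelihood (up to constants) of the induced density

    h(ε) = C(g) ε⁻¹ exp(−ρ(ε)) on (0, ∞).

Symmetry of `g` gives `ε ~ 1/ε` in law (`h(1/ε)/ε² = h(ε)`), which makes
the score a martingale and avoids the bias that asymmetric relative-error
losses incur.  Absolute values are used in both arguments of `g`; this is
forced by the symmetry requirement together with the closed-form LPRE
density.  The built-in losses are LPRE (`g = ab`,
`ρ(ε) = ε + 1/ε − 2`) and LSRE (`g = a² + b²`); both are convex and three
times differentiable, which the optimizer and the asymptotics require.
Custom losses must supply `g` and its first/second partials; derivatives
of `ρ` are assembled by the chain rule (never symbolically), and
construction is refused when `ε⁻¹e^{−ρ}` is not integrable.

For LPRE the density is implemented exactly as
`ε⁻¹exp(−ε−1/ε) / (2K₀(2))` — the exponent keeps the `−ε−1/ε` form and
the constant absorbs `e^{−2}` — an index-0 generalized inverse Gaussian.
`K₀(2) ≈ 0.113894`; the LSRE constant `≈ 0.911411` comes from quadrature.
The influence kernel used everywhere is
`u_h(z) = 1 + z h'(z)/h(z) = −z ρ'(z)` (LPRE: `1/z − z`), and
`u_h' (z) = −ρ'(z) − zρ''(z)` supplies Newton curvature
(`−ε u_h'(ε) = ερ' + ε²ρ'' ≥ 0` for convex losses).

## The γ-likelihood

The robust objective is

    ℓ_{γ,n}(β) = −(1/γ) log((1/n) Σ f_i^γ)
                 + 1/(1+γ) log((1/n) Σ t_i^{−γ} C(γ,h)),

with `C(γ,h) = ∫ h^{1+γ}` (Bessel closed form
`K_γ(2+2γ)/(2^γ K₀(2)^{1+γ})` for LPRE, asserted against quadrature).
Internally it is evaluated as `ℓ1 + ℓ2 + C0` with
`ℓ1 = −(1/γ) logΣ f_i^γ`, `ℓ2 = (1+γ)⁻¹ logΣ t_i^{−γ}` and
`C0 = (1/γ − 1/(1+γ)) log n + (1+γ)⁻¹ log C(γ,h)`; every sum of
exponentials is log-sum-exp stabilized and `log f` is computed directly
from `log y − x'β`, so the value is finite for any finite β.  The `1/n`
factors are retained so objective values are comparable across sample
sizes.  The gradient is `X'(w ∘ u_h(ε̂)) − κ X'π` with density-power
weights `w_i ∝ f_i^γ`, softmax `π_i ∝ e^{−γx_i'β}` and `κ = γ/(1+γ)`.
The per-observation contribution `ψ_y = f^γ s`, `s = −u_h(ε̂)x`, is
bounded by `h^γ|u_h|`, which vanishes at both ends of the response axis —
the redescending property that makes gross outliers harmless.

γ has no universal default; the package follows the study design in using
0.5 for simulation work and selects γ on a grid by held-out relative
prediction error in the forecasting workflow.  Values ≫ 1 treat most of
the sample as outliers and destroy efficiency.

## MM optimizer

`ℓ_{γ,n}` is nonconvex even for convex `g`.  Each iteration majorizes the
two pieces at the current iterate β_t:

- `ℓ1`: Jensen's inequality with weights `w_i(t)` gives
  `ℓ̃1(β|β_t) = −Σ w_i(t) log f_i(β) + (1/γ)Σ w_i log w_i` — a weighted
  GRE criterion, convex whenever `g` is.
- `ℓ2`: the log-sum-exp Hessian in `θ_i = −γx_i'β` is dominated by
  `B = (I − 11'/n)/2`, giving the quadratic
  `ℓ̃2(β|β_t) = γ²/(2(1+γ)) β'Mβ − γ/(1+γ) β'(X'π(t) + γMβ_t) + const`
  with `M = X'BX = (X'X − n x̄x̄')/2` (B is never materialized; M is
  β-free and computed once).

Both surrogates dominate their pieces and touch them at β_t, so
minimizing their sum (damped Newton with Armijo backtracking, ridge-damped
retry on a singular Hessian) never increases the objective; the recorded
trace is nonincreasing by construction.  Convergence is declared at
relative objective change ≤ 1e−8 (configurable), max 500 iterations.
Because MM converges linearly, the gradient norm at an objective-change
stop scales like the square root of the tolerance times local curvature —
users needing a small gradient should use the hybrid.  The default start
is the convex GRE minimizer (itself solved by globally convergent damped
Newton), falling back to least squares on `(X, log y)`.  Rank-deficient
designs are refused up front rather than silently regularized.  The
solver contains no randomness: results are a deterministic function of
(data, start).

The hybrid variant runs 10 MM steps (configurable) and then BFGS on the
objective with the analytic gradient; if BFGS fails or ends above the MM
iterate, the result falls back to a pure MM run and says so.  BFGS alone
is faster but start-sensitive; the MM warm start removes that fragility.

## Sandwich asymptotics

With `C(γ) = ∫h^{1+γ}`, `C1(γ) = ∫ε h^γ h' = −C(γ)/(1+γ)` (integration by
parts; the identity doubles as a parenthesization guard and is asserted at
construction), `C2(γ) = ∫u_h² h^{2γ+1}`, and design moments
`Π_k(γ) = ∫x^{(k)} e^{−γx'β₀} π(dx)` (plug-in: empirical averages at the
fitted β), the estimator satisfies
`√n(β̂_γ − β₀) → N(0, J⁻¹ΔJ⁻¹)` with

    J = C·C2(γ/2)·Π0(γ)Π2(γ) − (C+C1)² Π1(γ)Π1(γ)',
    Δ = (C²C2 − κ²C⁴)·Π0(γ)²Π2(2γ)
        + C(C+C1)[C(C+C1) − C(2γ) − C1(2γ)]·Π0(γ)·{Π1(2γ)Π1(γ)' + sym}
        + (C+C1)²[C(2γ) − C²]·Π0(2γ)·Π1(γ)Π1(γ)'.

Δ was derived here by linearizing the two log-of-sums terms of the
objective at β₀ (delta method on the four sample means involved); the
same expression results whether predictors are treated as random or
conditioned on, and it reduces with J to the Fisher information
`I₀ = ∫u_h²h · Π₂(0)` as γ → 0.  The derivation is validated two ways in
the test suite: a Monte-Carlo covariance oracle for the gradient at β₀ at
γ = 0.5, and the empirical covariance of `√n(β̂−β₀)` over 1000 simulated
fits against `n·J⁻¹ΔJ⁻¹`.  LPRE constants use Bessel closed forms —
`C2(γ) = 2^{1−2γ}/((2γ+1)²K₀(2)^{2γ+1}) · [γ(2γ+1)K_{2γ−2}(4γ+2) +
(1+γ+2γ²)K_{2γ−1}(4γ+2)]` — cross-checked against quadrature to 1e−6;
other losses use quadrature throughout.  `K_ν` is evaluated by the
standard special-function routine, itself checked against the integral
representation by quadrature to ~1e−9.

J is inverted by Cholesky; a condition number above 1e12 triggers a
warning.  Wald intervals are `β̂_j ± z·SE_j`; z-standardization against a
known β₀ is exposed for simulation studies only — applied work should use
the intervals.

## Synthetic-data generator

The generator reproduces the validation study design:

- predictors: rows i.i.d. `N(0, (1−ρ)I + ρ11')`, drawn as
  `√(1−ρ)z + √ρ w·1`; ρ ∈ {0, 0.6} are the studied settings;
- noise: LPRE draws from `scipy.stats.geninvgauss(p=0, b=2)` — exactly
  the GIG(0, 2, 2) law of the LPRE density — gated by a KS test against
  the quadrature CDF in the suite; LSRE (and custom) draws by rejection
  on `log ε` with a normal envelope matched to the target's log-scale
  spread (dominating constant found on a dense grid, acceptance rate
  monitored, failure below 1%);
- contamination: each response independently replaced with probability δ
  by a log-normal(μ, σ) outlier; μ = 5 gives gross upper outliers,
  μ = −5 near-zero ones; the true mask is returned for diagnostics only
  (estimators are always judged against β₀);
- packaged configurations: Model 1 (β₀ = (1,1,1)) and Model 2
  (β₀ = six 0.5s, 45 zeros, p = 51), n = 200, LPRE noise, no intercept
  column (configurable overrides).

What the generator does **not** emulate: serial dependence or
heavy-tailed predictors, x-dependent contamination, misspecified noise
families, or an unknown noise scale.  Passing tests therefore demonstrate
correctness of the estimator and its inference under the stated mixture
model, not performance on arbitrary real data.

A single explicitly seeded `numpy` Generator is threaded through all
sampling; replicate seeds in the harness are spawned from a master
`SeedSequence`, so every experiment is reproducible bit-for-bit.

## Experiments

Metrics: `RPE = Σ(y_new − ŷ)²/(y_new·ŷ)` (per term `y/ŷ + ŷ/y − 2`, i.e.
the out-of-sample LPRE loss, symmetric in its arguments) and
`MSE = ‖β̂ − β₀‖²`.  The replication harness simulates fresh training
data per replicate, draws the holdout response from the *clean* density
on the same design, fits every γ on the grid (warm-started from the
shared GRE fit), and aggregates medians with 25th/75th percentiles.
Replicate-level failures are excluded from aggregates but counted; more
than 5% aborts the experiment.  The full-scale study uses 10,000
replicates; the default here is T = 200, which is ample for the
qualitative orderings the package asserts (robust γ beats both the MLE
limit and an over-robust γ under contamination).

The forecasting workflow builds the periodic lagged design
`x_t = (y_{t−d}, …, y_{t−dq})` (rows with incomplete history dropped;
nonpositive series values are refused) and selects γ on a grid by
held-out RPE.

## Numerical choices

- Quadrature on (0, ∞) is always performed on the log axis
  `u = log ε ∈ [−40, 40]` with adaptive Gauss–Kronrod, absolute tolerance
  1e−10–1e−12 and explicit breakpoints near u = 0 so the narrow peak is
  never missed; lpre/lsre integrands decay doubly exponentially.
- `exp` arguments are clipped at ±350 only where the result multiplies a
  quantity that is exactly zero in the limit.
- Degenerate inputs: empty data, nonpositive responses (reported with row
  indices), non-finite predictors, misdeclared intercept columns and
  rank-deficient designs all raise informative errors.
- Intercept handling: a ones column is never added silently; its index
  can be declared so scale-equivariance (σ on y ⇔ +log σ on the
  intercept) is testable and exact.
- JSON outputs round to 12 significant digits and embed the full
  configuration and package version.

## Known limitations

- The nuisance noise scale is fixed at 1 (the intercept absorbs it);
  jointly estimating a scale parameter is out of scope.
- No L1/lasso penalization; the MM surrogate would accommodate it, but
  the solver does not implement it.
- γ-selection by γ-cross-entropy cross-validation is not provided; the
  grid + held-out-RPE procedure stands in.
- Nonsmooth losses (`a+b`, `max{a,b}`) are rejected rather than handled
  by subgradients.
- The sandwich is derived under correct specification (δ = 0); with
  contamination it remains useful for moderate δ and large γ (verified
  empirically via z-score normality), but no formal guarantee is made.
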