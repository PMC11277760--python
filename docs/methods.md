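# Methods

## Setting and notation

A finite universe `U` of `N` units carries a study variable `y`, `p`
auxiliary variables (rows `x_k'` of the `N×p` matrix `X`) and an
instrument matrix `Z` of the same shape. The estimand is the total
`t_y = Σ_U y_k`; the auxiliary totals `t_x = Σ_U x_k` are known. A
SRSWOR sample `s` of size `n` gives every unit inclusion probability
`π_k = n/N`, design weight `d_k = N/n`, joint inclusion probability
`π_kl = n(n−1)/(N(N−1))`, and tuning factors `q_k = 1` throughout (the
`q_k` enter all formulas through `Π_s⁻¹ = diag(q_k d_k)` and are
config-exposed, but only the unit value is exercised).

The working superpopulation model is `y = Xβ + e`, `e ~ (0, σ_e² I)`.
Column `j` of `X` is *endogenous* when `cov(x_j, e) ≠ 0`; its instrument
`z_j` satisfies relevance (`cov(x_j, z_j) ≠ 0`) and validity
(`cov(z_j, e) = 0`). Exogenous columns are their own instruments, so
identification is always exact; passing a `Z` with a different number of
columns raises a not-supported error rather than silently projecting.

## Estimators

* **Horvitz–Thompson** `t̂_HT = Σ_s d_k y_k`; variance estimator
  `N²(1−f) s²_y / n` (`f = n/N`, `s²` the sample variance). This is the
  Δ_kl double sum specialised to SRSWOR; the closed form is used so no
  `n×n` matrix is ever built.
* **Chi-square calibration / GREG**: weights
  `w = d + Π_s⁻¹X_s (X_s'Π_s⁻¹X_s)⁻¹ (t_x − X_s'd)`, equivalently
  `w_k = d_k(1 + q_k x_k'λ)`. The total equals
  `t̂_HT + b̂_s'(t_x − t̂_x,HT)`.
* **General-distance calibration** by Newton iteration on λ with
  `w_k = d_k F(q_k x_k'λ)`; `F(u) = 1+u` (chi-square, one step is exact,
  asserted in tests) and `F(u) = e^u` (raking). Stopping rule: maximum
  relative constraint gap `max_j |Σ_s w x_j − t_xj| / max(|t_xj|, 1)`
  below `tol = 1e−10`; `max_iter = 50`; start `λ = 0`. Non-convergence
  returns the last iterate flagged `converged=False`; a singular
  Jacobian raises. Weights are never clipped or bounded — chi-square
  weights may legitimately be negative.
* **Model-assisted IVC**: `W = d + Π_s⁻¹Z_s μ` with
  `μ = (X_s'Π_s⁻¹Z_s)⁻¹(t_x − X_s'd)`. Note the *transposed* cross-Gram:
  with a non-symmetric `Z_s'Π_s⁻¹X_s` this is the unique solve for which
  the calibration constraint on `X` holds and the weight path agrees
  with the regression path
  `t̂_IVC = t̂_HT + (t_x − t̂_x,HT)'β̂_IVC`,
  `β̂_IVC = (Z_s'Π_s⁻¹X_s)⁻¹Z_s'Π_s⁻¹y_s`. Both paths are computed and
  cross-asserted at 1e−8 relative on every call. Under SRSWOR with
  `q = 1` the constant `q_k d_k` cancels, so `β̂_IVC` coincides with the
  plain IV fit on the sample.
* **Model-based IVC (MBIVC)**: `W_k = 1 + t_x,ns'(Z_s'X_s)⁻¹z_k` with
  `t_x,ns = t_x − Σ_s x_k`; total
  `Σ_s y_k + t_x,ns'β̂_MBIVC`, `β̂_MBIVC = (Z_s'X_s)⁻¹Z_s'y_s`. At a
  census (`t_x,ns = 0`) every weight is 1 and the estimator is exact.

### Variance formulas

* The model-assisted asymptotic variance is the design double sum over
  `Δ_kl = π_kl − π_k π_l` applied to IV residuals. The estimable plug-in
  uses sample residuals `e_k = y_k − x_k'β̂_IVC` in the SRSWOR closed
  form `N²(1−f) s²_e / n`; a population-level evaluator
  (`ivc_population_variance`, given the universe and a slope) provides
  the theoretical value for oracle tests.
* The model-based MSE is reported as the sandwich
  `t_x,ns' A⁻¹ (Σ_s r_k² z_k z_k') A⁻ᵀ t_x,ns`, `A = Z_s'X_s`,
  nonnegative by construction. The residual reference slope defaults to
  `β̂_MBIVC` (computable from the sample); an override parameter accepts
  any reference slope. **Known limitation:** this sandwich captures only
  the *slope-error* component `t_x,ns'(β̂ − β)`. The full error of the
  MBIVC total also contains the non-sample residual sum `Σ_{U−s} e_k`,
  whose contribution `(N−n)σ_e²` typically dominates (e.g. ≈ 800 vs
  ≈ 90 at `N = 1000, n = 200, σ_e = 1`). The sandwich therefore
  understates the total's empirical MSE by roughly an order of
  magnitude on the default population; it is a component estimate, not
  a full-MSE estimate. Analytic bias expressions for the IVC/MBIVC
  totals are not implemented as numeric estimators — the published
  forms are dimensionally inconsistent — and empirical bias from the
  simulation module is the bias surface instead.

### Numerical policy

All `(·)⁻¹` are pivoted LU solves, never explicit inverses. Before each
solve the reciprocal condition number of the matrix is measured by SVD;
below `1e−12` a typed error is raised — `SingularDesignError` for
auxiliary Grams (naming the columns dominant in the near-null singular
vector), `WeakInstrumentError` for instrument cross-Grams (carrying the
condition number). This prevents explosive weights from numerically
irrelevant instruments. Constraint gaps are measured relative to
`max(|t_xj|, 1)` so near-zero totals do not blow up the criterion.

## Synthetic populations

`DGPConfig` defaults: `N = 1000`, `p = 20`, first column endogenous,
`β = 1` in every coordinate, and unit loadings
`δ = γ = σ_e = σ_ν = 1`. For endogenous `j`:

```
z_j ~ N(0,1),   x_j = δ z_j + γ e + ν_j,  ν_j ~ N(0, σ_ν²),
```

giving `Var(x_j) = δ² + γ²σ_e² + σ_ν²`,
`corr(x_j, e) = γσ_e/√Var(x_j)` and `corr(x_j, z_j) = δ/√Var(x_j)` —
both `1/√3 ≈ 0.577` at the defaults: moderate endogeneity, strong first
stage. The unit loadings are a design choice made once where the
benchmark design specifies the structure only qualitatively; they are
config-exposed but the defaults are not revisited. The OLS slope on the
endogenous column then has analytic inconsistency
`γσ_e²/Var(x_j) = 1/3`, a convenient closed-form oracle.

What the generator does *not* emulate: non-normal or heavy-tailed
auxiliaries, heteroskedastic errors, weak instruments, cluster or
stratified structure, item nonresponse. Passing tests on these
populations demonstrates the algebraic and design-based properties of
the estimators, not robustness to those real-data features.

## Monte-Carlo harness

One population is generated per configuration and held fixed; all
randomness across replicates is sampling randomness (this is the
design-based reading of Bias/MSE: `Bias = E(t̂) − t_y` and
`MSE = R⁻¹Σ(t̂_i − t_y)²` over repeated samples). Replicate `r` at
sample size `n` derives its generator from the seed tuple
`(master, n, r)`, so any cell can be reproduced independently and the
whole summary is a pure function of the configuration. Per cell the
harness records mean, bias, MSE, empirical variance (denominator `R`,
so `MSE = variance + bias²` holds as an identity) and `R_effective`;
replicates where an estimator raises a singular/weak-instrument error
are dropped and counted, and a cell losing more than 10% of replicates
aborts the run as a degenerate configuration rather than reporting a
silently truncated average.

Default problem sizes used by the shipped checks: the pattern grid runs
`n ∈ {50, 200}` at `R = 500` and the variance-calibration study
`n = 200` at `R = 2000`, both on the default `N = 1000, p = 20`
population — large enough for stable Monte-Carlo ratios, small enough
to run interactively.

### What the comparison shows

With one endogenous auxiliary at the default loadings, HT pays an order
of magnitude in MSE against any calibrated estimator. Between GREG and
IVC the outcome is a consistency/efficiency trade-off: the design
variance of GREG is driven by the census-OLS residual variance
`σ_e²(1 − γ²σ_e²/Var(x_endog)) = 2/3`, while IVC's is driven by the
structural residual variance `σ_e² = 1`, so under *strong* endogeneity
IVC's MSE runs ~1.3–1.5× GREG's even though its slope is the consistent
one. The two approach equality as the endogeneity loading `γ` shrinks.
Slope recovery is unambiguous: `β̂_IVC` and `β̂_MBIVC` converge to the
true `β` as `n` grows while the GREG slope stays at its shifted plim.

## Degenerate inputs and edge cases

`n = N` (census) makes HT exact, all variance estimators zero, IVC/GREG
weights equal to `d ≡ 1`, and MBIVC weights identically 1. `n < 2`
raises for every variance estimator. `n < p` makes the auxiliary Gram
singular and raises. Ties in drawn indices are impossible by
construction (`choice` without replacement); sample indices are kept
sorted for reproducible output ordering.
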