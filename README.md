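# ivcalib

Instrumental-variable calibration estimation of finite-population totals.

## The problem

Survey statisticians estimate a population total `t_y = Σ_U y_k` from a
probability sample `s` with design weights `d_k = 1/π_k`. When population
totals `t_x` of auxiliary variables are known, *calibration* adjusts the
design weights minimally so that the weighted sample totals of the
auxiliaries reproduce `t_x` exactly; with the chi-square distance this is
algebraically the generalized regression (GREG) estimator

```
t̂_GREG = t̂_HT + b̂_s' (t_x − t̂_x,HT),
b̂_s = (Σ_s d_k q_k x_k x_k')⁻¹ Σ_s d_k q_k x_k y_k .
```

The efficiency of GREG rests on the working model `y = Xβ + e` with
exogenous regressors. When some auxiliaries are *endogenous* —
correlated with `e` — the implicit slope `b̂_s` is inconsistent. The
classical fix is an instrumental variable `z_j` for each endogenous
`x_j` (relevant for `x_j`, uncorrelated with `e`); under exact
identification `Z` has the same shape as `X` (exogenous columns act as
their own instruments) and the IV slope is `β̂_IV = (Z'X)⁻¹ Z'y`.

`ivcalib` carries that idea into the calibration weights themselves:

* **model-assisted IVC** (design-based):
  `W = d + Π_s⁻¹ Z_s μ` with `μ` solved so that `Σ_s W_k x_k = t_x`
  exactly; equivalently `t̂_IVC = t̂_HT + (t_x − t̂_x,HT)' β̂_IVC` with
  `β̂_IVC = (Z_s'Π_s⁻¹X_s)⁻¹ Z_s'Π_s⁻¹ y_s` and `Π_s⁻¹ = diag(q_k d_k)`;
* **model-based IVC (MBIVC)**:
  `W_k = 1 + t_x,ns' (Z_s'X_s)⁻¹ z_k` where `t_x,ns` are the auxiliary
  totals over the non-sampled units, giving
  `t̂_MBIVC = Σ_s y_k + t_x,ns' β̂_MBIVC`, `β̂_MBIVC = (Z_s'X_s)⁻¹ Z_s'y_s`.

Both calibrate exactly on `X`, reduce to GREG / projection weights when
`Z = X`, and come with plug-in variance formulas (SRSWOR closed form for
the model-assisted variance; a sandwich form for the slope-error part of
the model-based MSE). The package also provides the Horvitz–Thompson
baseline, a synthetic-population generator with a configurable
endogeneity first stage, and a Monte-Carlo harness that tabulates Bias
and MSE per estimator × sample size.

It is written for survey methodologists and biostatisticians who want
to study — or apply — calibration weighting when registry or covariate
data are suspected to be endogenous.

## Worked example

`examples/endogeneity_and_instruments.py` draws 100 000 units from the
default process (20 standard-normal auxiliaries, the first one endogenous
through `x_1 = z_1 + e + ν`, true slope 1 everywhere) and fits both slopes:

```
true slope on every column: 1.0
OLS slope on endogenous x1: 1.3324  (analytic plim 1 + 0.3333 = 1.3333)
IV  slope on endogenous x1: 1.0042
OLS slope on exogenous x2:  0.9965  (unaffected)
```

OLS lands on its analytic inconsistency `γσ_e²/Var(x_1) = 1/3`; the IV
slope is consistent. `examples/monte_carlo_comparison.py` then compares
the total estimators over 300 repeated SRSWOR draws from one fixed
N = 1000 population:

```
 Sample Size Estimator         Bias          MSE
          50      GREG       23.219     8260.386
          50        HT       -1.003   504796.674
          50       IVC       27.181    12502.443
          50     MBIVC       49.449     3115.218
         200      GREG        3.319     2494.689
         200        HT        6.785    95855.420
         200       IVC        3.271     3805.027
         200     MBIVC       40.749     1921.217
```

HT ignores the auxiliaries and pays more than an order of magnitude in
MSE; the calibrated estimators exploit `t_x`. The IVC slope is the
consistent one under endogeneity, while GREG's census-fit slope
minimises design variance — the classic consistency-versus-efficiency
trade-off, visible in the MSE columns. See `docs/methods.md` for the
full account.

The other examples cover the generator and its diagnostics, the
calibration weight families, and the estimate-from-data path
(`run_estimate`) that works on any user CSV. A thin CLI wraps the same
functions:

```
ivcalib generate --seed 7 --out-dir out/
ivcalib estimate --config est.yaml --out-dir out/
ivcalib simulate --config sim.yaml --seed 1 --out-dir out/
```

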