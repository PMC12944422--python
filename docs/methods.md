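# Methods

## The problem

A method-comparison study asks whether two instruments measuring the same
quantity — here, skin temperature of the hand dorsum in °C — agree closely
enough to be used interchangeably. The design this package targets is a
repeated-measures protocol: each participant is measured with both a test
instrument (a smartphone-attached thermal camera) and a reference
instrument (a non-contact infrared thermometer) in two rounds, a stable
round (R1) and a dynamic round (R2) with repositioning between readings,
with 15 replicates per device per round. All statistics are defined on the
paired difference `d = t_test − t_ref`; a negative bias means the test
instrument reads low.

## Agreement statistics

* **Precision** is the intra-participant sample SD (n−1 denominator) of the
  replicates in each (participant, device, round) cell, averaged across
  participants per device and round.
* **Bland–Altman**: bias = mean(d), 95% limits of agreement
  `bias ± 1.96·SD(d)`. The multiplier is fixed at 1.96 (the large-sample
  normal quantile), not the t-based small-sample variant. The default
  analysis level is one unit per participant (the per-participant mean
  reading of each device within a round), which is the conventional unit
  for a single reported bias/LoA in replicated designs; a replicate-level
  option exists because some published analyses use replicate pairs.
* **ICC(2,1)** — two-way random-effects, absolute-agreement,
  single-measurement form, computed from the two-way mean squares
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` on the
  participants × devices matrix of per-participant means. Absolute
  agreement (rather than consistency) is the right form here because a
  constant offset between devices *is* a disagreement.
* **Inference**: Shapiro–Wilk gates the normality assumption at α = 0.05;
  paired and one-sample t-tests are two-sided; the one-way ANOVA of
  per-participant bias across a grouping factor (e.g. skin phototype)
  checks whether bias varies systematically with that factor.

Degenerate inputs (zero-variance differences, constant matrices, cells
with one replicate) raise typed errors rather than returning NaNs.

## Synthetic study generator

Per participant `p` and round `r`:

```
mu_pr  ~ N(pop_mean_r, pop_sd^2)          true skin temperature
b_p    ~ N(0, sigma_b^2)                  participant-specific device bias
ref_i  = mu_pr + N(0, ref_noise_r^2)
test_i = mu_pr + beta0_r + beta1*(mu_pr - pop_mean_r) + b_p
         + N(0, test_noise_r^2)
```

Readings are quantised to the display resolution (0.1 °C) and the
reference can optionally be clamped to its measurement range (32–42.9 °C;
off by default for statistical transparency). Each participant draws from
an independent seeded substream, so enlarging the cohort never reshuffles
existing participants.

**Why this bias structure.** The study conditions report a difference SD
(~1.54 °C, implied by the printed LoA) that far exceeds the combined
replicate noise (~0.34 °C). That excess has to live *between* participants,
which forces the random effect `b_p`. The documented over-reading at low
temperatures and under-reading at high temperatures (an X-shaped
difference-versus-mean pattern) is the simplest kind of
temperature-dependent bias, a negative linear slope `beta1` on the centred
true temperature.

**Defaults.** Round-level parameters are taken directly from the emulated
study conditions: population means 35.50/34.08 °C, offsets β0 =
−1.42/−1.15 °C, reference noise 0.030/0.093 °C, test noise 0.340/0.300 °C
(R1/R2). The free components are *moment-matched*, not hand-picked: with
the closed forms

```
sd_diff^2 = beta1^2 pop_sd^2 + sigma_b^2 + test^2 + ref^2
r         = (1+beta1) pop_sd^2 /
            sqrt(((1+beta1)^2 pop_sd^2 + sigma_b^2 + test^2)(pop_sd^2 + ref^2))
```

`match_variance_components` solves for `(pop_sd, sigma_b)` such that the
round-1 implied difference SD is 1.5408 °C and the implied between-device
Pearson correlation is 0.788, given β1 = −0.44 (a slope consistent with
the reported over/under-reading ranges). This yields pop_sd ≈ 2.48 °C and
σ_b ≈ 1.03 °C. A between-participant spread of ~2.5 °C is realistic for
hand-dorsum skin temperature, which varies far more across people than
core temperature does.

**What the generator does not emulate.** (1) Physical radiometry —
emissivity, distance, sensor drift; noise is purely statistical. (2)
Device-specific response to the environmental change between rounds: the
true temperature change `mu_p,R2 − mu_p,R1` is shared by both devices, so
the generator produces a strongly *positive* between-round change
correlation, whereas studies of this device class have observed near-zero
change correlation (device-specific drift dominating). Passing tests on
generated data therefore validate estimator correctness and the
bias-versus-noise decomposition, not every empirical feature of real
thermal-camera data.

## Calibration models

All ten models share one contract: fit on `(t_test, t_ref)` pairs, predict
a calibrated temperature for any finite input, record the training domain
and flag extrapolation. Quantile models expose a (2.5%, 50%, 97.5%)
triplet with crossings repaired by per-point sorting; point estimators get
conformal intervals downstream.

* **Polynomial + Huber** (degree 2, ε = 1.35, ridge α = 0): robust to
  outliers; columns are standardised before fitting so the penalty and the
  Huber scale are well-behaved. Reduces to least squares when all residuals
  fall within ε·scale.
* **Deming regression**: both instruments are noisy, so ordinary least
  squares of `t_ref` on `t_test` attenuates the slope by roughly
  `var(signal)/var(signal + x-error)`. The Deming slope

  ```
  beta = (s_yy − δ s_xx + sqrt((s_yy − δ s_xx)^2 + 4 δ s_xy^2)) / (2 s_xy)
  ```

  uses δ = Var(y-error)/Var(x-error), estimated from the data as the ratio
  of pooled within-participant replicate variances
  (reference/test — the response is the reference). δ → ∞ recovers OLS of
  y on x; δ → 0 the inverse of regressing x on y.
* **Isotonic regression**: exact pool-adjacent-violators solution of
  monotone least squares; linear interpolation between knots, constant
  boundary extension. Monotonicity is a physical constraint — a hotter
  surface cannot yield a lower calibrated reading.
* **Spline + Huber**: natural cubic spline basis (truncated-power
  construction with the natural constraints absorbed; linear beyond the
  boundary knots) with 6 knots at empirical quantiles of x, fit by IRLS
  under Huber loss. Scale is re-estimated each pass as 1.4826 × median
  absolute residual; convergence when the max coefficient change drops
  below 1e-8, capped at 200 iterations.
* **LOESS** (frac = 0.25, 1 robustness pass): local degree-1 weighted
  least squares over the ⌈frac·n⌉ nearest neighbours with tricube
  weights, bisquare reweighting between passes, evaluated by a fresh local
  fit at each query point. Written in-package because the available lowess
  implementations cannot combine robustness iterations with evaluation at
  arbitrary points.
* **Weighted spline**: isotonic pilot → residual variance in 10
  equal-count x-bins (floored at 1e-6 °C² so noiseless data cannot produce
  infinite weights) → inverse-variance weighted natural-spline fit. This
  addresses heteroscedastic error without trusting any single bin too far.
* **Quantile GBRT** (400 trees, rate 0.05, depth 3): one boosted model per
  quantile under pinball loss; the median model is the point predictor.
* **Monotone boost** (600 trees, rate 0.03, 31 leaves): a LightGBM median
  (0.5-pinball) booster whose fitted curve is then projected onto the cone
  of non-decreasing functions by isotonic regression on the training grid.
  Boosting libraries cannot enforce hard monotone constraints under
  non-smooth pinball objectives (they either refuse or leave residual
  violations), while the projection is the exact least-squares
  monotonisation of the boosted curve — predictions on any sorted grid are
  non-decreasing by construction. Unconstrained 0.025/0.975 boosters
  supply the interval.
* **Random forest / extra trees** (400 trees, min leaf 5; bootstrap
  on/off respectively): variance-reducing ensembles; predictions are
  bounded by the training response range and constant beyond the training
  domain.

All stochastic fits take a master seed from the `CalibratorSpec`, so any
fit is bit-reproducible.

## Evaluation protocol

Replicates of one participant are strongly dependent (shared `mu_pr` and
`b_p`), so row-wise cross-validation would leak participant identity into
the test folds and flatter every model — a 1-nearest-neighbour memoriser
makes this visible, with out-of-fold error several times its
resubstitution error. All evaluation therefore uses **grouped k-fold by
participant** (5 folds by default, deterministic given a seed, fold sizes
within one participant of each other). Metrics — MAE, RMSE, R², bias, and
Bland–Altman LoA of the prediction errors `y_pred − t_ref` — are computed
on pooled out-of-fold predictions. Both rounds are pooled for calibration
by default (a per-round option exists), and every model in a suite run
shares the identical fold assignment.

Hyperparameter search is an exhaustive grid over the documented search
ranges, selected by out-of-fold MAE with ties broken by RMSE then grid
order. Selection uses the same (flat) fold layer as the reported metrics;
this mildly optimistic coupling is standard when only one CV layer is
described, and the grids are small.

**Prediction intervals.** Quantile models use their own 0.025/0.975
outputs. Point estimators use split-conformal absolute-residual intervals:
with `m` calibration residuals, the radius is the ⌈(m+1)(1−α)⌉-th smallest
absolute residual (infinite when the index exceeds `m`), giving a marginal
coverage guarantee ≥ 1−α for exchangeable data. Deployment refits use the
full dataset for the point model and out-of-fold residuals as the
conformal calibration set, so calibration residuals remain exchangeable
with deployment errors. Coverage is marginal, not
participant-conditional.

## Numerical choices and problem sizes

* SDs use the n−1 denominator throughout; p-values are two-sided; α = 0.05.
* Quantile-crossing repair: per-point sorting (the simplest
  order-restoring operator).
* Spline knots at empirical quantiles, with duplicate knots collapsed
  (quantised data can tie).
* Degenerate LOESS neighbourhoods (all identical x) raise an error rather
  than silently averaging.
* Test-suite and acceptance simulations use the study's own design sizes
  (40 participants × 2 × 2 × 15) for pipeline checks, 1000 participants
  for parameter-recovery checks, 100,000 draws for the LoA capture rate,
  200 replicate simulations for conformal coverage, and a 10,000/10,000
  train/test split for quantile-coverage checks — sizes at which
  Monte-Carlo error is comfortably below the asserted tolerances.

## Known limitations

* The generator's linear-plus-random-effect bias model is the simplest
  structure matching the targeted moments; real thermal-camera error
  includes drift, ambient sensitivity and emissivity mismatch that it does
  not represent.
* Calibration is univariate (`t_test` only); ambient temperature,
  distance and emissivity covariates are out of scope.
* The repeated-measures LoA variance-component correction (Bland–Altman
  for replicated data) is deliberately not implemented; the simple formula
  is used at a chosen analysis level instead.
* ICC and correlation are reported on per-participant means by default;
  replicate-level values will differ when within-participant noise is
  large relative to between-participant spread.
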