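# Methods

## Model

Each participant's hourly MET-minutes series y_t (165 points, hour 0 =
midnight of day 2) is modelled as SARIMA(p,1,q)(P,1,Q)[24]: after the
regular and seasonal differences w_t = (1−B)(1−B²⁴) y_t (140 effective
observations), w follows the multiplicative seasonal ARMA

  φ(B) Φ(B²⁴) w_t = θ(B) Θ(B²⁴) ε_t,   ε_t ~ iid N(0, σ²),

with no constant (any deterministic level and any fixed 24-hour profile
are annihilated by the double difference).  MA sign convention: θ and Θ
enter with a plus sign on the innovation side.  The candidate grid fixes
d = D = 1 and m = 24 and varies p, q ∈ {0..3}, P, Q ∈ {0,1}: 64 models,
numbered 1..64 in lexicographic (p, q, P, Q) order.

## Estimation

σ² is profiled out in closed form, so the optimizer works on the
concentrated likelihood of the p+q+P+Q AR/MA weights.

Two objectives are implemented:

* **Conditional sum of squares (CSS)** — innovations computed recursively
  through the expanded lag polynomials with zero pre-sample values
  (`scipy.signal.lfilter`); fast and used to produce starting values.
* **Exact Gaussian likelihood (default)** — Kalman filter on the Harvey
  companion state space of the differenced ARMA, with the stationary
  initial covariance solved by a doubling iteration for the discrete
  Lyapunov equation, and a frozen steady-state gain once the covariance
  recursion converges (tolerance 1e−12).  The filter loop is numba-compiled.

Exact likelihood was made the default because at 140 effective
observations a 24-lag seasonal MA is informed by fewer than six seasonal
cycles, where the CSS objective differs materially from the exact one
(weight differences approaching 0.1 against an exact-ML reference); the
exact objective agrees with an independent state-space implementation to
~1e−4 in the weights on the same data.

Optimization is deterministic L-BFGS-B (ftol 1e−9, max 500 iterations,
numerical gradients) started from the CSS solution; for redundancy-prone
specs (both p>0 and q>0, or P=Q=1) a second deterministic start is derived
Hannan–Rissanen style (long-AR innovations proxy, then one least-squares
pass), because near-common-factor configurations such as an ARMA(2,2) fit
to ARMA(1,1)-like data have a multimodal likelihood.  If the optimized
objective is ever worse than the all-zero start, the fit is redone from
zero and the better result kept, so the reported likelihood never falls
below the white-noise start.

Box bounds per coefficient follow the polynomial structure: a degree-k
polynomial with roots outside the unit circle has |c_i| ≤ C(k, i), so an
AR(2) admits φ₁ up to 2 — per-coefficient bounds of ±0.99 would cut off
legitimate optima.  After convergence each factor polynomial
(non-seasonal AR/MA, seasonal AR/MA) must have all roots outside the unit
circle with margin 1e−3; seasonal factors are checked through their roots
in u = B²⁴ (|u| > (1+margin)²⁴), and degrees ≤ 3 use closed-form
Schur–Cohn conditions rather than an eigenvalue root find.  A fit that
ends on a bound, fails the root margin, or does not satisfy the optimizer's
convergence test is flagged `converged = False` and assigned AIC = +∞: it
is reported but can never be selected.

AIC = 2k − 2 log L with k = p+q+P+Q+1 (σ² counts; no constant is fitted).
Ties are broken by fewer weights, then enumeration order.

## Preprocessing rules

* Non-wear: every maximal run of exactly-zero minutes.  A zero minute is
  indistinguishable from true rest in this convention; all zero runs are
  treated as non-wear.
* Exclusion: any run of **31 or more** minutes ("more than 30") excludes
  the participant; a 30-minute run is retained.  Exclusion is monotone in
  gap growth.
* Imputation: each retained run is filled, every minute, with the mean of
  the up-to-15 *pre-imputation, observed* minutes immediately preceding
  the run; fewer than 15 preceding observed minutes truncate the window;
  a gap at the series start falls back to the first observed value (logged
  as degenerate).  Using only pre-imputation values avoids chaining
  imputed data and makes the operation idempotent.
* Binning: left-closed clock-hour bins from midnight of day 2; the window
  ends at 21:00 of day 8, so 6·24 + 21 = 165 bins; a series that does not
  cover the window raises a coverage error rather than producing a short
  vector.

## Synthetic cohort generator

The generator emulates the data the analysis assumes, not raw device
output:

* **Hourly process**: a stationary ARMA (the configured weights, Gaussian
  innovations, 340-step burn-in) is integrated back over both differences
  with the first 25 integrated values set to zero, and added to a fixed
  24-hour baseline profile (default: ~60 MET-min at night rising to ~170
  at midday).  Weights are validated for stationarity/invertibility before
  simulation, with the offending polynomial named on rejection.
* **Floor**: cohort generation clips wear-time hours from below at a rest
  level of 30 MET-minutes (0.5 MET) rather than 0, because an exact zero
  is the non-wear code; exact zeros come only from injected gaps.  With
  the default innovation SD of 1.0 MET-min about 5–10% of hours touch the
  floor — the doubly integrated process drifts with variance growing
  super-linearly in t, so no innovation scale both matters dynamically and
  keeps the week-long path strictly inside the physical range.  This
  truncation is a deliberate, mild misspecification; oracle tests that
  check the ARMA structure itself (ACF agreement, parameter recovery,
  reference-implementation equivalence) disable clipping instead.
* **Minutes**: each hour's total is split over 60 minutes by a symmetric
  Dirichlet (concentration 8), with the last minute absorbing the
  floating-point remainder so re-aggregation is exact.  Only the hourly
  sum is analytically relevant.
* **Non-wear injection**: Poisson-count gaps per day, uniform lengths
  (short 5–25 min, long 31–90 min), placed uniformly; runs are zeros, not
  missing codes.  A participant designated analyzable re-draws placements
  that would accidentally merge short runs into a >30-minute run; the
  `study_design()` preset (66 participants, exactly 22 forced to carry a
  missing period) therefore reproduces its 22/44 split exactly.
* **Scores**: scale = intercept + β·(true weights) + N(0, noise_sd), with
  the default β per scale taken from the published per-scale regression
  estimates and intercepts at typical student-population means; clipping
  to the instruments' ranges (BDI-II 0–63 etc.) exists but is off by
  default.  Per-participant generating weights are drawn from a small pool
  of model structures (40% (1,1,1)(0,1,1), 20% (2,1,2)(0,1,1),
  20% (3,1,3)(1,1,1), 20% (0,1,1)(1,1,1)) with Gaussian jitter (SD 0.12)
  re-drawn into the admissible region, so all eight feature slots vary
  across a cohort and the score regression is identifiable.

What passing tests on this generator do **not** show about real data: real
activity is bounded and non-Gaussian, its non-wear is not Poisson, real
minute-level structure is autocorrelated rather than Dirichlet-exchangeable,
and a real cohort's innovation scale is far larger relative to the diurnal
profile than the generator's (the generator trades amplitude realism for
an exactly-known generating process).

## Association stage

Per scale, OLS with intercept on the 8 raw (unstandardized) weights:
slopes, two-sided t p-values, R², overall F = (R²/8)/((1−R²)/(n−9)) with
p from F(8, n−9), VIFs on the 8 predictors (intercept excluded), and
centered partial residuals (x_ij − x̄_j, e_i + β_j(x_ij − x̄_j)) whose OLS
slope equals β_j.  Significance threshold 0.05 per scale with no
multiple-testing correction by default (an explicit Bonferroni/Holm
adjustment of the five overall F p-values is available).  Rank deficiency
raises an error naming the collinear columns; the pipeline additionally
offers `drop_constant` for small cohorts in which no selected model used
some order (the column is then identically zero).

## Power analysis

Fixed-effects multiple-regression F test, noncentral-F formulation with
λ = f²·N: power = P(F′(u, N−u−1, λ) > F_crit(α)).  At f² = 0.35, α = 0.05,
u = 8, the smallest N with power ≥ 0.8 is 52 (achieved 0.8089 → 0.81);
power at the post-exclusion sample of 44 is 0.71.  The Monte-Carlo
cross-check scales the simulated signal so the *realized* noncentrality
equals f²·N per replicate, matching the fixed-design convention (with
random designs the rejection rate falls a few points below the formula —
that is a property of random-X power, not an error in either number).

## Problem sizes used in the checks

Reference-implementation agreement uses ten 165-point series × eight
identified specs (tolerances |Δweight| ≤ 0.05, |ΔAIC| ≤ 2; degenerate
common-factor specs such as ARMA(2,2) on ARMA(1,1) data are excluded
because their MLE is not unique, and any two correct implementations can
disagree there).  Parameter recovery uses 50 seeds at 165/2000/5000
points; selection consistency 20 seeds × the full 64-model grid; the
F-test size 600 null replicates; pipeline demonstrations run 12-participant
cohorts.  These sizes were chosen to make the checks statistically
meaningful while keeping a full run in the minutes range.

## Known limitations

* The exact-ML engine fits only the models in this study's design space
  (no constant, d = D = 1 in the generator; the engine itself accepts any
  small orders but has no exogenous regressors or forecasting).
* AIC selection at 140 effective points is noisy; the per-participant
  "best" model should be read as a summary statistic, not a discovered
  truth — the package's own selection-consistency check shows ~85% P
  recovery under strong seasonal signal, not certainty.
* Regressing scores on *estimated* weights is an errors-in-variables
  design; slopes are attenuated relative to the generating values.  Exact
  recovery is only claimed (and tested) for regression on the true
  weights at zero outcome noise.
* The imputation rule carries the previous activity level into the gap;
  across hour boundaries with steep profile ramps this biases the gap
  hour's total toward the earlier hour.
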