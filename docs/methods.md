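# Methods

This note documents the models, the simulation design, the numerical
choices, and the limits of what the package's passing tests demonstrate.

## Data-generating processes

All three system types are built from i.i.d. standard-normal innovations
and share one measurement idea: an instrument observes a latent process
through a loading plus additive noise.

* **I(0)** — two independent stationary AR(1) series,
  y_t = β y_{t−1} + u_t with |β| < 1, defaults β₁ = −0.5, β₂ = −0.2
  (the package's worked stationary example). Stationary components start
  from state 0 and discard a burn-in of 50 points to remove the
  initialization transient; random walks start at 0 with no burn-in, since
  they have no stationary distribution to reach.
* **CI(1)** — a shared unit random walk x_t with
  y₁ = b₁x + u₁, y₂ = b₂x + u₂ and standard-normal noise u. The
  combination y₁ − (b₁/b₂)y₂ is stationary by construction, so the
  cointegrating vector is (1, β₀)′ with β₀ = −b₁/b₂. Table conditions use
  b₁ = b₂ = 1 (β₀ = −1).
* **I(1)** — the same construction with *independent* random walks:
  y_i = b_i x_i + u_i, defaults b₁ = b₂ = 1. The noise term matters: the
  differenced series are MA(1), which a VECM with one lagged difference
  cannot fully whiten, so the rank test's finite-sample size at T = 100
  runs near 3–4% at the nominal 1% level. That is the realistic regime for
  measured psychological data (an instrument never observes the latent
  trend noise-free) and is what the replication harness reproduces. Pure
  random walks — whose size is far below nominal (< 1%) — remain available
  via `simulate_ar1(beta=1)`.

Seeding: one master `SeedSequence` spawns independent child streams per
replication, and within a replication separate streams drive the
generator, the two ordinal-cut draws, and the missingness draw, so any
replication can be re-run in isolation bit-identically.

## The rank test

`fit_vecm` implements the reduced-rank regression with the levels entering
at lag 1 (transitory form) and one lagged difference by default — the
minimal admissible order for VAR(1) generators; with no deterministic
regressors in the cointegrating relation this parameterization has exactly
the same eigenvalues and trace statistics as the long-run form because the
regressor spans coincide. An **unrestricted intercept** is included in the
short-run dynamics, matching the default of standard VECM software, and
the embedded critical values (6.50/8.18/11.65 for one common trend,
15.66/17.95/23.52 for two, at 10/5/1%) are the corresponding trace-table
entries — note 8.18 and 11.65 are squares of the demeaned Dickey-Fuller
quantiles, as the n − r = 1 case requires. Simulated null quantiles at
T = 100 (15.9/18.3/23.1) confirm the match; without the intercept the null
quantiles collapse to 10.8/12.7/16.5 and the table would be far too
conservative.

The generalized eigenproblem is solved with `scipy.linalg.eigh` on the
symmetrized matrix pair, eigenvalues clipped into [0, 1); eigenvectors
carry the b′S₁₁b = I normalization, so α = S₀₁β directly. β̂₀ is the
second component of the leading eigenvector divided by the first; if the
first component's magnitude is below 1e−10 the replication is reported as
a failure rather than normalized. β̂₀ is recorded for every cointegrated
replication regardless of the rank decision — identification accuracy and
estimation accuracy are separate indicators. T in the statistic is the
number of usable rows after lagging, never the intended length. Moment
matrices with condition number above 1e12 or non-positive determinant
raise a `DegenerateInputError`.

The sequential decision tests r = 0 and then r ≤ 1, stopping at the first
non-rejection; ranks 0/1/2 map to I(1)/CI(1)/I(0).

## The ADF test

`adf_test` fits Δy_t = c + τt + ρy_{t−1} + Σφ_j Δy_{t−j} + a_t by OLS
(deterministic terms per `spec`), tests ρ = 0 one-sidedly, and
interpolates the p-value bilinearly (sample size × probability) in the
embedded finite-sample tau quantile tables, clipping to [0.01, 0.99].
Defaults — trend specification, lags = ⌊(T−1)^(1/3)⌋ — mirror the common
applied diagnostic workflow. With no lags and no deterministics, ρ̂ equals
the OLS AR(1) coefficient minus one exactly; the suite asserts this
algebraic identity and checks empirical size (5% on random walks) and
power by simulation.

## Degradation operators

The pipeline order is generate → discretize/scale → bound → inject
missingness → listwise deletion: a bounded instrument administered on some
days.

**Scales.** Cut points are anchored on the *pooled* realized range of both
components — one questionnaire spans the phenomenon, and random walks have
no fixed theoretical range that could anchor it instead. Pooled anchoring
is load-bearing: it keeps the two components' effective measurement slopes
equal (so scaling barely inflates the β̂₀ IQR for cointegrated pairs) while
a component occupying only part of the shared range gets fewer effective
categories (so coarse scales strongly inflate I(1) misclassification).
Per-series anchoring produces the opposite, empirically wrong, pattern.
Interval scales use equal-width bins, half-open, last bin closed. Ordinal
scales place k − 1 unequally spaced cuts; the four spacing schemes are:
random — relative widths i.i.d. uniform(0.5, 1.5), drawn independently per
component; increasing/decreasing from the median — widths geometric in the
distance from the middle with the extreme-to-middle ratio fixed at 8
regardless of k; monotone — geometric left to right with end-to-end ratio
12. Holding the *total* inequality fixed (rather than a per-step ratio)
means adding scale points refines resolution without changing the
instrument's overall nonlinearity, which is what makes a 10-point ordinal
scale behave more benignly than a 7-point one. "Pooled" ordinal conditions
cycle the four schemes across replications in equal proportion.

**Rounding.** Discrete-data conditions round the continuous values to the
nearest whole number, keeping the original numeric range.

**Missingness.** Both components are unobserved at the same occasions (a
skipped diary day). Regular mode clears occasions k, 2k, …; random mode
clears a simple random sample of ⌊pct·T⌋ occasions. Listwise deletion then
concatenates the remainder, and downstream tests treat the result as
equidistant — that distortion is the object of study, not a bug. Under
synchronized deletion the β̂₀ estimates stay unbiased even at dense
regular deletion; only dispersion grows.

**Ceiling/floor.** `merged_fraction` is the proportion of the 10 scale
points drawn into the merge — an instrument property, independent of the
sample: a 40% ceiling summarizes the values 7–10 into 7, a 50% ceiling
maps everything at or above 6 to 6, `side="both"` applies half the
fraction per tail. A trending series that lives entirely inside the merged
zone becomes constant; this is the ceiling pathology itself, and such
replications (about 10% of integrated systems at the 50% ceiling, ~1% of
them at a 3-point scale) are excluded from the summaries and reported in
`MCRow.failures`. The harness aborts if a condition's failure rate exceeds
`max_failure_frac` (default 0.30, sized to admit the harshest ceiling
condition). Misclassification percentages keep the full replication count
as denominator.

## Quality indicators

Per true type, misclassification is the percentage of replications whose
estimated type differs (correct% + wrong% + failed% = 100 exactly). Over
cointegrated replications: mean, median, interquartile range
(linear-interpolation quantiles), and %OUT — the percentage of estimates
outside the boxplot fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR]. The shorthand
"median ± 1.5 IQR" describes the same band only approximately (for a
symmetric distribution the fences sit at median ± 2·IQR); the fence
definition is the one whose outlier rates match a normal-ish estimate
distribution at the 3–5% level that the tables show.

## Problem sizes and runtime

Default table conditions: T = 100 intended observations, 1% level, 1000
replications per system type per condition; the sample-size sweep uses
500 replications per length over T ∈ {30, 50, 70, 100, 200, 500}. One
full table (5–9 conditions × 3 types × 1000 replications) runs in about
ten seconds on one CPU; the acceptance script's six quantities complete in
well under a minute.

## What the synthetic data do and do not show

The generators emulate: latent AR(1)/random-walk/common-trend dynamics
observed through a noisy instrument, Gaussian innovations, k-point
interval and ordinal response scales anchored on the observed range,
synchronized missing occasions, and boundary category merging. They do not
emulate: item-level questionnaire aggregation, non-Gaussian or
heavy-tailed innovations, time-varying parameters, asynchronous
missingness between partners, deterministic trends or drifts, systems of
more than two variables, or explosive dynamics. Conclusions from passing
tests therefore speak to measurement-scale and missingness effects on rank
identification under these idealized dynamics, not to misspecification of
the dynamics themselves.

## Known limitations

* The ordinal spacing constants (total ratios 8 and 12) and the ceiling
  boundary rule are concrete instantiations of qualitative design
  descriptions; they are exposed as module constants and `BoundSpec`
  parameters for sensitivity analysis.
* Under the participation semantics adopted for ceilings, the
  cointegrated-system misclassification at the harshest (50%) ceiling runs
  milder than its reference value; the boundary-rule family that matches
  it instead overshoots integrated-system misclassification.
  No single rule reproduces both columns; the trade-off is documented in
  the test suite.
* p-values of the ADF test come from table interpolation, not a response
  surface; they are adequate for 1–10% decisions, not for tail precision.
* The critical-value table covers bivariate systems only (k = 2), matching
  the package's scope.
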