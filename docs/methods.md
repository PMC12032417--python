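# Methods

## The analysis problem

A 24-h day is partitioned into five behaviors: sleep period, sedentary time
(SB), standing, light physical activity (LPA) and moderate-to-vigorous
physical activity (MVPA). Daily minutes in these behaviors form a
*composition*: they always sum to 1440 min, so only relative information is
meaningful and raw minutes are perfectly collinear. The package asks how
day-to-day and person-to-person differences in this composition relate to
daily outcomes (affect valence, energetic arousal, calmness on 0–100 visual
analogue scales; working-memory accuracy in percent), and what change in an
outcome is expected when a fixed number of minutes moves from one behavior
to another.

## Compositional geometry

All modelling happens in isometric log-ratio (ilr) *pivot coordinates*.
For parts taken in a chosen order with part 1 the pivot,

    z_k = sqrt((D-k)/(D-k+1)) · ln( x_k / gmean(x_{k+1}, …, x_D) ),  k = 1..D-1,

so the first coordinate is the (scaled) log-ratio of the pivot part against
the geometric mean of everything else — "MVPA relative to the remaining
behaviors" when MVPA is the pivot. Natural logarithms throughout. The
contrast matrix is orthonormal, which gives three properties the tests
exercise: the map is an isometry (ilr distance = Aitchison distance), it is
scale invariant, and any two pivot orders are related by a fixed orthogonal
matrix `Q` (`rotate_basis`). The last property lets one model fit report
both the MVPA-first and the SB-first first coordinates by rotating the
coefficient draws (`β' = Qβ`), instead of refitting; a test verifies the
rotated summary agrees with an independent refit within Monte-Carlo error.

Coordinates 2..D-1 depend on how the non-pivot parts are ordered; the
package fixes them to canonical label order (`pivot_order`). The first
coordinate — the only one reported as a named contrast — does not.

Zero minutes are rejected at closure with an error naming the part, because
the day-level inclusion filters make all parts positive in valid data; an
optional additive offset (`close(..., offset=...)`, default off) exists for
degenerate synthetic rows.

## Between/within decomposition

Each person's compositional mean is the *geometric* center of their days
(closed per-part geometric mean), not the arithmetic mean of minutes. In
ilr space the geometric center is exactly the arithmetic mean of the day
ilr vectors, so the decomposition

    ilr(day) = between(person) + within(person, day)

is an exact identity with within-deviations summing to zero per person
(tested at 1e-9 on a study-scale table). Arithmetic-mean centering would
break both identities. The sample reference composition used for
substitution estimates is the geometric center of the per-person means,
each participant weighted equally regardless of day count; a pooled-days
variant is available (`method="pooled"`).

Days with a missing outcome still contribute to the person's compositional
mean; they drop only from the model rows (complete-case analysis).

## The multilevel model

For outcome `y` of person `i` on day `j`:

    y_ij ~ Normal(μ_ij, σ)
    μ_ij = β0 + βB'·zB_i + βW'·zW_ij + γ'·c_ij + u0_i + uW_i'·zW_ij
    (u0_i, uW_i) ~ MVN(0, Σ_b)           — random intercept + within slopes

Covariates `c` are baseline age, sex (0/1 indicator) and BMI, daily wear
time, and the previous-day outcome (lag-1), built from day adjacency:
weekend break days appear as day-index gaps and deliberately break lag
chains. Continuous covariates are mean-centered; centering shifts only the
intercept, never the compositional coefficients or substitution contrasts.
A prospective (next-day outcome) alignment is available: each day's
composition is paired with the following day's outcome, and the same-day
outcome becomes the lag.

### Priors

The priors are weakly informative and scale with sd(y):

- `β, γ ~ Normal(0, (10·sd(y))²)`, intercept centered at mean(y);
- `σ ~ half-t(3, 2.5·sd(y))` via an inverse-gamma scale mixture;
- `Σ_b` gets a *scaled inverse-Wishart* prior
  `Σ_b = diag(α)·Σ_c·diag(α)` with `Σ_c ~ IW(q+1, I)` (marginally uniform
  correlations) and `α_k ~ Normal(0, (2.5·sd(y))²)`, giving heavy-tailed
  half-normal-like margins on the random-effect SDs.

The scaled-IW family was chosen over half-t + LKJ because every full
conditional stays conjugate, and the redundant multiplicative parameter α
has a Gaussian conditional that passes freely through zero — the standard
cure for the stuck-near-zero behaviour of centered Gibbs samplers when a
variance component is small. All scales are configurable (`PriorConfig`).

### Sampling

The posterior is simulated with a blocked Gibbs sampler written for exactly
this model family (`coda24._gibbs`):

1. `β` is drawn *collapsed*, with the random effects marginalised out via
   the Woodbury identity, i.e. from the exact Gaussian conditional under
   `y ~ N(Xβ, σ²I + ZΣ_bZ')`. This removes the dominant β–b autocorrelation.
2. The random-effect block (b, α, Σ_c, σ²) is refreshed five times per
   sweep; all person-level updates are batched `(m, q, q)` linear algebra
   with no Python loop over persons.

Defaults follow the analysis protocol: 4 chains × 2000 iterations with 1000
warmup (4000 post-warmup draws), and convergence is gated on split-chain
R̂ < 1.05 and bulk ESS > 400 (computed by ArviZ) for every population-level
parameter. Non-convergence is flagged and warned about, never raised; the
CLI signals it with exit code 3. Fits are bit-reproducible given (seed,
chains, iterations). Two independent checks guard the sampler: with random
effects disabled and flat priors its posterior means match OLS within
Monte-Carlo error, and predictions are invariant to the pivot basis used
for fitting.

Reduced settings (2 chains × 1400/400) are used for the replicated
simulation experiments; they are the smallest configuration that still
clears the absolute ESS > 400 gate.

## Substitution (reallocation) analysis

For a reallocation of `t` minutes from behavior A to behavior B at a
reference composition `x0`, the posterior difference per draw is

    Δy = β_level' · ( ilr(x0 + t·e_B − t·e_A) − ilr(x0) ),

with `β_level` the between- or within-person fixed coefficients; covariates
and random effects cancel exactly in the difference, which a test verifies
against the full two-prediction oracle at 1e-10 per draw. Within-level
contrasts are evaluated at the sample reference composition with zero
within-deviation — an average day of an average participant — using the
population-average slopes, not person-specific ones. Summaries are the
posterior mean and 95% equal-tailed interval; "significant" means the
interval excludes zero. No multiplicity adjustment is applied.

Because ilr is nonlinear in minutes, adding `t` minutes to a behavior is
not the mirror image of removing `t` minutes; grids therefore cover all 20
ordered pairs at both levels for 1–60 min, and a 30-min matrix view (rows =
gaining behavior, columns = donating behavior) condenses them. Cells whose
donor behavior would be exhausted are emitted with `feasible=False` and
missing estimates rather than dropped.

## Day-level validity filters

A valid day requires wear time ≥ 20 h, > 0 min of sleep, and at least one
detected walking period (a boolean column; raw detection is upstream of
this package); participants with fewer than 3 valid days are excluded
entirely. Every removed day is logged with a reason code and the log is
complete: retained + excluded = input. An optional minimum number of affect
ratings per day (`min_ratings`, with an `n_ratings` column) supports the
sensitivity analysis restricted to well-sampled days.

## Synthetic data generator

No participant-level data are publicly available, so the generator is the
sampling counterpart of the model above, calibrated once to the published
sample characteristics:

- 199 participants; days per participant uniform on 3–22 (a fixed-days mode
  gives exact design-row counts for structural tests);
- person-level ilr means MVN around the ilr of the closed mean composition
  (7.95, 10.5, 2.79, 1.15, 1.35 h); day deviations MVN(0, Σ_W). The
  between covariance is diagonal in the MVPA-first basis with variances
  (0.0768, 0.0297, 0.0202, 0.1445), found once by
  `scripts/calibrate_generator.py` so that simulated per-part hour SDs
  approximate (1.1, 1.1, 0.84, 0.31, 0.42); with four free variances and
  five targets the fit compromises slightly on standing/LPA. Σ_W defaults
  to the same matrix (ilr-space ICC ≈ 0.5).
- outcomes are generated *sequentially from the conditional (lag-adjusted)
  model*, so the echoed true parameters are exactly what the fitted model
  estimates: lag coefficient 0.3; random-intercept and residual scales
  chosen so the marginal mean and SD land on the published targets
  (e.g. valence 65.69 ± 12.2); compositional effects default to zero and
  are set per experiment (the recovery study uses 3.65 on the first within
  coordinate, a realistic published effect size);
- wear time is 24 h minus a non-wear draw concentrated below 4 h, so every
  generated day is a valid ≥ 20-h day (mean 20.4 h); its day-to-day spread
  is consequently narrower than the published 2.7 h, a deliberate
  divergence since only valid days are emulated;
- 5% of outcome values are missing at random by default.

What the generator does *not* emulate: the working-memory ceiling effect
(all outcomes are Gaussian), prompt-level affect sampling and
sedentary-triggered prompting (outcomes are generated directly at the daily
level), weekend gaps in day indices, accelerometer signal processing, and
any covariate–composition dependence. Passing tests therefore demonstrate
correctness of the machinery under the model's own assumptions, not
robustness to the violations real data would bring.

## Simulation experiments and their readings

`recovery_experiment` repeatedly simulates and refits, scoring per
parameter the systematic bias (mean of estimate − truth), RMSE, 95%-CI
coverage, and the rate of CIs excluding zero; non-converged replicates are
counted and excluded. Two standing observations:

- With a strong first within coefficient (3.65) at 100 persons × 10 days,
  the posterior mean carries a small positive systematic bias (~0.3 outcome
  units) that does not vanish with n. It traces to the lagged outcome being
  correlated with the random intercept (the dynamic-panel/Nickell
  mechanism) — a property of the analysis model itself, not of the sampler.
  It stays below 10% of the effect at study scale.
- Under the null (all compositional effects zero) per-coordinate
  false-positive rates run at roughly 5–15% over 20 replicates, the
  between-level ones slightly inflated by the same mechanism.

## Numerical choices and limitations

- Tolerances: exact algebraic identities are tested at 1e-9–1e-10;
  Monte-Carlo comparisons at multiples of the relevant posterior SD/MCSE.
- Problem sizes in tests (20×6 small table, 199×12 study-scale table,
  100×10 × 20 replicates for the experiments) were chosen as the smallest
  sizes at which the corresponding property is informative.
- Ties/degenerate inputs: zero-minute reallocations return an exact zero
  with a degenerate [0, 0] interval and are never flagged significant;
  infeasible grid cells are flagged, not dropped; an all-zero within
  covariance produces exactly constant compositions per person.
- The sampler is specific to Gaussian outcomes with a single grouping
  factor; crossed or nested random effects and non-Gaussian families are
  out of scope, as are one-to-many reallocations and person-specific
  substitution effects.
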