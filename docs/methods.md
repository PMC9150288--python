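# Methods

This note records the statistical model the package implements, the
defaults and numerical choices that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the design was genuinely open.

## Model and assumptions

A pregnancy attempt is a two-stage nested multinomial process over a
conception window of τ menstrual cycles (default 6, matching the
motivating application).

**Stage 1 (conception).** The time to clinically-recognized pregnancy T₁
follows a discrete-time hazard, logit P(T₁ = t | T₁ ≥ t, x) = g_t + γᵀx.
The cycle intercepts are parameterized as a reference intercept at t = 1
plus offsets I(t = 2…τ), so fitted coefficients line up with the layout of
published coefficient tables.  Fitting uses the person-period expansion:
subject i contributes U_i = (T₁∧C∧τ) rows with the binary event indicator
δ_it, and the working-independence logistic log-likelihood on these N = ΣU_i
rows equals the discrete-time survival log-likelihood exactly (a property
the test suite verifies against a subject-by-cycle oracle).  Censoring C
is assumed independent of T₁ given x; no sensitivity machinery is
provided.  Cycles with no person-period rows inherit the last estimable
cycle's baseline logit, with a warning — extrapolation is explicit, never
silent.

**Stage 2 (gestation).** Given conception within the window, the outcome
(2 = clinical loss, 3 = preterm, 4 = full-term) follows a
baseline-category logit with full-term as the reference.  The model is
deliberately agnostic to the timing of conception: T₁ is not a stage-2
covariate.  The state codes 2/3/4 are kept so coefficient signs remain
comparable with the published tables.

**Composition.** The risk profile is
p(τ) = (π₀, π₂|₁·π_¬0, π₃|₁·π_¬0, π₄|₁·π_¬0) with
π_¬0 = 1 − ∏ₜ(1 − hₜ(x)).  Class order is fixed everywhere as
(no-pregnancy, loss, preterm, full-term); one canonical axis prevents
silent permutation bugs.

## Missing data

Both outcome stages can be missing: R₁ = 0 (censored before conception,
first-stage status at τ unknown) and R₂ = 0 (recognized pregnancy with
unknown result).  Subjects observed through τ without conception carry
R₂ = 1 vacuously — their gestation outcome is undefined, not missing.
The sequential-MAR assumption is: P(R₁|w, Y₁) = P(R₁|x′) and
P(R₂|w, R₁=1, Y) = P(R₂|z′, R₁=1, Y₁).

**Sequential MI (default path).** Per imputation: (i) missing baseline
covariates are completed by chained equations (10 cycles; logistic draws
for 0/1 columns, normal draws at the residual scale for continuous
columns); (ii) the conception cycle of every R₁ = 0 subject is drawn from
the conditional distribution of T₁ over {u+1, …, τ, τ+1} given T₁ > u and
the auxiliaries x* (τ+1 encoding no conception), implied by a pooled
discrete-time hazard model on x*; (iii) unknown gestation outcomes of
selected subjects are drawn from a multinomial model on z and the
auxiliaries.  M = 10 by default; points are pooled by Rubin's rules
(mean; within + (1 + 1/M)·between variance).  Per-imputation random
streams are spawned from the master seed, so results do not depend on M
or execution order.  A literal censoring-cycle-stratified multinomial
imputation model is available but not the default: its strata are sparse
at realistic n, while the pooled hazard model targets the same
conditional distribution under proportional-on-logit effects and is
numerically stable.  The first-stage model is always refit on the
*observed* follow-up (with imputed covariates only) — censoring is
handled by the person-period likelihood, so imputed conception times are
never fed back into the hazard fit.  Default auxiliaries x* = x ∪ x′.

**IPW path.** The gestation model is fit to second-stage complete cases
weighted by 1/π^C, π^C = P(R₂=1|z′,R₁=1,Y₁=1)·P(Y₁=1|x,R₁=1)·P(R₁=1|x′),
each factor a logistic regression.  Weights are truncated at the 1st/99th
percentiles by default (configurable): near-zero estimated probabilities
otherwise destabilize the estimator.  The stage-2 factor is fit among
conceivers only — under the vacuous-R₂ convention, Y₁ = 0 rows have
R₂ ≡ 1 and a Y₁ term would be perfectly separated.

**Verification probabilities.** π^R = P(R₂=1|z′,R₁=1,Y₁)·P(R₁=1|x′) for
the HUM adjustment; a single-model form P(R=1|w) is provided for
applications where second-stage missingness is rare, and is the pipeline
default.  Estimated probabilities below 10⁻³ are floored with a warning.

## HUM validation

The forced-choice rule assigns K profiles (one per class) to the K class
vertices by minimizing Σ_k ω_k‖p⁽ᵏ⁾ − e_{c_k}‖ over the K! permutations
(brute force; K = 4 → 24).  The permutation constraint is essential: an
unconstrained per-individual argmin would decouple the K decisions and
render the weight vector ω inert.  Default ω = (1,1,1,1), which speaks to
overall classification performance.  Ties are scored conservatively: a
tuple counts as correct only when the identity permutation is the unique
minimizer within 10⁻⁹; the all-uniform degenerate case therefore scores 0.

The nonparametric HUM averages the correct-classification indicator over
all n₁·…·n_K tuples (exact mode, vectorized, refused above 10⁶ tuples) or
over tuples sampled uniformly with replacement (Monte-Carlo mode, default
2×10⁵ draws; at that size the MC error near HUM ≈ 0.1 is ~5×10⁻⁴).
Realistic class sizes give ~10⁹ tuples, so MC is the practical mode.  The
verification-bias-adjusted estimator weights each tuple by the inverse
product of its members' π^R and normalizes by the total weight; it reduces
algebraically to the unweighted estimator when the π^R are constant (an
identity the tests assert exactly).

Uncertainty comes from a subject-level unstratified bootstrap
(normal-approximation CI truncated to [0,1]).  The Harrell optimism
correction refits the pipeline on each resample and scores it on both the
resample and the original data; the corrected value is the apparent value
minus the mean optimism.  By default the correction conditions on the
originally selected model form — re-running selection inside the bootstrap
is exposed behind a flag but is known to be unstable in small samples,
where variable selection inflates in-sample separation of the risk scores.

## Synthetic cohorts

The generator emulates a preconception trial population of women aged
18–40 with one or two prior pregnancy losses: age ~ N(28.7, 4.5²),
BMI ~ N(26.5, 6²), cycles already spent trying ~ uniform{0…5}, binary
aspirin/race/education/parity/hypertension/smoking covariates, first- and
second-stage coefficients set to the published model values, a constant
per-cycle dropout hazard logistic in x′ (intercept −3.6, so ~3% per
cycle), and stage-2 observation probability logistic in z′ (intercept 4.0,
~98%).  These defaults put the four observation patterns near 9%, 31%,
1%, 59% — the realistic regime of roughly 8% censored before conception,
29% without pregnancy, 1% conceptions with unknown result.  Baseline
covariate missingness defaults to the low observed rates (0.5–1.4%) on
BMI, hypertension, smoking and education.

Stage-1 missingness is generated *through the dropout process*: a
Bernoulli R₁ drawn independently of T₁ cannot be embedded in observed
(U, δ) data without contradiction, so the dropout hazard depends on x′
and is independent of T₁ given x′, which is the sequential-MAR-compatible
generative form; R₁ is then determined by (T₁, C, τ).  Stage-2
missingness is a direct Bernoulli draw among conceivers, never reading
the gestation outcome (an independence the tests verify empirically).

What the generator does **not** emulate: day-level fecundability or
cycle-length biology (cycles are abstract discrete trials), sterility or
cure fractions, covariate-dependent censoring by default (available for
stress tests), time-varying covariates, and MNAR mechanisms.  Passing
tests therefore demonstrate correctness of the estimators under the
stated MAR structure, not robustness to its violation.

## Numerical choices

- Logistic fits: statsmodels IRLS, tolerance 10⁻¹⁰, 200 iterations;
  estimates with |coef| > 100 or non-finite standard errors are reported
  as separation, never silently returned.
- Multinomial fits: L-BFGS on internally centered/scaled covariates
  (coefficients mapped back), gradient tolerance 10⁻⁸, 500 iterations;
  empty outcome classes raise with the class named.
- AIC backward selection removes, at each step, the non-forced covariate
  whose removal most decreases AIC (lexicographic tie rule); applied to
  the stacked M·n completed rows without adjusting AIC for the M-fold
  sample-size inflation — the literal stacked-data procedure, which
  over-weighs evidence by a factor of M and is therefore conservative
  about dropping covariates.
- Bootstrap and imputation streams are spawned from a single master seed
  (PCG64 SeedSequence), making every report reproducible bit-for-bit for
  a fixed configuration; all derived seeds stay below 2³¹.

## Problem sizes used by the test suite

Simulation-based checks run at sizes chosen to keep Monte-Carlo error
well below the tolerances they assert: parameter recovery uses 50
replicate cohorts of n = 2000; hazard calibration uses a single n = 50000
cohort; the verification-bias comparison uses 200 replicates of n = 4000
scored with 2×10⁴ MC tuples; the chance-level HUM check averages 100
replicate profile sets of 200 per class with 10⁵ MC tuples in total.

## Known limitations

- The HUM lacks established "good/poor" benchmarks beyond its 1/K!
  chance level; interpret magnitudes comparatively.
- The chained-equations imputer covers continuous and 0/1 covariates;
  multi-level categoricals must arrive integer-coded and are treated as
  continuous in covariate imputation (outcome imputation is fully
  multinomial).
- With only ~50 replicates, two-standard-error recovery checks on many
  coefficients simultaneously will occasionally flag a component by
  chance; the per-component z-values are reported to make this visible.
- The exact-enumeration HUM holds all pairwise distance matrices in
  memory; above the 10⁶-tuple ceiling use Monte-Carlo mode.
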