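# Methods

## Model

An individual's life is an absorbing Markov chain on `s` living stages plus
death.  The transient matrix `U` (column = current stage) collects the
probabilities of surviving and moving among living stages over one projection
interval; its column deficits `m' = 1' − 1'U` are the per-stage death
probabilities, and the assembled `(s+1)×(s+1)` chain `P` is column-stochastic
with death absorbing.  We require the spectral radius of `U` to be strictly
below 1, so every individual is absorbed with probability 1 and lifetime
accumulations converge; matrices violating this (or with column sums above 1
beyond a 1e-12 tolerance, configurable) are rejected at the door rather than
producing a silently divergent iteration.

On the transition from stage `j` to stage `i` the individual collects a
random reward `r_ij` — here, offspring produced during the interval.  The
dead collect nothing, so the absorbing-source column of every reward-moment
matrix is identically zero.  All randomness in `r_ij` is *within-stage*
variability shared by all individuals in a stage; between-individual
heterogeneity in rates is deliberately outside the model, which is exactly
what makes its output the null baseline against which observed variability
can be judged.

## Moment recursions

Let `R_m` hold the mth raw moments `E[r_ij^m]` and `ρ_m(t)` the vector of
mth raw moments of reward still to be accumulated with `t` steps remaining.
Conditioning on one transition and expanding `E[(r + ρ)^m]` binomially
(rewards independent of the subsequent accumulation) gives

    ρ_m(t+1) = Σ_{j=0}^{m−1} C(m,j) (P ∘ R_{m−j})' ρ_j(t) + P' ρ_m(t),

with `ρ_0 = 1` and terminal condition `ρ_m(0) = 0`.  For `m = 1..3` these are
the familiar mean/second/third-moment recursions; the implementation supports
arbitrary order with precomputed binomial coefficients and raises if any
moment exceeds 1e300.  Raw moments (about zero) are stored throughout — the
recursion couples orders through raw, not central, moments.

Numerical choices:

* All orders are updated jointly in one sweep per backward step, lower
  orders feeding higher ones within the sweep; at the fixed point this is
  equivalent to converging order-by-order but costs one pass.
* Convergence: sup-norm change of every order below `tol` (default 1e-10);
  `max_iter` default 1e6.  Non-convergence raises with the residual — it
  signals a spectral radius near 1, not a situation to paper over.  The
  geometric convergence rate is the spectral radius of `U`, so even
  survival 0.999 converges in ~3·10^4 cheap sweeps.
* The recursion runs on the full `(s+1)`-state system; the absorbing entry
  is verified to be ~0 and dropped from output.
* Statistics: variance `ρ2 − ρ1²`, SD, CV, skewness
  `(ρ3 − 3ρ1ρ2 + 2ρ1³)/sd³`.  A variance in `[−tol, 0]` is clamped to 0;
  below `−tol` it raises.  Skewness is NaN where the SD is 0 and the CV is
  NaN where the mean is 0 (a zero SD with positive mean yields CV = 0,
  which is well-defined and kept).

Mean lifetime reward from the first stage equals the net reproductive rate
`R0 = max eig F(I−U)^{-1}` whenever rewards are the fertilities of `F`
(destination-independent, collected on every outgoing transition); this and
the age-classified survivorship sum `Σ l_x f_x` serve as cross-checks, not as
the computation itself.

## Reward models

* **Empirical**: `E[r^m]` is the plain mean of mth powers of per-stage
  individual observations (the raw-moment definition; no small-sample
  correction).  A stage declared reproducing but given no data raises a
  named error — never a silent zero.
* **Poisson** (random offspring given a mean): raw moments by the Touchard
  recurrence `μ_{k+1} = λ Σ_j C(k,j) μ_j`, robust at any order, checked
  against brute-force pmf summation.
* **Bernoulli** (monovular species): every raw moment equals `p`.
* **Fixed**: `E[r^m] = r^m` — the no-within-stage-variance floor.  With unit
  rewards for every living stage the accumulated reward is longevity, and
  its mean reproduces the fundamental-matrix column sums.

Rewards depend on the source stage by default and are broadcast across
destinations; full destination-dependent matrices pass through unchanged for
life cycles where reproduction rides on the transition into a reproductive
state (supported but exercised only structurally — no published worked
example exists to test against).

**Reward on death.** Whether an individual that dies during an interval
still collects that interval's reward is a timing convention the projection
framework leaves open.  The default (`reward_on_death=True`) collects the
source-stage reward on every outgoing transition including death —
reproduction precedes death within the interval — which is also what makes
the longevity and R0 identities exact.  `reward_on_death=False` zeroes the
death row for the stricter convention; both are exposed everywhere
(builders, simulator, CLI).

## Variable environments

With `q` environmental states, individuals are jointly classified as
(stage, environment), ordered stage-major (environment fastest: the first
`q` joint states are stage 1 in each environment).  Within a step the
individual first makes its demographic transition under the current
environment's `U_e`, collecting that environment's reward, and then the
environment advances by the column-stochastic `D` — rewards ride on the
demographic transition only, and the reverse event order is deliberately not
configurable (it would silently change results).  With `K = K_{s,q}` the
vec-permutation (commutation) matrix, the joint transient block is

    T = (I_s ⊗ D) · K · blockdiag(U_1..U_q) · K',

built by explicit block assembly and verified two independent ways: the
`q=1` reduction is exact to 1e-12, and an environment-aware Monte-Carlo
simulator that tracks stage and environment separately (never touching this
algebra) agrees with the joint engine within Monte-Carlo error.  Death is
pooled into a single absorbing state: remaining rewards after death are zero
in every environment, so pooling preserves all moments and keeps the chain
small.

Environment types: periodic (circulant `D`, e.g. seasons), sequential
(superdiagonal chain whose final state self-loops to end the sequence),
stochastic (any column-stochastic `D`), and the four-state fire-recency
chain (fire with probability `f` resets to state 1, otherwise the
time-since-fire clock advances and saturates at state 4).  For stochastic
environments the moments by starting stage are the stationary-distribution
(`Dπ = π`) average of the *raw* moments across starting environments;
statistics are derived after averaging, never averaged themselves.
Stationary averaging is disabled for sequential environments, whose
stationary distribution (all mass on the end state) is of no interest.

## CV/skewness ratio for rare Bernoulli reproduction

Three distributional benchmarks anchor the patterns the statistics display:
Poisson lifetime reproduction has CV equal to skewness; an exponentially
distributed reproductive span with constant output has CV equal to half the
skewness; and sustained per-step Bernoulli(`p`) reproduction over a long,
high-survival life yields an (approximately geometric) offspring count with

    CV / skewness = 1 / (2 − p),

approximately 1/2 for small `p`.  `bernoulli_cv_skew_ratio` implements this
closed form; the recursion on a single-stage chain with survival 0.999 and
Bernoulli(0.01) rewards reproduces it to within the stated approximation
(≈0.52 vs 0.5025).  Note the naive binomial-count ratio `(1−p)/(1−2p)` tends
to 1, not 1/2; it describes a fixed number of trials, which is not the
high-survival lifetime regime the benchmark addresses.

## Discounted rewards

On an ergodic chain rewards accumulate forever; with a discount `d ∈ (0,1)`
the conditional accumulation becomes `r + d·ρ`, so the order-`j` term of the
recursion picks up `d^j` and the iteration converges geometrically in `d`.
Discount 1 is permitted only for absorbing chains (recovering the plain
engine, which the tests confirm as the `d → 1⁻` limit); requesting it on an
ergodic chain raises.

## Trajectory simulator

`simulate_lifetimes` follows `n` independent individuals through the chain,
drawing destinations from the column CDFs and rewards from the same
distributions whose moments feed the recursions (fixed / Poisson / Bernoulli
/ empirical resampling, honouring `reward_on_death`), with a hard lifetime
cap (default 1e6 steps) against near-reducible chains and full
reproducibility from a numpy `Generator` seed.  Empirical raw moments carry
standard errors `sd(x^m)/√n`, and engine-vs-simulation agreement is asserted
within three standard errors at `n = 1e5` across fixtures spanning Leslie,
stage-classified, and joint-environment chains and all four reward models.

## Synthetic data

The generator module emulates the shapes of data such studies produce, not
any particular study's numbers:

* `leslie_from_schedule` builds strict Leslie matrices (no self-loops) from
  age schedules; `random_stage_model` builds seeded random column-
  substochastic stage matrices with optional stasis/retrogression, spectral
  radius kept below 1 by rescaling column sums into (0.3, 0.95).
* `synthetic_cohort` draws per-stage individual reproductive outputs with a
  target mean and index of dispersion: Poisson at dispersion 1, gamma-Poisson
  (negative binomial) above it — the simplest count mixture hitting an
  arbitrary overdispersion, chosen because empirical reproduction data are
  typically overdispersed (index of dispersion well above 1).  Defaults used
  in tests (means up to ~8 offspring per interval, dispersion 5–10, cohorts
  of 5000–20000) sit in the range such laboratory and field cohorts report.
* The named six-stage matrices `trillium_like_u` / `lomatium_like_u` are
  clearly labelled **synthetic** stand-ins with the documented life-cycle
  structure of well-studied forest-herb and fire-adapted-prairie perennials
  (germinant/seedling progression; bidirectional movement among large size
  classes; reproduction restricted to the flowering stages).  They exercise
  the machinery structurally; no numerical claim about any published
  population rests on them.

What passing tests show — and do not.  The synthetic generator reproduces
individual stochasticity and within-stage reward variability under exactly
known conditions, so agreement there validates the algebra and its
implementation.  It does not emulate heterogeneity among individuals,
measurement error, temporal autocorrelation in vital rates beyond the
explicit environment chain, or the sampling designs of real studies, so
tests passing here say nothing about whether any particular field estimate
of `U` is adequate.

## Problem sizes

The default suite and the benchmark script run small systems by design —
stages ≤ 6, environments ≤ 4, Monte-Carlo cohorts of 1e5 — because the
quantities being checked (closed forms, analytic limits, 3-SE agreement) are
already decisive at these sizes; the engine itself is `O(k² n²)` per sweep
and handles much larger chains without structural change.

## Known limitations

* Only moments are computed; the full distribution of lifetime reproduction
  is available solely through the simulator's histograms.
* No estimation: `U`, `F`, and reward data are inputs, not things fitted
  from raw observations.
* Heterogeneity models (frailty, genetic variation in rates) are out of
  scope; the package computes the null against which they are compared.
* Destination-dependent rewards are supported but untested against any
  published example (none prints one).
* Sensitivity analysis and population-growth linkage of mean lifetime
  reward (which is a cohort quantity, not `R0`, when reward currencies
  differ) are not provided.
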