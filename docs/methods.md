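# Methods

## Model and estimand

Subjects carry a continuous biomarker X, a binary covariate Z1 and two
continuous covariates Z2, Z3.  The hazard is

    h(t | X, Z) = h0(t) · exp( βX · 1{X > θ} + βZ1·Z1 + βZ2·Z2 + βZ3·Z3 ),

i.e. the biomarker influences survival only through its dichotomisation at
the true cutpoint θ; the boundary value X = θ belongs to the low group.  The
estimand of every method is θ.  Default coefficients are
βX = ln 3, βZ1 = ln 2, βZ2 = ln 0.5, βZ3 = ln 2 (hazard ratios 3, 2, 0.5, 2),
strong enough that an omnibus test of the Cox model is significant even at
n = 250.

## Partial likelihood

`fit_cox` maximises the Cox partial likelihood with the Efron approximation
for tied event times (ties are almost surely absent in simulated data but
arise in user data).  Newton iterations with step-halving start at β = 0 or a
caller-supplied warm start; convergence requires the relative log-likelihood
change to fall below 1e-9 within 100 iterations.  Non-convergence and
quasi-separation (|β̂| > 15) are flagged, never raised; flagged fits are
excluded from criterion ranking and counted in the diagnostics.  Stratified
fits sum per-stratum partial likelihoods with separate baseline hazards; the
parameter count k excludes strata, and every stratum must contain at least
one event.  The null log partial likelihood is evaluated at β = 0 on the same
strata structure, so the model LRT χ² = 2(ℓ̂ − ℓ0) and the AIC = −2ℓ̂ + 2k are
mutually consistent: at fixed k, argmax χ² ≡ argmin AIC, which is why methods
A and E1 agree estimate-by-estimate.

The likelihood, gradient and Hessian are computed twice over: a vectorised
numpy implementation is the reference, and a compiled single-pass kernel
(numba) removes per-call overhead in the grid scans.  A test asserts their
agreement to 1e-9 including tied data; if the compiled path is unavailable
the numpy path is used transparently.

"Chi-square statistic" is read as this model LRT χ² rather than a Wald or
score statistic.  The three are asymptotically equivalent; the LRT reading
makes the A ≡ E1 identity exact, matching the observed near-identity of the
two methods' results.

## Criteria

* **Harrell c-index** — share of comparable pairs whose predictor ordering
  matches the survival ordering.  A pair is comparable when the subject with
  the shorter observed time had the event; time-tied pairs count only when
  exactly one is an event; predictor ties contribute 1/2.
* **Gönen–Heller CPE** — K(β̂) computed from coefficients and covariate pairs
  only: the mean over unordered pairs of 1/(1 + exp(−|β̂'(x_i − x_j)|)),
  pairs at zero difference contributing 1/2.  By construction it never falls
  below 0.5 and is unaffected by the censoring pattern.
* **Log-rank test** — the standard two-sample statistic with hypergeometric
  variance, equal to the Cox partial-likelihood score test on the group
  indicator in the absence of ties (tested to 1e-6).

Both concordance measures are verified against brute-force double loops and
against lifelines.

## Candidate grid and search

Candidates are the distinct observed biomarker values v with
min_prop ≤ P(X ≤ v) ≤ 1 − min_prop, default min_prop = 0.10.  Unbounded
search would admit degenerate dichotomisations; 10% per side is the
convention of maximally-selected-statistics practice and is configurable.
Criterion ties break toward the smallest candidate — deterministic and
independent of subject order.

The AddFor stepwise search reduces to this exhaustive scan when one cutpoint
is estimated, so C1/D1 are exhaustive scans.  The scans warm-start each
candidate's Newton solve from the neighbouring solution (one subject changes
group between adjacent candidates), falling back to a cold start on failure.

**Genetic algorithm (C2/D2).**  Real-coded, population 50, at most 100
generations, tournament selection (size 3), arithmetic crossover, Gaussian
mutation with sd = range/20, elitism 1, early stop after 20 stagnant
generations; deterministic under its seed.  The fitness of a cutpoint is
piecewise constant between consecutive observed values, so evaluations are
memoised per piece; the GA's job is only to locate the best piece, and on
50-piece problems it matches the exhaustive optimum in ≥95% of seeded runs
(tested).  The original study does not print GA settings; these defaults were
sized so that the 1-D search is reliably exhaustive-equivalent.

**Method A effect size.**  The cutpoint comes from the full-data scan; HR and
p come from twofold cross-validation: halves stratified on event status, each
half dichotomised at the cutpoint estimated on the *other* half, one pooled
Cox fit of the out-of-fold indicator plus covariates.  Pooling (rather than
averaging per-fold effects) uses every subject exactly once and yields a
single HR/p pair.  **Method B** estimates the cutpoint on one stratified
random half, with its own grid from that half's empirical quantiles, and
takes HR/p from the held-out half.

**Method F** reports the smallest log-rank p uncorrected; it is a
selection-biased quantity (noted in the result diagnostics) and is reported
for ranking, not inference.

## Synthetic data

Covariates: X, Z2, Z3 ~ N(0,1) i.i.d., Z1 ~ Bernoulli(0.5).  The source
design specifies these only graphically; standard normal X places the true
cutpoints {0.2, 0.7, 1.2} 0.2–1.2 SD above the median, consistent with the
reported median-attraction magnitudes.

Event times come from Bender-style inverse-transform sampling with linear
predictor lp:

* exponential: T = −log(u) / (λ e^lp), default λ = 0.2
* Weibull: T = (−log(u) / (λ e^lp))^(1/γ), default γ = 1.5, λ = 0.1
* Gompertz: T = (1/b) · log(1 − b·log(u)/(a e^lp)), default a = 0.003, b = 0.098

with u drawn from the open unit interval.  `true_survival` provides the
closed-form inverse; a round-trip identity to 1e-10 is tested for all three
families.

**Censoring.**  Follow-up ends administratively at t = 1; drop-out times are
U[0,1].  Two targets govern censoring: pc_t (total censored share) and pc_f
(share of censorings strictly before t = 1).  These are met by two calibrated
parameters: a multiplier on the baseline rate (λ or a), which moves the
administrative share P(T_S > 1), and a per-subject drop-out probability q.
On a 100 000-subject common-random-numbers sample the realized pc_t is
monotone decreasing in the multiplier and the realized early share is
monotone increasing in q, so nested Brent root-finding (inner: multiplier at
fixed q; outer: q) hits both targets; the result is verified to tolerance
0.02 and cached per scenario (calibration is a deterministic function of the
scenario's generative fields, shared by all replicates, with a fixed internal
sample seed).  Infeasible targets are reported as non-convergence and
propagate as errors.

Final data: T = min(T_S, C, 1), event = 1 iff T_S ≤ min(C, 1); columns
`time, event, X, Z1, Z2, Z3`.

**What the generator does not emulate:** correlation among covariates,
informative (covariate-dependent) censoring, measurement rounding of the
biomarker, time-varying effects, competing risks.  The last omission that
matters most in practice is rounding: laboratory biomarkers are often
recorded on coarse grids, which shrinks the candidate set and with it the
spread of maximally selected estimators.  Passing tests therefore establish
the estimators' behaviour under these stated continuous-data conditions, not
their numerical performance on any particular clinical dataset.

## Study design and performance measures

The full factor grid is 3 distributions × θ ∈ {0.2, 0.7, 1.2} ×
n ∈ {250, 500, 750} × pc_t ∈ {0.2, 0.5, 0.8} × pc_f ∈ {0.25, 0.50} = 162
scenarios.  One master seed spawns per-scenario child seeds
(`numpy.random.SeedSequence`), and each scenario spawns per-replicate seeds,
so any single replicate can be replayed from its recorded integer seed and
results are identical for any worker count.

Per (scenario, method), with n non-missing estimates θ̂_i:

* bias = mean(θ̂) − θ, MCSE = EmpSE/√n
* EmpSE = √(Σ(θ̂ − mean)²/(n−1)), MCSE = EmpSE/√(2(n−1))
* MSE = mean((θ̂ − θ)²), MCSE = √(Σ((θ̂−θ)² − MSE)²/(n(n−1)))
* precision gain of M vs reference R = 100·((EmpSE_R/EmpSE_M)² − 1), with a
  leave-one-replicate-out jackknife MCSE (no closed form exists for the
  ratio); replicates are paired by id and pairs missing on either side are
  excluded.

The exact identity MSE = bias² + EmpSE²·(n−1)/n holds on every row.  Missing
estimates are excluded with reported counts, never silently dropped.
Aggregation pools replicate-level estimates across collapsed factors and
recomputes all measures; pooling across different θ is refused because bias
would mix targets.  The replication rule n_sim = ⌈(SD/target MCSE)²⌉ gives
369 for SD 0.096 at target 0.005.

## Problem sizes in the shipped checks

The full 162 × 500 study is days of CPU; the package's own checks run
scaled-down versions chosen to keep Monte Carlo error well below the effects
they probe: 300 replicates for the near-median bias cell, 2 × 150 for the
far-cutpoint/heavy-censoring cell, 2 × 75 for the strata-collapse cell, and
4 × 2 × 100 for the monotonicity-in-(n, pc_t) comparison at θ = 1.2.
`scripts/acceptance.py` uses 500 replicates per scenario.  `required_nsim`
lets users size their own runs.

## Known limitations

* One cutpoint per biomarker; the stepwise/genetic machinery is not extended
  to k ≥ 2 thresholds.
* No selection-bias correction for method F's minimum p and no confidence
  intervals for θ̂.
* No left truncation, interval censoring, time-varying covariates or
  competing risks; censoring is assumed non-informative.
* The strata method E2 is reported as specified even though its AIC criterion
  structurally favours balanced strata: far-from-median cutpoints give
  near-median estimates (large negative bias), which the harness reproduces.
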