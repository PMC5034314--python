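# Methods

## Scope and data model

The package analyses three inputs: length-at-age records (integer ages from
vertebral band counts, disc widths in mm), age-composition counts per
integer age class, and species life-history tables (annual reproductive
output of daughters `b`, age at maturity `alpha_mat`, maximum age
`alpha_max`, as point values or uniform ranges). Sexes are pooled and ages
are treated as exact; there is no ageing-error model, no sex-specific
growth, and no alternative growth function (Gompertz, logistic) — the von
Bertalanffy form is the contract.

## Growth model

Disc width at age t is `DW_t = DW_inf − (DW_inf − DW_0)·exp(−k·t)` — the
size-at-age-zero parameterisation, appropriate for live-bearing rays that
are born large — with lognormal observation error: `ln DW_obs ~
Normal(ln DW_t, sigma2)`. Parameters and priors:

| parameter | units | strong | weaker | uninformative |
|---|---|---|---|---|
| k | year⁻¹ | Beta(1.05, 1.5) | Beta(1.05, 1.1) | Uniform(0, 2) |
| DW_inf | mm | Normal(3100·κ, 100) | Normal(3100·κ, 400) | Uniform(0, 4000) |
| DW_0 | mm | Normal(880, 200) | Normal(880, 300) | Uniform(0, 2000) |
| κ | — | Gamma(1000, 990) on [0.7, 1.3] | Gamma(200, 198) on [0.7, 1.3] | Uniform(0.7, 1.3) |
| σ² | log-space | half-Cauchy(0, 30000) | same | same |

Normal priors are (mean, sd); Gamma is (shape, rate), so the strong κ prior
has mean 1000/990 ≈ 1.01 — the empirical conversion from maximum observed
size (3100 mm here) to asymptotic size. κ's support is implemented as a hard
truncation of the gamma. The half-Cauchy scale of 30000 is enormous relative
to a log-space variance; it is kept as tabled and is effectively flat over
the posterior's support, so it acts as a weakly-informative positive prior.
Beta parameters are (shape1, shape2). The joint support additionally
enforces DW_inf > DW_0 > 0, k > 0, σ² > 0.

Sampling uses an affine-invariant ensemble sampler (emcee) with a vectorised
log posterior in the natural parameter space: 32 walkers, 1000 warmup and
1000 retained steps by default (configurable). Walkers are initialised by
jittering a crude data-driven point (k = 0.2, DW_inf = 1.15·max width,
DW_0 = 0.9·min width, κ = 1.01, σ² = 0.05) inside the joint support. Each
walker is treated as a chain for split-Rhat and bulk ESS (computed with
arviz). Ensemble walkers carry within-walker autocorrelation, so Rhat decays
toward 1 more slowly than for independent NUTS chains; a fit whose Rhat
exceeds the threshold (default 1.01) is flagged with a warning and
`summary_.converged = False`, never silently discarded. For final estimates,
run longer chains until the flag clears.

Posterior summaries are means with equal-tailed 2.5%/97.5% credible
intervals per parameter.

## Catch curve

`build_age_composition` tabulates counts for every integer age from 0 to
the maximum observed age (explicit zeros for gaps); caller-specified age
classes believed unrepresentative can be excluded from the structure.
`catch_curve_slope` then

1. finds the peak (modal) age class — ties resolve to the earliest age,
   which retains the most classes and is the most conservative choice;
2. drops all classes younger than the peak (ascending limb = lower
   catchability of young animals), keeping the peak itself;
3. drops zero-count classes (their log is undefined);
4. requires at least three remaining classes and returns Z = −slope of the
   OLS regression of ln(count) on age.

`bootstrap_Z` repeats this after deleting `floor(drop_fraction·n)` records
(default 20%) without replacement per replicate — deletion, not resampling
with replacement, matching the description of "removing" points — with
20,000 replicates by default. Replicates left with fewer than three usable
classes are discarded and counted, not padded. The Z interval is reported as
equal-tailed 2.5%/97.5% quantiles; an optional `max_age_cutoff` drops the
oldest, sparsely sampled ages (e.g. ages ≥ 10) to guard against
overestimating Z when old animals may be missing for reasons other than
mortality (migration, catchability).

`fishing_mortality` resamples the Z and M draw vectors independently with
replacement to a common length and differences them elementwise; negative F
draws are retained (the lower interval bound can legitimately be negative
when Z and M overlap). The F interval uses 5%/95% quantiles to match the
demography convention.

## Demography

With average lifespan `omega = (alpha_mat + alpha_max)/2`, natural mortality
is `M = 1/omega`, survival to maturity `l_mat = exp(−M·alpha_mat)`, and
r_max is the root of

    g(r) = exp(r·alpha_mat) − exp(−M)·exp(r·(alpha_mat − 1)) − l_mat·b.

`alpha_mat` is used as a continuous exponent (no rounding to whole years).
The root is found by bracketed Brent iteration after expanding the bracket
upper edge geometrically within [−1, 5]; the returned root must satisfy
|g(r)| < 1e−10 or the solver errors with diagnostics. (g(−M) = −l_mat·b < 0
and g → ∞ as r grows, so a bracket always exists for M < 1.) Root finding on
the residual replaces generic function minimisation: same solution,
better-behaved contract.

The Monte Carlo draws (b, alpha_mat, alpha_max) independently and uniformly
from their ranges — a single shared draw of alpha_mat feeds both M and the
Euler-Lotka exponent, the only internally consistent reading of computing M
"iteratively" from the drawn ages — computes omega, M, l_mat and r_max per
draw, and reports medians with 5%/95% quantiles. Draws with
alpha_mat ≥ alpha_max are rejected, redrawn and counted (impossible for
non-overlapping ranges). Percentile convention: the reported intervals are
the 5th and 95th percentiles. Under the default ranges omega follows a
symmetric trapezoid on [10, 13] whose closed-form 5%/95% quantiles map to
M of 0.097/0.079 — matching that convention, whereas 2.5%/97.5% would give
0.098/0.078; the acceptance tests use the closed-form trapezoid quantiles as
the analytic oracle.

Default ranges (the devil-ray case): b ∈ [0.25, 0.5] female pups·year⁻¹
(single pup annually or biennially, 1:1 sex ratio), alpha_mat ∈ [5, 6] y,
alpha_max ∈ [15, 20] y. `rmax_batch` applies the same machinery per row of
a species table, with per-species seed substreams derived from the master
seed (switchable to a shared seed for exact row reproducibility); malformed
rows are reported by species name and processing continues.

## Synthetic data

The generators supply every input at known truth so all stages are testable
without field data:

- **Length-at-age**: ages uniform over a range (default 0–14), widths
  lognormal around the VB curve; optional size-window truncation by
  rejection (default 1100–2400 mm, imitating a catch sample that spans only
  ~77% of maximum size). Defaults (n = 60, k = 0.12, DW_inf = 3000,
  DW_0 = 900, σ² = 0.01) imitate the kind of sample the workflow targets;
  the original per-age counts are not public, so these are assumptions, not
  data. Ages are sampled uniformly — not from the mortality-decayed age
  structure — to decouple growth tests from mortality.
- **Age composition**: expected catch proportion ∝ sel(a)·exp(−(M+F)·a)
  sampled multinomially. Selectivity is a logistic ascending limb rescaled
  to reach exactly 1 at the full-recruitment age and flat thereafter
  (steepness = ∞ gives knife-edge selection), the minimal ogive consistent
  with lower catchability of young classes.
- **Fished population**: deterministic cohort model with constant
  recruitment; M applies at every age, F from the recruitment age onward.
  Its noise-free equilibrium catch curve has slope exactly −(M+F) beyond
  the peak, which closes the loop on the catch-curve estimator and shows
  that a steep right limb can arise from fishing alone.

What the generators do **not** emulate: ageing error, sex structure,
recruitment variability, migration, size-selective gear within the recruited
ages, and density dependence. Passing tests therefore demonstrate that the
estimators recover the truth under the model's own assumptions, not that
those assumptions hold for any particular fishery.

## Numerical choices and problem sizes

- All randomness flows from a single user seed; bootstrap replicates,
  pipeline stages and batch rows use substreams derived via
  `numpy.random.SeedSequence`. Same seed ⇒ bit-identical draws.
- Growth-fit acceptance checks run at n = 300 records (recovery of
  k = 0.12 within ±0.02 under uninformative priors) and n = 120 truncated
  records (directional prior pull of DW_inf toward 3100·1.01); the
  bootstrap recovery check uses 5,000 sampled individuals and 2,000
  replicates; the Monte Carlo runs its full 10,000 draws.
- Euler-Lotka: Brent tolerance xtol = 1e−14, residual contract 1e−10,
  verified against an independent bisection oracle at 1e−8.
- OLS slopes use `scipy.stats.linregress`; tests check them against the
  closed-form covariance/variance ratio computed independently.

## Known limitations

- The catch curve assumes constant recruitment, a closed population,
  non-selective catch over recruited ages, and a sample large enough to
  represent the age structure; violations bias Z in either direction.
- M = 1/omega is a coarse lifespan-based approximation; r_max inherits its
  error. The Euler-Lotka form assumes knife-edge maturity and constant
  adult mortality.
- The ensemble sampler's Rhat-across-walkers is conservative; treat the
  convergence flag as a prompt to lengthen chains, not as a hypothesis
  test.
- Informative priors deliberately pull DW_inf toward out-of-sample maximum
  size; if the local population genuinely grows smaller than the species
  maximum, the strong preset overestimates asymptotic size by design.
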