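# Methods

## The model

`ratewalk` models counts of events (incident cases, deaths) aggregated
over evenly spaced periods.  Conditional on a latent level of risk, counts
are Poisson:

    y_t ~ Poisson(P_t · exp(η_t)),   t = 1..n,

with P_t the population at risk and η_t the log-rate.  The Poisson
likelihood is appropriate for rare events (rates below roughly 4 per 100);
for nonrare events the binomial family replaces it, y_t ~ Binomial(P_t,
logit⁻¹(η_t)), and the latent walk moves on the logit scale.

Time dependence enters only through the first-difference (random-walk)
prior η_t ~ Normal(η_{t−1}, τ²).  This encodes the one substantive
assumption of the model: risk drifts smoothly, with no parametric trend
shape, no changepoints, and a single smoothness parameter τ learned from
the data.  Because t = 0 does not exist, η₁ needs its own prior,
Normal(−5, 5²) by default — centered on a rate of e⁻⁵ ≈ 674 per 100,000
and wide enough to be diffuse for any rare-event application.  The default
τ ~ HalfNormal(1) is likewise diffuse: year-over-year changes in log-rates
of real diseases are far smaller than 1.

For k related series (e.g. demographic groups), the joint variant draws
increments from a multivariate normal, **η**_t ~ Normal(**η**_{t−1}, Σ),
with Σ = diag(τ)·C·diag(τ) decomposed into per-group scales and a
correlation matrix C with an LKJ(2) prior.  Shape 2 places mild mass
toward independence while allowing strong correlations when the data
demand them.  When a panel carries several age strata, each stratum forms
its own joint system (its own Σ); strata share nothing but the time index.
In the default non-joint mode every (group, stratum) series is fit
independently with its own τ.

### Parameter summary

| parameter | meaning | default | units |
|---|---|---|---|
| `eta1_prior_mean` | center of the η₁ prior | −5 | log rate |
| `eta1_prior_sd` | spread of the η₁ prior | 5 | log rate |
| `tau_prior_sd` | half-normal scale for τ | 1 | log rate per period |
| `lkj_shape` | LKJ concentration for C (joint) | 2 | — |
| `chains` / `draws_per_chain` / `warmup` | MCMC protocol | 4 / 6000 / 3000 | draws |

The protocol defaults mirror the package's reference analysis: 4 chains of
6000 draws each, first 3000 discarded, leaving 12,000 retained draws.

## Sampling

The posterior is explored with the package's own Hamiltonian Monte Carlo
sampler.  The model is small and its gradients are closed-form, so the
sampler works directly on a fused log-density/gradient kernel rather than
an autodiff graph; a finite-difference check and a comparison against the
reference density functions pin the kernel in the test suite, and an
independent affine-invariant ensemble sampler (emcee) run on the reference
densities cross-checks the posterior itself on a small problem.

Choices that matter:

- **Non-centered parameterization.**  The walk is expressed through
  standardized increments, η_t = η_{t−1} + τ·z_t with z ~ Normal(0, 1),
  and τ through log τ.  This removes the funnel geometry that defeats
  centered samplers when τ is small.
- **Vectorized batching.**  Positions are (batch × dimension) arrays where
  a batch element is one (series, chain) pair.  Chains, independent
  series, and replicate datasets all ride the same iteration loop; the
  recovery and calibration studies below fit 100–400 posterior chains in
  one pass this way.
- **Warmup.**  Stan-style windowed adaptation: a fast phase tunes the step
  size per batch element by dual averaging (target acceptance 0.8) against
  a unit metric; doubling windows estimate a diagonal mass matrix from
  warmup draws and restart step-size adaptation; a terminal phase re-tunes
  the step size.  The initial step size comes from the usual
  double-until-acceptance-crosses-½ heuristic.  The number of leapfrog
  steps is drawn uniformly from 1..24 per iteration (1..48 in joint mode,
  where τ needs longer trajectories) to avoid resonance.
- **Correlation updates.**  In the joint model the correlation matrix is
  parameterized by canonical partial correlations (tanh of unconstrained
  values building the Cholesky factor row by row); independent scaled-Beta
  priors on the CPCs induce exactly the LKJ distribution, verified in the
  tests against an onion-method sampler.  These few parameters are updated
  by an adaptive Metropolis step between HMC iterations and carry zero
  momentum during the Hamiltonian flow — they stay fixed along each
  trajectory, so their potential terms cancel in the acceptance ratio and
  the composition remains a valid Metropolis-within-Gibbs scheme.  This
  trades some mixing speed for not having to differentiate through the
  Cholesky construction.
- **Determinism.**  One user seed is expanded through numpy's
  `SeedSequence` into per-chain initialization streams and the shared
  update stream; identical seed, spec, and data give bit-identical draws.
- **Divergences.**  An energy error beyond 1000 marks a transition
  divergent (and rejected).  More than 10% divergent transitions after
  warmup raises an error rather than returning draws.

## Diagnostics and summaries

Convergence gates follow common practice: classic split R-hat (each chain
halved, potential scale reduction over the half-chains) must be below
1.01, and the Monte Carlo SE of each posterior mean (posterior SD divided
by the square root of the bulk effective sample size, the latter via
arviz) must be below 10% of the posterior SD.  The 10% gate quantifies
"MCMC error small relative to posterior uncertainty"; it is this package's
convention.  Parameters with numerically constant draws (e.g. τ pinned by
a degenerate fit) pass by definition.  Summaries are posterior means with
equal-tailed 95% intervals (2.5th/97.5th percentiles), matching the
reporting convention of surveillance tables; highest-density intervals are
deliberately not offered.

All derived quantities — percent change, AAPC, standardized rates,
inequality measures, Theil index — are computed per draw and summarized
afterward.  The mean of a ratio is not the ratio of means, so computing
(say) percent change from summarized rates would bias both the point
estimate and the interval.  AAPC is the arithmetic mean of per-transition
APCs within a window, computed per draw so its CI is a true posterior
interval; a geometric-mean variant (which compounds exactly to the
endpoint ratio) is available via `geometric=True`.  Percent changes
intended for tables are rounded half away from zero.

For age-standardized pairwise comparisons, excess cases are accumulated
stratum by stratum, EC = Σ_i (R_di − R_ai)·P_di, never from standardized
rates: standardized rates weight strata by the standard population rather
than the actual one, so an RD×P shortcut miscounts cases (a test asserts
the two genuinely differ on stratified data).  The advantaged/disadvantaged
orientation of a comparison is declared by the caller; inferring it from
estimated rates could flip between draws and corrupt the intervals.

The Theil index uses expected burdens b_j = R_j·P_j (model rates times
population, inheriting posterior uncertainty) with natural logarithms:
T = Σ ω_j ln(ω_j/p_j).  Its between/within decomposition over nested units
satisfies T_total = T_between + Σ_u s_u·T_within,u exactly, draw by draw.

## Synthetic data

`ratewalk.simulate` runs the generative model forward: Gaussian (or
correlated multivariate-normal) random-walk latents, then Poisson or
binomial counts.  Defaults emulate a realistic registry series — 20 annual
periods, populations of 10⁶, increment scale τ = 0.05, starting rates in
the 100-per-100,000 range (roughly 10³ cases per period) — and an optional
geometric population-growth schedule reproduces the dynamic where a
persistent rate gap yields growing excess-case counts.  Each (group,
stratum) series consumes its own RNG stream spawned from the master seed,
so enlarging a panel never perturbs existing series.

What the generator does *not* emulate: reporting delay, small-cell
suppression, miscoded race/ethnicity, population denominators estimated
with error, or abrupt coding changes.  Passing recovery and calibration
tests therefore demonstrates that the software correctly infers the model
it claims to fit — not that the model is adequate for any particular
registry's artifacts.

## Verification studies

Two simulation studies gate the statistical behavior (both batched into
single sampler passes and sized to run in seconds–minutes on one CPU):

- **τ recovery** — panels of 20 periods with ~10³ cases per period,
  25 replicates at each τ ∈ {0.02, 0.05, 0.1}, fitted with 4 chains ×
  3000 draws (1500 warmup); the 95% CI must cover the generating τ in at
  least 80% of replicates per setting.
- **Interval calibration** — 100 panels simulated with η₁ drawn from its
  prior and τ fixed at 0.05, fitted with 4 chains × 1500 draws; pooled
  95% CI coverage of exp(η_t) must lie in [0.88, 0.99].  (Fixing τ rather
  than drawing it from its prior makes the check slightly conservative;
  exact 0.95 coverage is only guaranteed when all parameters are drawn
  from their priors.)

These reduced draw counts relative to the 6000/3000 analysis protocol are
the package's problem-size choice for repeated-fit studies; single
analyses should use the defaults.

## Numerical notes and limitations

- Degenerate inputs: populations must be strictly positive (a
  zero-population cell is an error, not an NA); suppressed or missing
  count tokens in input tables are hard errors since the model has no
  missing-data pathway; missing periods are structural errors.
- Calendar-year time labels must be consecutive; a gap such as 1999, 2001
  is rejected as a missing period.  Non-integer labels are treated as
  opaque ordered identifiers with even spacing assumed (a warning is
  logged).
- log τ is clipped to ±40 inside the sampler kernels to keep exp finite;
  the clip is far outside any region with posterior mass.
- Quantile-based intervals commute with monotone transforms only up to
  interpolation between order statistics.
- Joinpoint-style changepoint detection is intentionally out of scope, as
  are spatial models, covariates, and indirect standardization (SMR).
- The Poisson family assumes no extra-Poisson dispersion beyond what the
  latent walk absorbs; strongly overdispersed counts at short series
  lengths will inflate τ estimates instead.
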