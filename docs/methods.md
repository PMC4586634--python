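# Methods

## The problem

Cause-specific event counts built from administrative labels (death
certificates are the canonical example) are cross-misclassified: some
events of the cause of interest are labelled as other-cause and vice
versa.  Per observational unit `i` we observe two labelled counts over a
person-time `t_i`:

```
w1_i  events labelled cause-of-interest
w2_i  events labelled other-cause
```

The true counts `y1_i ~ Poisson(t_i λ_i)` and `y2_i ~ Poisson(t_i μ_i)`
are latent.  A true cause-of-interest event keeps its label with
probability `se` (sensitivity); a true other-cause event keeps its label
with probability `sp` (specificity).  With `u1 ~ Binomial(y1, 1-se)` and
`u2 ~ Binomial(y2, 1-sp)` mislabelled each way,

```
w1 = y1 - u1 + u2,    w2 = y2 + u1 - u2.
```

Marginally the observed counts are independent Poissons with mixture
rates

```
E[w1] = t (λ se + μ (1-sp)),    E[w2] = t (λ (1-se) + μ sp),
```

so their total is conserved, `E[w1] + E[w2] = t (λ + μ)`, for every
(se, sp).  `observed_loglik` evaluates this marginal likelihood in closed
form (including factorial constants, so values are true log-pmfs and can
be tested against enumeration); `latent_count_oracle` recomputes single-
unit probabilities by brute-force enumeration of the latent
configurations, using the conservation identity `y1 + y2 = w1 + w2` to
make the enumeration exact.

Rates follow log-linear models with the exposure always in the second
design column:

```
log λ_i = β0 + β1 x_i + z_i'β  [+ random intercept]
log μ_i = γ0 + γ1 x_i + z_i'γ  [+ random intercept]
```

Expected counts are `t_i ×` rate; `t_i` multiplies both mixture terms and
the exponent (standard Poisson offset convention).

## Identifiability and the mirror mode

The likelihood is exactly invariant under the simultaneous swap
(λ, μ, se, sp) → (μ, λ, 1-sp, 1-se): a classifier worse than random with
the streams relabelled explains the data equally well.  `se + sp > 1`
selects the meaningful branch.  The package enforces this at
initialization only (starting values are redrawn from the priors until
`se + sp > 1`; after 1000 failures the priors themselves are declared
inconsistent) and additionally freezes (se, sp) for the first half of
burn-in so the rate models orient themselves into the correct basin
before the classifier parameters move.  Without that freeze a few percent
of chains on simulated data wander into the mirror mode during the
chaotic early phase and cannot leave it (the prior penalty is
astronomical but so is the barrier).  The posterior itself is not
truncated.

## Models

Four analysis models plus the naive baseline:

| label     | effects                   | (se, sp)        |
|-----------|---------------------------|-----------------|
| naive     | any                       | fixed at (1, 1) |
| Model 1   | fixed                     | known values    |
| Model 2   | fixed                     | beta priors     |
| Model 3   | random intercepts         | known values    |
| Model 4   | random intercepts         | beta priors     |

Random-intercept structures:

- `random_shared` — one intercept per cluster added to **both**
  log-rates, variance σ².  This is the structure used by the simulation
  harness (below).
- `random_common_variance` — separate intercepts per stream, common σ².
- `random_correlated` — separate intercepts, bivariate normal with
  (σ1, σ2, ρ).

## Priors

- Coefficients: independent N(0, sd=10) — sd, not variance or precision;
  on the rate scale this allows multiplicative effects over ~17 orders of
  magnitude, i.e. effectively flat.
- se, sp (when unknown): independent Beta(a, b).  From validation data
  (m gold-standard subjects, w correctly labelled) the conjugate form is
  Beta(w+1, m-w+1).  From expert statements, `beta_from_mode_percentile`
  solves "most likely value m, probability p of being below v" by 1-D
  root search; the default matches m as the beta **mode** (the
  Beta-Buster convention), `statistic="mean"` matches it as the mean.
  Published rough summaries of such statements tend to sit closest to
  the mean rule (mode 0.8 / 5% below 0.7 gives (39.0, 9.7) under the
  mean rule vs (48.3, 12.8) under the mode rule); both are exposed and
  both are tested for self-consistency.  The "could be as high as"
  upper statement over-determines a two-parameter family and is treated
  as a check, not a constraint.
- Random-effect scales: σ ~ Unif(0, D), default D = 5 (large enough for
  log-rate dispersion in any realistic count regression; inverse-gamma
  and half-Cauchy alternatives are deliberately not offered).
  Correlated model: σ1 ~ Unif(0, B1), σ2 ~ Unif(0, B2), ρ ~ Unif(-1, 1).

## Posterior computation

The sampler targets the marginal likelihood (latent counts integrated
out) — no data augmentation of y/u is stored.  Blockwise adaptive
random-walk Metropolis with blocks: β, γ, (se, sp) jointly on the logit
scale, σ (or σ1, σ2, ρ), and the per-cluster random intercepts (updated
for all clusters in one vectorized pass with independent accept/reject
per cluster, valid because clusters are conditionally independent).
Proposal scales adapt every 25 iterations toward ~30% acceptance during
burn-in only and are frozen afterwards, preserving detailed balance.

Three structural moves fix the slow directions of this posterior:

1. **Coefficient/intercept translation.**  When every unit in a cluster
   shares a covariate pattern the likelihood constrains only the cluster
   predictors `x_k'β + e_k`; the split between β and the intercepts is
   prior-driven.  The move proposes β → β + δ, e → e - Pδ (P the
   cluster-level design), leaving the likelihood exactly invariant; only
   the priors enter the ratio.  In the shared-intercept model the single
   intercept serves both streams, so β and γ shift together.
2. **Compensated (se, sp) move** (separate-intercepts models).  The data
   pin each cluster's two mixture rates, not (se, sp).  The move
   proposes (se', sp') and solves the 2×2 inversion per cluster for the
   intercepts that keep both mixture rates fixed, again likelihood-
   invariant.  The deterministic transform has per-cluster Jacobian
   `λμ(se+sp-1) / (λ'μ'(se'+sp'-1))`, included in the acceptance ratio.
   Rejected automatically if the inversion leaves the admissible region
   (se'+sp' ≤ 1 or a negative rate).
3. **Conjugate (se, sp) refresh.**  Each observed count is a sum of two
   independent thinned Poissons (kept vs crossed-over events); drawing
   the binomial split and then se, sp from their Beta full conditionals
   is an exact Gibbs move on the marginal space.  It activates together
   with the (se, sp) updates after half of burn-in.

Correctness of the sampler is established two ways: prior recovery with
the likelihood switched off (`fit(..., prior_only=True)` must reproduce
every prior's moments) and agreement with an independently written
log-density driven by an affine-invariant ensemble sampler (emcee) on a
small fixed-effects problem.

Summaries are posterior means with equal-tailed empirical-quantile
intervals (linear interpolation), split-chain rank-normalized R-hat and
ESS (a single chain is split into halves for the diagnostics).  Constant
chains are flagged degenerate rather than erroring.

In **cut mode** (`cut_se_sp=True`) se and sp are redrawn from their
priors every iteration with no Metropolis correction: their marginal
"posterior" equals the prior exactly, and the remaining parameters adapt
to each draw.  This is the Monte Carlo sensitivity analysis device; the
BUGS cut operator is approximated by exactly this prior-only resampling.

Defaults: 4 chains, 5000 burn-in, 5000 kept, thin 1 — deliberately
generous for one-off analyses and overridden downward by the study
harness.  A warning (not an error) fires below 1000 total iterations.

## Simulator and study conditions

`make_design(p, r)` builds the full factorial of `p` binary covariates
(exposure first) with `r` replicates per pattern; units sharing a
pattern share a cluster label.  `generate_dataset` draws intercepts per
cluster (none / common / shared / correlated), then latent Poisson
counts, then the binomial crossover; everything is deterministic given
the seed, and the latent record (y, u, intercepts) is returned only when
explicitly requested.

The coverage-study scenario (`table_truth`) uses three binary
covariates, 4 replicates per pattern (n = 32), person-time 1000,
log-rates

```
log λ = -1 + 0.5 x - 0.5 z1 + 0.1 z2      (stream observed in w1, se)
log μ = -2 - 0.3 x + 0.2 z1 + 0.5 z2      (stream observed in w2, sp)
```

with a **single shared random intercept per unit** (variance σ²)
entering both log-rates, se = 0.9, and sp ∈ {0.8, 0.6}.  Two structural
choices here deserve justification:

- *Unit-level intercepts.*  With pattern-level clusters the exposure
  contrast is identified only through the intercept prior and naive 95%
  widths come out ≈ 0.85 at σ² = 0.10, scaling as √(σ²/2).  Unit-level
  intercepts give widths 2·1.96·√(σ²/8 + Poisson) ≈ 0.47/0.70/0.99/1.20
  across σ² = 0.10/0.25/0.50/0.75 and a naive collapse of coverage to
  ≈ 0.72 — the operating characteristics this harness is designed to
  exhibit.  The intercepts model overdispersion, not cluster
  correlation.
- *Shared between streams.*  If each stream draws its own intercept,
  the two-stream mixture averages the dispersion (each observed
  stream's log-rate variance is ≈ 0.52 σ², not σ²), and — more
  seriously — a corrected model with two free intercepts per unit is so
  flexible that the marginal likelihood tilts (se, sp) away from their
  priors (verified against a 160k-iteration reference run: se posterior
  0.82 under a 0.90 ± 0.042 prior), destroying the correction.  One
  shared intercept per unit keeps (se, sp) prior-dominated, which is
  the regime the corrected-model operating characteristics describe.

The corrected model's priors are centred on the generating values:
se ~ Beta(45, 5) (mean 0.9, sd 0.042) throughout; sp ~ Beta(40, 10)
(mean 0.8, sd 0.056) for the sp = 0.8 scenario and sp ~ Beta(30, 20)
(mean 0.6, sd 0.069) for the sp = 0.6 scenario, keeping the prior
concentration comparable.

The worked sensitivity example (`worked_example_truth`) uses the same
log-linear models but 8 clusters of 4 units with bivariate-normal
intercepts (σ1 = 0.2, σ2 = 0.4, ρ = 0.5), se = 0.75, sp = 0.8 — a large
observational study with unit totals in the low hundreds.

What the simulator does **not** emulate: covariate-dependent
misclassification, time-varying rates, zero-inflation, negative-binomial
dispersion, or exposure misclassification.  Passing tests therefore
certify recovery of this generative structure, not robustness to those
features in real data.

## Study harness

`run_replicates` derives per-replicate seeds from the master seed with a
counter-based scheme (`SeedSequence(master, spawn_key=(r, slot))`), so
any scenario is independently reproducible.  Each fit is screened with
split-chain R-hat < 1.1 on the tracked parameters; failures are re-run
once with doubled burn-in and doubled thinning, then excluded with a
logged count (never silently).  Reported per cell: replicate-averaged
posterior mean, averaged 95% width, empirical coverage, and the Monte
Carlo standard error of each (coverage MCSE = √(c(1-c)/R)).

Problem sizes: the test suite runs R = 64 replicates per coverage
scenario and R = 20 per robustness cell; the acceptance script runs
R = 100 per coverage scenario.  Fits are single chains of 1500 burn-in
and 2000 kept draws at thinning 2; tolerances are always expressed as
three Monte Carlo standard errors computed from the replicates actually
run.  These sizes are the package's default trade-off between Monte
Carlo precision and desk runtime; R = 1000 reproduces the original
experiment scale.

`sensitivity_grid` fits the known-(se, sp) model at each grid pair plus
one cut-mode fit, and `combine_conservative_interval` takes the envelope
(min lower, max upper) across the grid — the conservative reading of a
fixed-value sensitivity analysis.

## Numerical choices and degenerate inputs

- Mixture rates are evaluated in linear space with a floor of 1e-300
  before the log; an exactly zero mixture rate facing a positive count
  returns -inf (documented, not an exception).
- Non-finite proposals (overflowed rates) are rejected inside the
  sampler; `case_rates` raises a structured overflow error naming the
  offending unit when called directly.
- Equal-tailed intervals use linear-interpolation quantiles; with draws
  1..1000 the 95% interval is (25.975, 975.025).
- Cluster labels must form a contiguous 0..K-1 index set; datasets with
  fewer than 100 retained draws cannot be summarized.
- Missing-data cells are rejected at parse time, never imputed.

## Known limitations

- Fixed-effects models with unknown (se, sp) (Model 2) lack the
  structural moves (no free intercepts to compensate with), so their
  (se, sp) chains rely on the conjugate refresh alone and mix more
  slowly; use longer chains there.
- The corrected model's exposure estimate is convex in se, so posterior
  spread in (se, sp) produces a small overcorrection of the attenuated
  effect (visible as replicate-averaged means a few hundredths beyond
  the truth at σ² = 0.10, growing with σ²).  This is a property of the
  exact posterior, not of the sampler — the long-run reference produces
  the same values.
- Hypothesis-testing operating characteristics (Type I error, power)
  are not implemented; the harness exposes the hooks (per-replicate
  intervals) needed to add them.
- Random slopes and BUGS-language export are out of scope.
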