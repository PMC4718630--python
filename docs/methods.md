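# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
surveys do and do not establish about real data.

## Detection histories

Photographic records are reduced to events by merging, within each
(point, species), any image closer than one minute to the previously
retained event (greedy left-to-right; images exactly one minute apart
are distinct events). Species enter the analysis if body mass ≥ 100 g
and the species is ground-dwelling, or is arboreal but yielded ≥ 5
events in every surveyed year at at least one site.

Per population and year, a points × days matrix holds 1 (photographed),
0 (sampled without a photograph) or missing (camera not active); days
are then grouped into 15 contiguous periods covering the site's season
window, so each period spans ~7–8 days. The boundary rule is fixed for
reproducibility: with D days, the first `D mod 15` periods are one day
longer. A period is 1 if any constituent day is 1, missing only if no
day was sampled. Grouping changes the time unit of the detection
probability, not the occupancy estimates.

Populations are stratified by two statistics computed on the grouped
matrices: the annual detection rate (total detections over total
*sampled* cells — missing cells are excluded from the denominator so
staggered deployments do not deflate the rate) and mean detections per
year. Rate > 8% → Case 1; otherwise < 5 detections/year → Case 3;
otherwise Case 2. The 8% rule is applied on the period scale (the scale
the models operate on).

## Occupancy models

State process per point j: `Z_j1 ~ Bern(ψ_1j)`;
`Z_j,t+1 | Z_jt ~ Bern(Z_jt φ_jt + (1 − Z_jt) γ_jt)`; occupancy is
closed within years. Observation process: each sampled period is
`Bern(Z_jt p)`; absence generates structural zeros. The marginal
likelihood sums the latent states out by a two-state forward recursion
per point and is the correctness oracle for the samplers (the tests
compare it with exhaustive latent-state enumeration on small instances).

**Case 1.** Covariates are z-scored within site (sample sd; the binary
people covariate is left as is). Logit-linear effects: initial occupancy
~ elevation, people (year 1), distance to edge; survival and
colonization ~ rain, max/min temperature (year-level) and people
(point × year). Transitions from year t use source-year covariate
values. Each of the 11 effects is multiplied by an inclusion indicator
with prior `Bern(0.5)` (Kuo–Mallick indicator selection), so the chain
samples the full 2¹¹ model ensemble and occupancy draws are model
averages.

Sampling is Metropolis-within-Gibbs with latent-state augmentation:

- `Z` by forward-filtering backward-sampling per point (closed-form
  conditionals);
- `p` by conjugate Beta–Gibbs (`Uniform(0,1)` prior);
- intercepts and included effects by adaptive random-walk Metropolis
  (proposal scales tuned toward 0.44 acceptance during burn-in only,
  then frozen, keeping the retained chain valid);
- excluded effects refreshed from their prior; indicators by their
  Bernoulli full conditionals.

Priors. Effects: `Normal(0, sd 10)` — deliberately vague, which also
gives indicator selection a strong Occam penalty; a weaker sd-2.5 slab
was prototyped and rejected because null effects in weakly identified
blocks then hover at E[w] ≈ 0.5. Intercepts: standard logistic on the
logit scale, which is exactly `Uniform(0,1)` on the probability scale;
this makes the all-indicators-off submodel coincide exactly with the
Case 2 model (the tests exploit this for a cross-validation of the two
samplers) and is the genuinely uninformative choice.

**Case 2.** Constant ψ₁, φ, γ, p with `Uniform(0,1)` priors; every
update is then conjugate Beta–Gibbs given the augmented states — same
posterior as a Metropolis implementation, with no tuning.

**Case 3.** Per year, x of n sampled points with ≥1 detection; posterior
`Beta(a₀+x, b₀+n−x)` with a flat prior by default (`Beta(0.5, 0.5)`
available); 1,000 independent draws per year; years with no sampled
points are marked missing.

Chain settings: the "full" profile runs 3 chains of 250,000 iterations
(Case 1) or 30,000 with 29,000 burn-in and thinning by 3 (Case 2); the
"fast" profile — the package default for routine work — runs 3 chains of
5,000. Both retain 1,000 total draws split across chains ("last 1,000"
is read as total, consistent with Case 2's arithmetic). Convergence is
monitored with the classic potential scale reduction factor (implemented
directly; the popular rank-normalized variant would not match the
textbook formula the tests check against); any parameter at R̂ ≥ 1.03
raises a warning and flags the fit, but draws are still returned.

Annual occupancy per retained draw is the population-level recursion
`ψ_{t+1} = ψ_t φ_t + (1−ψ_t) γ_t` evaluated at that draw's parameters,
with covariate terms averaged over points (Case 1). The realized
proportion of occupied points is available behind `annual="realized"`;
the recursion is the default because the index tracks the population
process, not one finite-sample realization.

## WPI

`WPI_t = exp( mean_i log(ψ_ist / ψ_is1) )` per draw index; draws are
paired across populations by index, which is a valid convolution of
independent posteriors. ψ is floored at 1e-6 before logs (the geometric
mean is otherwise undefined at 0; the floor preserves ordering). The
per-year central value is the median or the half-sample mode, whichever
is lower (the mode guards against the right skew of ratio
distributions); 50/80/95% percentile envelopes are reported.
Aggregation across sites is the population-count-weighted geometric mean
per draw and year — with these weights the aggregate equals the pooled
community's index exactly — and a later-starting site is excluded at its
own baseline year, where its index is the constant 1 and carries no
information. All three detection cases enter the site index by default
(`include_case3_in_wpi=False` drops Case 3).

## Trend classification

For each posterior realization, `ψ(t) = logistic(α + βt)` is fitted by
ordinary least squares on logit(ψ) against time (ε-clipped at 1e-6).
Because each realization is a deterministic trajectory inside (0,1),
this reparameterization is exact — a binomial-family IRLS fit is kept as
the independent test oracle, not the implementation. Years are centered
before fitting (numerical symmetry; the slope is unchanged). The 80%
interval is the (10th, 90th) percentile pair of the slope draws,
type-7 (linear-interpolation) quantiles. Entirely below zero →
Decreasing; above → Increasing; else Stable, relabelled Unknown for
Case 3; an interval touching zero exactly counts as straddling — the
conservative reading, since early warnings are preferred to missed
declines.

## Community statistics

G-tests use `G = 2 Σ O ln(O/E)` with zero cells contributing zero and no
continuity correction (this reproduces the published 0.61 and 35.44 on
the detection-level × status table); computed via scipy's log-likelihood
ratio mode. Six factor families (class, IUCN, mass category, guild,
landscape, hunting) are tested at Bonferroni α = 0.05/6 ≈ 0.008. Mass
bins are 100–1,000 g, 1,001–10,000 g, > 10,000 g. Site-proportion GLMs
are binomial events/trials fits weighted by populations per site (the
unweighted variant is a flag, since the source formulation leaves
weighting ambiguous); AIC is −2 log L + 2k with k the nominal column
count, so an uninformative covariate costs exactly 2. Landscape
classification square-root transforms edge density, computes pairwise
Mahalanobis distances from the sites' own 2×2 covariance (no
regularization; collinear metrics raise an error, exactly identical
sites short-circuit to one cluster), and cuts a UPGMA dendrogram at
height 1.5.

## Synthetic surveys

The generator emulates the standardized protocol: 60 points (default),
a 112-day season window, 30-day deployments staggered so the union of
active windows spans the season, 3–8 annual surveys. Ground-truth
occupancy follows the exact state process above, including optional
logit-linear covariate effects applied to standardized covariates.
Ground-truth detection is defined per ~7.5-day period — the scale the
models estimate — and converted to a daily Bernoulli rate via
`p_day = 1 − (1−p)^(1/period_length)`; a detected day yields one event
at a random daytime hour, sometimes with extra images under a minute
later so the event-collapsing step has work to do. Default dynamics
(ψ₁ = 0.6, φ = 0.8, γ = 0.1, p = 0.3) describe a moderately common,
slowly declining forest species and put the population at Case-1
detection; Case 2/3 populations are produced by lowering p (≈0.1 and
≈0.05 at 30 points).

What the simulations do not contain: spatial autocorrelation between
points, animal movement or home-range structure, within-day detection
clustering beyond the duplicate-image mechanism, observation-level
heterogeneity in p, and species misidentification. Passing recovery
tests therefore establishes the estimators' correctness under the
model's own assumptions — not robustness to their violation in field
data.

## Problem sizes and tolerances

Routine tests and the recovery experiments run the fast MCMC profile
(3 × 5,000 iterations) at the protocol's natural scale (60–100 points,
5–6 years, 20 replicates), which keeps the full suite within tens of
minutes on one core while leaving the full-length profile one flag
away. Monte-Carlo assertions use explicit error budgets (3× batch-means
MCSE for posterior-mean comparisons, exact binomial intervals for
simulated frequencies); deterministic oracles are checked at 1e-8 to
1e-12. The indicator-selection experiment simulates a community that is
well identified in every block (γ = 0.3, p = 0.5) because a selection
sanity check is meaningless when a block's likelihood is flat; the
parameter-recovery experiment uses the canonical declining community
(ψ₁ = 0.6, φ = 0.8, γ = 0.1, p = 0.3).

## Known limitations

- The trend classifier's 80th-percentile rule has a nominal false-trend
  rate near 20% for genuinely stationary populations — that is the
  flip side of the deliberate early-warning bias — and in simulations
  of well-detected stable populations the realized rate is slightly
  above nominal (~25–30%), because any finite set of points drifts from
  its realized first-year occupancy toward the survival/colonization
  equilibrium and the posterior correctly tracks that realized drift.
  Status calls for individual populations should be read with this
  base rate in mind; the community-level summaries are the robust
  output.

- Case-1 covariate effects are shared across points and years within
  their block; no spatial random effects or detection covariates.
- At fast-profile chain lengths, intercept chains occasionally exceed
  R̂ = 1.03 and are flagged; the full profile resolves this at ~50×
  the cost.
- The Case-3 posterior conditions on naïve occupancy and therefore
  inherits its downward bias under imperfect detection; that is the
  method's intent (error quantification for sparse data), not a bug.
- Aggregation assumes populations' posteriors are independent across
  sites and species; draw-index pairing is one valid convolution but
  not the only one.
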