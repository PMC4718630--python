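# wpimon

Standardized assessment of wildlife population trends from camera-trap
surveys: detection-stratified Bayesian dynamic occupancy models, the
Wildlife Picture Index (WPI), population trend classification, and
community-level status statistics — with a synthetic-survey generator
that provides known ground truth for every stage.

## Who this is for

Ecologists and biodiversity analysts working with standardized
camera-trap monitoring (60–90 points per site at ~1 point / 1–2 km²,
each deployed ≥30 consecutive days in an annual dry-season window,
repeated for 3–8 years). Raw photographic records are reduced to
presence–absence detection histories; most tropical forest mammals and
birds are detected far too rarely to estimate abundance, so occupancy —
the probability that a species occupies a sampling point in a given
year — is the monitored state variable, and imperfect detection must be
modelled rather than ignored.

## The model

Each population (a species at a site) is assigned a detection level and
an estimator to match:

- **Case 1** (annual detection > 8%): dynamic occupancy model with
  covariates. Latent occupancy `Z_j1 ~ Bernoulli(ψ_1)` evolves between
  years through survival φ and colonization γ,

  `ψ_{t+1} = ψ_t φ_t + (1 − ψ_t) γ_t`,

  while period-level detections are `y_jtk ~ Bernoulli(Z_jt p)`.
  Logit-linear covariate effects act on initial occupancy (elevation,
  people, distance to edge), survival and colonization (rain, max/min
  temperature, people); each of the 11 effects carries a
  `w_i ~ Bernoulli(0.5)` inclusion indicator, so the MCMC averages over
  the 2¹¹-model ensemble and `E[w_i]` measures covariate importance.
- **Case 2** (≥5 detections/year but ≤8%): the same dynamic model with
  constant ψ₁, φ, γ, p and no covariates.
- **Case 3** (<5 detections/year): per-year naïve occupancy with a
  conjugate Beta–binomial posterior (too little data to separate low
  detection from low occupancy).

Posterior annual-occupancy draws feed the WPI — the geometric mean of
baseline-relative occupancies over the n populations of a community:

`WPI_t = exp( (1/n) Σ_i log(ψ_it / ψ_i1) )`

computed per posterior draw, so the index has a full posterior each year
(identically 1 in the baseline year). Trends are classified per
population by fitting `ψ(t) = logistic(α + βt)` to every posterior
realization; a slope distribution whose 80th-percentile interval lies
entirely below (above) zero is Decreasing (Increasing), anything else is
Stable — except Case 3, where "no detectable change" reflects lack of
power and is labelled Unknown. Community analyses compare status
frequencies across factors with G-tests (Bonferroni α = 0.05/6), relate
per-site status proportions to site covariates with binomial GLMs and
AIC, and classify landscapes by UPGMA clustering of Mahalanobis
distances on (proportion forested, √edge density), cut at height 1.5.

## Worked example

```python
import numpy as np
import wpimon as w

cfg = w.CommunityConfig(rng_seed=42, species=[
    w.SpeciesParams("red_duiker", psi1=0.6, phi=0.8, gamma=0.1, p=0.3)])
bundle = w.simulate_bundle(cfg)
hist = w.prepare_populations(bundle["events"], bundle["deployments"],
                             bundle["traits"], site="SIM")["red_duiker"]
case = w.classify_case(hist)                       # -> Case 1 (10.8%)
model = w.DynamicOccupancyModel(case=1, seed=0).fit(hist, bundle["covariates"])
rec = w.classify_population(model.to_draws(population="red_duiker", case=1))
series = w.compute_wpi([model.to_draws(population="red_duiker", case=1)])
```

Output of the full script:

```
case level:      1 (annual detection 10.8%, 31.4 detections/yr)
posterior mean psi: [0.555 0.494 0.439 0.411 0.385]
true annual psi:    [0.6   0.52  0.464 0.425 0.397]
highest inclusion: gam_peop E[w]=0.25
trend: slope -0.169 (80% interval -0.312 to -0.043) -> Decreasing
WPI central: [1.    0.864 0.775 0.723 0.679]
```

The simulated species declines (true ψ drops from 0.60 to 0.40 over
five years); the posterior means track the truth, no covariate reaches
the E[w] > 0.5 inclusion threshold (none was simulated), the slope
interval excludes zero so the population is classified Decreasing, and
the single-population WPI falls accordingly from its baseline of 1.

The same chain runs from a shell:

```sh
wpimon run --out-dir run1 --seed 2   # simulate→prepare→fit→wpi→classify→analyze
```

writing `cases.csv`, `draws.csv`, `wpi.csv`, `status.csv`, `report.json`
and a `manifest.json` with input hashes and seeds.

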