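# benthovuln

Trait-vulnerability analysis of Mediterranean benthic mass mortality events
(MMEs): which combinations of ecological traits are being lost as abnormal
mortality episodes — marine heatwaves, storms, disease outbreaks, mucilage,
pollution — hit benthic species populations.

The package is aimed at marine community ecologists working with
species-by-trait tables and event-level mortality records. It provides, as a
tested reusable pipeline:

- **Functional entities (FEs).** Species sharing an identical combination of
  ten categorical traits (feeding, longevity, coloniality, morphology,
  carbon storage, energetic resource, height, growth rate, calcification,
  motility) collapse into one FE; redundancy statistics (mean/max species
  per FE, singleton share) quantify how buffered the assemblage is.
- **Trait space.** Gower dissimilarity over mixed nominal/ordinal traits
  (d(i,j) = (1/T) Σ_t δ_t with 0/1 nominal mismatch and range-scaled rank
  differences for ordinal traits), embedded by principal coordinates
  analysis; the dimensionality m minimizes the mean absolute deviation
  (mAD) between Gower and embedded Euclidean distances.
- **Impacted trait volume.** The convex-hull volume V of impacted-FE
  coordinates over the global-hull volume, cut by mortality severity (low
  < 30%, moderate 30–60%, severe > 60%), driver class, region, and year;
  unbalanced survey effort is handled by balanced resampling (draws of 100
  records, 1000 repetitions).
- **Zero-one-inflated beta (ZOIB) regression.** Bayesian models of percent
  mortality on trait categories, and of annual impacted volume on
  per-driver impacted-FE counts:
  P(Y=0) = p01·(1−ζ′), P(Y=1) = p01·ζ′, and on (0,1) a Beta(μφ, (1−μ)φ)
  density weighted by 1−p01, with logit(μ) = Xβ, flat priors on β,
  Student-t(3, 0, 2.5) on the intercept, Gamma(0.01, 0.01) on φ.
  Sampling is conjugate Gibbs for the point masses plus adaptive Metropolis
  for the regression block; convergence is certified by rank-normalized
  split R-hat ≤ 1.01 and fits summarized with Bayesian R².
- **Synthetic data with ground truth.** A generator emulating the study
  conditions (389 species, ~220–230 FEs, a 1986–2020 record stream rising
  from 88 to 997 events per five-year period, driver frequencies dominated
  by temperature anomalies, trait-dependent severities), so every stage can
  be validated against known parameters.

## Worked example

```sh
python examples/functional_entities.py
```

```
389 species -> 223 functional entities
mean species per FE: 1.74 (max 12)
singleton FEs: 171 (76.7%)
```

A simulated 389-species assemblage collapses into 223 FEs; 171 of them hold
a single species, i.e. three quarters of the realized trait combinations
have no redundancy and disappear with their only carrier.

```sh
python examples/severity_regression.py
```

```
max split R-hat: 1.0025 (retained draws: 2000)
  calcification=a: 62.4% [60.9%, 63.8%]
  calcification=b: 65.4% [64.0%, 66.9%]
generating effect on category 'b': {'b': 1.2}
```

The ZOIB severity model recovers the injected vulnerability of calcified
species: their posterior mean mortality exceeds the uncalcified category,
with converged chains (R-hat ≈ 1.00). Other scripts in `examples/` cover
dataset simulation, trait-space construction, severity-gradient volumes,
and regional balanced resampling.

A thin CLI wraps the same pipeline: `benthovuln simulate`,
`benthovuln run`, `benthovuln validate` (YAML configs; see
`benthovuln --help`).

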