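# Methods

## Data model

A **mortality record** is one quantified MME observation: a species
population at a georeferenced site and year, with a driver set and a
percent mortality recorded in 10% steps from 10 to 100. Records with drivers
of both classes (abiotic: temperature anomaly, storm, pollution, turbidity
increase, other abiotic; biotic: disease, mucilage coverage, predator
outbreak, other biotic) are tagged as a *combination* rather than duplicated
across classes. Rows whose percent mortality is blank ("observed but not
quantified") are counted and excluded from analysis. Severity classes
partition the percent grid: low < 30, moderate 30–60 inclusive, severe
> 60. The boundary values 30 and 60 are moderate because "below 30%" and
"exceeding 60%" exclude them from the outer classes; since percentages are
10% steps, only those two values are affected.

A **trait table** holds ten categorical traits per species, validated
against a typed schema (nominal or ordinal, fixed vocabulary). Missing or
out-of-vocabulary values are errors, never imputed: the analysis assumes a
complete characterization, and silent imputation would contaminate FE
construction. The morphology vocabulary carries twelve categories even
though realized datasets may use fewer — the schema is the vocabulary, the
data its realization.

**Functional entities** group species with identical ten-trait signatures.
FE identifiers are assigned in lexicographic signature order, so
construction is deterministic and invariant to row order. An FE is
*impacted* by a record subset as soon as one member species appears in one
record: within-FE redundancy is no protection once any member proves
vulnerable.

## Trait space

Pairwise dissimilarities between FE signatures use the Gower metric with
equal trait weights: nominal traits contribute 0/1 mismatches; an ordinal
trait with K vocabulary categories at ranks 1..K contributes
|rank_i − rank_j| / (K − 1). We compute distances on FE signatures directly;
because species within an FE are identical in every trait, this equals the
species-level matrix with duplicate rows collapsed. A tie-adjusted ordinal
variant (Podani ranks on realized values) is available behind a flag;
range-scaled vocabulary ranks are the default as the plainest reading of
"Gower with equal weights".

Principal coordinates analysis is classical metric scaling: double-center
−D∘D/2, eigendecompose, scale eigenvectors by the square roots of positive
eigenvalues. Negative eigenvalues (inevitable for non-Euclidean Gower
matrices) are reported but contribute no axis; no Cailliez or Lingoes
correction is applied, so the quality selection operates on the uncorrected
space. Eigenvalues below 1e−9 of the largest are treated as zero.

The embedding dimension m is selected from candidates 2–10 by minimizing
the mean absolute deviation between the Gower distances and the Euclidean
distances on the first m axes, over all unordered pairs. Ties — including
the floating-point-level ties that arise when the input is exactly
Euclidean and every m at or above the true dimension attains numerically
zero mAD — are broken toward the smallest m (within 1e−12 of the minimum).
mAD compares raw embedded distances by default; a flag rescales them to
[0, 1] first. On study-scale synthetic tables the profile bottoms out
around m = 6–8 with mAD ≈ 0.05.

## Trait volumes

The trait volume of an FE set is the m-dimensional volume of the convex
hull of its coordinates (Qhull), using the first m_selected axes. Impacted
fractions divide by the global-hull volume, which is cached per space.
Sets with fewer than m+1 points, or affinely dependent ones, are flagged
degenerate and score volume 0 rather than a lower-dimensional measure —
this keeps fractions well-defined and makes the flag visible downstream.

Severity-gradient subsets use ≥-thresholds at 10..90 plus a top bin at
exactly 100% mortality. Regions band longitude at 11.5°E and 22.0°E
(configurable; conventional Western/Central/Eastern Mediterranean cuts —
Sicily Channel and western Aegean). The driver × year grid has twelve
classes (five abiotic singles + abiotic combination, four biotic singles +
biotic combination, mixed abiotic × biotic), giving 420 cells over a
35-year study window. Decade and five-year summaries are arithmetic means
over calendar windows aligned to the first study year.

Balanced resampling draws n = 100 records without replacement per
repetition (observations are unique events, so replacement would duplicate
them), R = 1000 repetitions, and reports the impacted fraction and FE-count
distributions. With n equal to the group size every repetition reproduces
the full-group value exactly, which the tests assert.

## ZOIB regression

Percent mortality lies on [0, 1] with genuine mass at total mortality, so
models use the zero-one-inflated beta family: total point-mass probability
p01, conditional-one probability cond_one, and a mean/precision beta
component on (0, 1). The published mixture equations do not define a
normalized density as printed; we implement the standard family (the one
the brms `zero_one_inflated_beta` family defines) and expose the mapping
ω ↔ p01, ζ ↔ p01·cond_one. Priors: flat coefficients, Student-t(3, 0, 2.5)
intercept, Gamma(0.01, 0.01) precision, Beta(1, 1) point-mass
probabilities.

The severity models regress per-record mortality on the record species'
category of one trait (ten models, one per trait; reference coding, first
observed category as reference); the volume model regresses annual
impacted fractions on per-driver-class impacted-FE counts. Chain plans:
2 chains × 2000 draws with 1000 warmup (2000 retained) for severity,
2 × 3000 with 1000 warmup (4000 retained) for volume.

The sampler exploits the model structure. The point-mass block is exactly
conjugate given the observed zero/one counts and is drawn by Gibbs. The
regression block uses Metropolis updates with several sweeps per recorded
draw: saturated categorical designs are reparameterized to per-category
means (unit Jacobian; removes the intercept–coefficient correlation, after
which componentwise kernels with Robbins–Monro scale adaptation mix best),
while numeric designs are centered and sampled with a covariance-adapted
joint kernel (Haario-style, scale tuned to ~23% acceptance) after a
componentwise warmup phase. Beta-likelihood evaluations reduce to per-group
sufficient statistics (n, Σ log y, Σ log(1−y)), so cost is independent of
the record count for categorical designs.

Convergence is certified by rank-normalized split R-hat (via arviz) ≤ 1.01
on every parameter; exact equality to 1 is unattainable in finite chains.
Constant chains return 1 with a warning. Reduced chain plans used in some
fast tests carry more R-hat estimation noise and use a correspondingly
looser gate there; production plans keep 1.01. Bayesian R² is the per-draw
var(fitted)/(var(fitted)+var(residual)) with fitted values the mixture
means p01·cond_one + (1−p01)·μ_i.

## Synthetic data

The generator provides ground-truthed inputs with the study's statistical
structure: 389 species, a record stream over 1986–2020 whose five-year
counts interpolate geometrically between 88 and 997 (the published
endpoints), driver labels with temperature anomalies at roughly half of all
labels (~85% of abiotic ones), a rising share of multi-driver events, ~70%
of records in the western basin, and an impacted pool of ~19% of species.
Severities are ZOIB draws with logit(μ) = baseline + the sum of the
species' trait-category effects, discretized to the nearest 10% step;
zero draws and values rounding below 10% are unquantifiable events and are
redrawn, so period counts match the schedule exactly, and one-draws map to
100%. Defaults (baseline −2.8, φ = 0.7, zoi = 0.12, coi = 0.85, one
vulnerable category per trait) were fixed once by simulation to approximate
the published severity mix (≈55/21/24 vs 54/20/26 severe/moderate/low).

Trait values are drawn from a latent-archetype mixture by default: each
species copies archetype trait values with probability 0.92 and draws the
rest uniformly, with 60 archetypes under gently decaying weights. The
archetypes induce the between-trait correlation real assemblages show;
with ten independent traits, any marginals concentrated enough to collapse
389 species into ~228 FEs would force a single dominant signature of 25+
species, where the observed maximum is 12. Supplying explicit per-trait
category probabilities switches to independent sampling. The generator does
not emulate spatial coastline structure, environmental covariates, or
taxonomic correlation between phylum and traits — passing tests demonstrate
correctness of the computations under the modeled structure, not ecological
realism of any particular dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run the full pipeline at study scale
(389 species, ~2800 records) and validate geometry against closed forms
and a 10⁶-draw Monte-Carlo rejection oracle (instance sizes chosen so the
oracle's own standard error sits well inside the 2% comparison band).
Parameter-recovery checks use n = 2000 responses over 20 seeded
replicates at the production chain plan; the posterior-calibration check
uses reduced plans at n = 400. Degenerate inputs (single-category traits,
all-zero responses, groups smaller than the subsample, contradictory year
windows) raise typed errors rather than guessing. All randomness flows
through explicit integer seeds; identical seeds give byte-identical CSV
output and identical posterior draws.

## Limitations

- The trait-space quality criterion is the mean absolute deviation only;
  alternative quality indices (squared deviation, kernel-density
  hypervolumes) are out of scope.
- Hull-based volumes ignore FE abundance: a one-species FE stretches the
  hull as much as a twelve-species FE shifts nothing.
- The severity models treat records as independent observations; repeated
  events on the same population and spatial autocorrelation are not
  modeled.
- Discretizing ZOIB draws to 10% steps (the database convention) slightly
  biases naive refits of the continuous model to record data; recovery
  guarantees are stated for continuous responses.
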