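# Methods

This note records the modelling assumptions, numerical conventions and open
design choices behind the package, in the spirit of a statistical software
methods appendix. Nothing stated here is an empirical claim beyond what the
test suite and `scripts/acceptance.py` compute.

## Consensus model

The unit of inference is a *gene set consistently co-expressed across all
datasets*. Each of the `L` datasets is clustered independently by `C`
methods at a fixed cluster count `K`, giving `R = C × L` hard partitions;
their element-wise average after label alignment is the fuzzy consensus
partition matrix (CoPaM), whose entry `(k, g)` estimates the probability
that gene `g` belongs to consensus cluster `k` across the evidence. The
difference-threshold binarisation (DTB) turns this into hard gene sets at a
tunable stringency `δ`. Two modelling consequences worth keeping in mind:

* **Missing-gene weighting.** A gene's memberships are averaged only over
  partitions whose dataset contains it. The estimator for a gene present in
  `L*` of `L` datasets therefore has higher variance than for a complete
  gene; the `L*` inclusion threshold (default 13 of 16) bounds this.
* **Reference dependence.** All partitions are aligned to one reference (the
  first method on the first dataset, per `K`). Any fixed reference yields
  the same consensus up to row permutation; the choice only fixes row order,
  and is made deterministically.

### Min-min relabelling

The alignment cost of reference cluster `i` and target cluster `j` is the
symmetric difference of their gene sets restricted to the genes both
partitions contain. The globally minimal unmatched pair is matched first
(ties to the lowest `(i, j)` index), so the best-recovered clusters align at
the expense of poor ones — appropriate when only the top clusters are kept.
The cost function is a package choice; an empty cluster's cost against a
non-empty one degenerates to the latter's size, letting empty SOM units
participate without special-casing.

### DTB conventions

The margin comparison is non-strict (`≥ δ`), matching the "lower by at least
δ" reading; at `δ = 0` a strict unique maximum is required so that exact
ties remain unassigned and `δ = 0` stays meaningful. This gives the nesting
property: the cluster at `δ₂ ≥ δ₁` is always a subset of its `δ₁` version
(asserted over the full grid in the tests).

## Base clusterers

* **Kaufman k-means** — fully deterministic: first centre minimises total
  Euclidean distance to all points; each next centre maximises the summed
  positive reduction in the points' nearest-centre distances; then Lloyd
  iterations (squared Euclidean, ≤ 300, emptied clusters re-seeded with the
  farthest point).
* **Bubble SOM** — online SOM on the most-square grid factorising `K`
  (4×4 for `K = 16`; `|rows − cols|` minimal otherwise — the per-`K` grid is
  a package choice). The bubble neighbourhood updates every unit whose grid
  distance to the best-matching unit is *strictly* below the radius; the
  radius decays linearly from `max(grid dims)/2` to 1 and the learning rate
  from 0.5 to 0.01 over `100·G` updates. The strict comparison matters: a
  non-strict bubble at the terminal radius of 1 would keep dragging
  neighbouring units together and collapse small grids. Sample order is
  drawn by seeded shuffles of a canonical (lexicographic) row ordering, so
  the result is reproducible *and* invariant to permutations of the input
  rows. Units that end empty are kept as empty clusters so `K` is preserved
  for relabelling. The inner loop is numba-jitted when numba is present.
* **Ward clustering** — scipy's Ward linkage on Euclidean distances, tree
  cut at exactly `K`; the linkage is computed once per dataset and re-cut
  for every `K` in the grid.

## M-N selection

Dispersion of a candidate is the mean over datasets of
`(1/(n·D)) Σ_g ‖x_g − mean profile‖²` computed on the genes present in each
dataset (a package definition of the "modified MSE"; singletons score 0).
Both axes are min-max normalised over the candidates *currently on the
plot*, and the normalisation is recomputed after every overlap-removal round
— a deliberate choice, since the corner is only defined relative to the
points present. A consequence is that selection distances are not comparable
across rounds and need not be monotone. A degenerate axis (all candidates
equal) contributes zero to the distance. Overlap removal is strict (any
shared gene); distance ties prefer the larger candidate, then the lower
`(K, δ, index)` provenance.

## Enrichment

The overlap test is the exact one-sided (upper-tail) hypergeometric
probability with the study's gene universe as background, target lists
intersected with the universe before testing. The tail is summed in log
space (log-gamma binomial coefficients combined with logsumexp), which keeps
full relative precision at tails around 1e-52; the tests pin it against an
exact rational-arithmetic oracle for universes up to 60 and against scipy in
the extreme-tail regime. No multiple-testing correction is applied — these
are single-comparison p-values by design.

## Clinical statistics

* **Hypoxia score** — per-sample median over the present signature genes,
  average-ranked over samples, scaled `(rank − 1)/(n − 1)`. Rank-basedness
  makes the score invariant to strictly increasing transforms of expression;
  note the invariance is exact only for odd signature sizes (an even-count
  median interpolates between order statistics).
* **Cox regression** — univariate partial likelihood on the score
  (lifelines, Efron ties, Wald p). The hazard ratio is per full 0→1 range
  of the score, not per dichotomised groups.
* **ROC/AUC** — positives are events within the horizon (default 10 years),
  negatives survived past it, censored-before-horizon samples excluded; AUC
  via the Mann-Whitney statistic with the asymptotic normal p-value.
* **ER ANOVA** — per-gene p-values from two-group ANOVA on standardised
  (zero-mean, unit population-sd) expression; fold-changes as ratio of group
  means on the positive scale. The signature-level fold-change is the
  geometric mean of member fold-changes; significance compares members
  against the rest of the genome by ANOVA on `log(−log p)` and on
  `log(fold-change)`, with the fold-change-scale p reported as the headline
  (it is the one paired with a fold-change) and the other returned
  alongside. p-values are clipped to `[1e-300, 1]` before the double log.
* **Tightness test** — observed MSE of the standardised expression block
  versus a normal distribution fitted to the MSEs of `n_random = 1000`
  random same-size gene sets; `p = Φ((obs − μ̂)/σ̂)` (smaller MSE more
  favourable). The normal fit is adequate for set sizes ≳ 10 by CLT; for
  very small sets the p-value is approximate.
* **Sub-cluster discovery** — hierarchical clustering of `1 − ρ` Spearman
  distances (default average linkage, distance cut 0.6, minimum size 5, all
  configurable); constant rows are excluded with a warning.

## Conventions

Standard deviations use the population (denominator `n`) convention
everywhere. Gene identifiers are trimmed and compared case-insensitively.
Quantile-normalisation ties receive the mean of the cross-column rank means
they span. Missing cells are rejected, never imputed — the missing-data unit
of this framework is a whole gene per dataset. Floats are written to TSV
with 6 significant digits. Note that one-colour normalisation (quantile
normalisation then per-gene z-scoring) is *not* idempotent: re-quantile-
normalising a z-scored matrix assigns fresh rank means. Row moments (mean 0,
sd 1) are nonetheless stable under re-application; only the two-colour
centring path is exactly idempotent.

## The synthetic world

The generator's defaults state the testing world: 16 one-colour datasets
with 3–7 conditions, 2,000 genes, two anti-correlated planted clusters of
120 and 150 genes, per-dataset Gaussian noise of sd 0.3 around piecewise-
linear monotone latent trajectories (endpoints ±1, one random interior
breakpoint — the gradual up/down regulation seen in hypoxia time courses),
15% per-dataset missing genes with every gene kept in ≥ 13 datasets
(rejection sampling), and background genes carrying independent unit-variance
noise. Clinical cohorts are log-normal-like: signature-gene log-expression
tracks a latent uniform [0, 1] score with amplitude 2 plus noise (sd 0.3);
survival is exponential with log-hazard `Σ β_S · HS_S` using the *realised*
rank-scaled median score (the exact covariate the downstream Cox fit sees),
uniform censoring calibrated by bisection to the target rate, Bernoulli(½)
ER labels, and multiplicative ER fold-changes on member genes. The
`n_background_genes` control (default 1,000) exists because genome-wide
backgrounds are needed by the signature-level ER test and the tightness
test.

What the generator does **not** emulate: platform-specific probe artefacts,
batch effects, correlated background structure, non-proportional hazards,
informative censoring, or missing-at-random violations. A green test
therefore establishes that the algorithms recover *planted, well-specified*
structure — it does not certify behaviour on real cohort data with
confounding.

## Known limitations

* The consensus assumes every dataset carries signal for the same cluster
  structure; datasets where a planted pattern is absent dilute its
  membership rather than being down-weighted adaptively.
* M-N selection returns an ordered list but no significance statement; how
  many clusters to keep remains a judgement on the distance gap.
* The SOM is the only stochastic base method; its seed is recorded in the
  partition provenance and derived deterministically from the run seed.
* Cox fits are univariate by design; no clinical covariates, no competing
  risks.
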