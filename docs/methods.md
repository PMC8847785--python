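# Methods

## The question and the design

A common-garden transplant separates host-driven from environment-driven
microbiome membership. Oysters (or any sessile filter feeder) collected
from several wild populations are held under one shared environment;
their gill communities are profiled in the field (baseline) and
repeatedly during the garden phase. Taxa whose population signature
survives weeks of shared water are operationally **resident**; taxa
exchanged with the shared environmental pool are **transient**. The
package implements the statistical chain for that inference on a
samples × ASVs count table with per-sample `population`,
`source ∈ {field, common_garden}`, `timepoint` (days in the garden;
undefined for field samples) and `tank` labels.

## Filters

* **Sample depth**: samples with fewer than `min_reads = 1000` total
  reads are excluded (strict "less than": exactly 1,000 reads is kept).
* **ASV prevalence**: only ASVs present (count > 0) in *strictly more
  than* `min_prevalence = 1%` of samples are scored. The prevalence
  filter belongs to the flexibility stage by default — β-diversity
  distances are computed on all depth-filtered samples — because a
  presence-based pairwise score is the component that is unstable for
  near-singleton taxa. An option applies it before the distance stage
  too. Prevalence is always evaluated after depth filtering.
* Counts must be integers; relative abundances are rejected because every
  downstream statistic starts from presence = count > 0.

## β diversity and group tests

Pairwise dissimilarity is binary **Sorensen-Dice**,
`D = 1 − 2a/(2a+b+c)` (`a` shared, `b`/`c` unique presences). Two
non-empty samples sharing nothing get `D = 1`; a sample with zero reads
across ASVs has no defined distance and is an error rather than a 1.
An abundance-weighted variant (`1 − 2Σmin/Σ(x+y)`) is exposed but
non-default — the named index is the presence/absence one.

**PERMANOVA** (one factor). With `N` samples in `g` groups and
`d_ij` the distances,

    SS_total  = (1/N) Σ_{i<j} d_ij²
    SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²
    pseudo-F  = ((SS_total − SS_within)/(g−1)) / (SS_within/(N−g))

`p = (1 + #{F_perm ≥ F_obs}) / (1 + B)` over `B = 999` label
permutations (never zero; resolution 1/(B+1)). An exhaustive mode
enumerates all distinct labelings for small designs. Field and garden
strata are always tested separately; tank-level pseudo-replication in
the garden stratum is *not* modelled (no nested/multi-factor design),
which overstates effective sample size there — a deliberate scope limit.

**Dispersion homogeneity.** Principal-coordinates embedding of the
double-centred `−½d²` matrix; axes with negative eigenvalues are kept
separately and *subtract* from squared distances to group centroids
(floored at 0 before the square root), the standard treatment for
non-Euclidean dissimilarities. The statistic is the one-way ANOVA F of
the distances-to-centroid; p by label permutation with centroids and
distances recomputed per permutation. Centroids, not spatial medians.

**Rank-sum contrast.** Mann-Whitney U from midranks; exact p by
dynamic-programming enumeration of rank subsets when `n_a·n_b ≤ 400` and
the pooled values are tie-free, otherwise the normal approximation with
tie and continuity corrections (p floored at the smallest positive
double so it stays in (0, 1]).

**Divergence regression.** Each (garden sample, field sample) pair
within a population is one observation: OLS of dissimilarity on the
garden member's residence time in days, pooled and per population, with
the usual t-test on the slope. Pairs are not independent (each sample
enters many pairs); this mirrors the source design and is not corrected
— treat the per-pair p-values as descriptive.

## Flexibility scores

For one ASV, each unordered sample pair with the ASV present in at least
one member scores 1 (present in both) or 0 (present in one); pairs where
both lack the ASV are uninformative about it and are excluded. With
`K_p` = presence count in population `p` (size `n_p`, `S = ΣK_p`,
`N = Σn_p`):

    both-present within  = Σ_p C(K_p, 2)
    eligible within      = Σ_p [C(K_p,2) + K_p(n_p − K_p)]
    both-present between = (S² − ΣK_p²)/2
    eligible between     = both-present between + Σ_p K_p(N − n_p − (S − K_p))

`s_within` and `s_between` are the two ratios and
`FS = (s_within + ε)/(s_between + ε)` with smoothing `ε = 0` by default.
`FS > 1` ⇒ resident, `FS < 1` ⇒ transient, `FS = 1` ⇒ neutral.
`s_between = 0 < s_within` gives `FS = +∞` (kept for ranking, excluded
from the dip test, reported in the run log). ASVs with zero eligible
pairs in either class are flagged `undefined` and dropped from the FS
distribution. A `mode="dissimilarity"` option scores the literal
within/between *dissimilarity* ratio `(1−s_w)/(1−s_b)`; its orientation
is inverted (resident ⇔ score < 1) and the residency rule follows the
mode. The sharing form is the default because "restricted to a
population" must mean *high* within-population co-occurrence.

Tails: `ceil(fraction × n)` ASVs per side (at `n = 1375` and 1% this is
14 per tail, 28 over both); boundary ties break by higher prevalence,
then lexicographic ASV id (an invented, documented rule). Per-order
summaries report min/quartiles/max, n and the fraction of FS > 1, with
unlabelled ASVs pooled as `unclassified`.

## Dip statistic and bootstrap

The dip of an ECDF is the smallest sup-norm distance to any unimodal CDF
(convex, then concave). The implementation iteratively refines a modal
interval: fit the greatest convex minorant and least concave majorant of
the ECDF on the current interval (in count units, so ties are exact);
if their largest mutual gap exceeds the deviation already charged for
the flanks, shrink to the bracketing touch points, charge the flanks'
convex/concave fitting error, and repeat; the dip is half the final
charge. Equally spaced distinct points attain the minimum `1/(2n)`.
The test suite verifies exact agreement (≤ 1e-6, typically ~1e-12) with
an independent linear-programming oracle that fits a banded unimodal CDF
for every candidate mode. Two cautionary properties found this way:
the dip is location-scale invariant but **not** invariant under general
monotone transforms (CDF convexity is metric, not ordinal), and the
naive "best one-sided convex + concave fit per mode" decomposition
underestimates the dip (the two sides are coupled through the modal
value) — hence the modal-interval algorithm.

`dip_test` calibrates against uniform(0,1) samples of the observed size
(`B = 2000` bootstrap replicates by default; `p = (1 + #{dip_boot ≥
dip_obs})/(1 + B)`). The uniform null is the standard, slightly
conservative calibration for the dip.

## Synthetic data generator

Defaults mirror the motivating design: 6 populations × (5 field samples
+ 8 garden timepoints at days 1, 2, 7, 14, 21, 28, 35, 42 × 4 samples,
one per replicate tank) = 222 samples; 400 ASVs (120 resident, 80 core,
200 transient).

* **Residents** are present with probability 0.9 in their home
  population (field *and* garden — residency persists) and leak
  elsewhere at 0.02.
* **Core** taxa are present everywhere at 0.8.
* **Transients** carry a background presence of 0.05 everywhere plus one
  *pulse window* — two adjacent garden timepoints shared by every tank,
  since all tanks draw the same water — during which each garden sample
  picks the ASV up with probability `q_pop(t) = cap·(1 − e^(−λ_pop t))`
  (`cap = 0.9`, `λ = 1.0 /day` for every population by default).
  Synchronised pulses are what make transients *between-population
  enriched*: at one timepoint, two populations contribute `m²`
  between-population pairs but only `m(m−1)/2` within-population pairs,
  so `s_between > s_within` and FS falls below 1. Independent uniform
  scatter alone cannot produce FS < 1 in expectation (within- and
  between-population pairs then share the same co-occurrence structure),
  and *population-specific* uptake pushes FS of shared taxa above 1
  (a block of high-uptake populations behaves like a metapopulation
  resident) — which is why the default λ is uniform across populations.
  Window length, cap and λ were fixed once from this expected-value
  analysis.
* **Counts**: present taxa draw a negative-binomial count (dispersion
  0.5) around a per-ASV log-normal weight scaled to the sample's depth,
  with at least one read so presence and counts agree. Depths are
  log-normal around 20,000 reads; 1% of samples are drawn shallow
  (~400 reads) so the depth filter has something to remove.
* **Tanks** are recorded but generate no effect by default (a
  `tank_effect` option perturbs per-tank presence for sensitivity work).
* `generate_null_dataset` gives every ASV a single Beta(0.7, 2.5)
  presence probability shared by all samples — no structure of any kind —
  for type-I-error and null-FS studies.

What the generator does *not* emulate: phylogenetic correlation among
ASVs, taxon-taxon interactions, compositional coupling beyond the shared
depth, tank effects (by default), seasonal drift in the source water, or
sequence-level noise (simulation starts at the ASV table). Passing tests
therefore certify the statistical chain, not robustness to those
real-data features.

With fast-saturating default exchange (λ = 1/day) the garden transient
load plateaus within days, so the pooled divergence slope at the default
settings is small and its sign seed-dependent; the λ–slope relationship
is demonstrated with slower two-level rates (0.08 vs 0 per day), where
positive-λ populations show clearly positive slopes and zero-λ
populations do not.

## Numerical and design details

* Permutation p-values use the +1 convention throughout; every
  permutation test and bootstrap takes an explicit seed (no global
  state), and the pipeline derives per-stage seeds from one master seed
  via `SeedSequence`, making whole-run reports byte-identical for a
  given config + seed.
* PCoA eigenvalues within `max|λ|·1e-10` of zero are dropped; squared
  centroid distances are floored at 0 before the square root.
* `pseudo-F = +∞` is the sentinel when `SS_within = 0`; permutation
  comparisons use a `1e-12` slack so exact ties count as ≥.
* Pipeline stage order is fixed; each stage logs input/output sizes, any
  stage error aborts the run naming the stage and leaves a `FAILED`
  marker next to the partial outputs.
* Scaled problem sizes used by the test suite (a 3-population,
  33-sample design for unit tests; 200 replicates × 199 permutations for
  the PERMANOVA type-I check; 50 replicates × 199 bootstraps for the
  null-FS unimodality check) were chosen to exercise every code path at
  comfortable statistical resolution.

## Known limitations

* One-factor PERMANOVA only; tank nesting and multi-factor designs are
  out of scope, as are post-hoc pairwise PERMANOVAs and any
  multiple-testing correction (reports label p-values "uncorrected").
* Divergence regression inherits pair-level pseudo-replication (above).
* The dip's uniform-null bootstrap is conservative for heavy-tailed FS
  distributions; infinite FS values are excluded from (or optionally
  capped for) the dip rather than modelled.
* FS is presence-based by construction; abundance-weighted fidelity
  metrics are intentionally not implemented.
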