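# restrans

**Resident or transient?** Partitioning the members of a host-associated
microbiome by how tightly they track their host population.

When animals from several wild populations are reared together in a common
garden (same water, same food, same tanks), any microbiome differences that
*persist* point to host-governed, population-restricted **resident** taxa,
while taxa that wash in and out with the shared environment are
**transients**. `restrans` implements the full statistical chain for this
design on an ASV (amplicon sequence variant) count table plus sample
metadata (`population`, `source` = field / common_garden, `timepoint`,
`tank`):

1. **Filtering** — drop samples with fewer than 1,000 reads; drop ASVs
   present in no more than 1% of samples (a flexibility-stage filter).
2. **β diversity** — binary Sorensen-Dice dissimilarity,
   `D = 1 − 2a/(2a + b + c)`, with `a` = shared ASVs and `b`, `c` the ASVs
   unique to each sample.
3. **Group tests** — one-factor PERMANOVA (999 permutations) and a
   homogeneity-of-dispersions test per stratum, both implemented from the
   defining sums of squares; two-sample Wilcoxon rank-sum contrasts of
   within- versus between-population dissimilarities; OLS regression of
   garden-vs-field dissimilarity on days in the garden (community
   divergence over time).
4. **Flexibility scores** — for each ASV, the ratio of within- to
   between-population per-pair sharing, `FS = s_within / s_between`
   (pairs where the ASV is absent from both samples are uninformative and
   excluded). `FS > 1` ⇒ resident, `FS < 1` ⇒ transient, `FS = 1` ⇒
   population-blind. Bimodality of the FS distribution is assessed with an
   in-house Hartigan dip statistic and a uniform-null bootstrap; the top
   and bottom 1% FS tails and per-order summaries are extracted.
5. **Synthetic data** — a generator that emulates the study design
   (6 populations × 5 field samples + 8 garden timepoints × 4 samples)
   with planted resident / core / transient ASVs and known ground truth,
   so the whole chain is testable without any sequencing data.

The filters and the distance/scoring steps are scikit-learn style
transformers/estimators (`DepthFilter`, `PrevalenceFilter`, `SorensenDice`,
`FlexibilityScorer`) and compose with sklearn pipelines; the tests are
plain functions returning result dataclasses.

## Worked example

```python
import numpy as np
from restrans import (GeneratorConfig, generate_dataset, sorensen_dice_matrix,
                      permanova, flexibility_scores, dip_test, select_tails)

table, meta, taxonomy, truth = generate_dataset(GeneratorConfig(seed=42))

field = meta.index[meta["source"] == "field"]
dm = sorensen_dice_matrix(table.loc[field])
res = permanova(dm, meta.loc[field, "population"], n_permutations=999, seed=1)
print(f"field PERMANOVA: pseudo-F = {res.pseudo_F:.2f}, "
      f"R^2 = {res.R_squared:.3f}, p = {res.p_value:.3f}")

fs = flexibility_scores(table, meta, min_prevalence=0.01)
finite = fs["fs"][np.isfinite(fs["fs"])]
dip = dip_test(finite, n_bootstrap=2000, seed=2)
print(f"dip = {dip.dip_statistic:.4f}, bootstrap p = {dip.p_value:.2e}")
```

prints

```
field PERMANOVA: pseudo-F = 8.24, R^2 = 0.632, p = 0.001
dip = 0.0596, bootstrap p = 5.00e-04
```

The PERMANOVA says field communities differ strongly by population
(p at the permutation floor, 63% of the distance variance among
populations). The dip test rejects unimodality of the flexibility-score
distribution: the community splits into a resident mode (FS > 1) and a
transient mode (FS < 1). On this synthetic dataset the residency calls
recover 99.7% of the planted resident/transient labels, and
`select_tails(fs, fraction=0.01)` returns the most population-faithful
ASVs in the top-1% tail.

The same analyses are available from the shell:

```bash
restrans simulate --out-dir sim/ --seed 7
restrans run --table sim/asv_table.tsv --metadata sim/metadata.tsv \
             --taxonomy sim/taxonomy.tsv --out-dir out/ --seed 1
restrans diptest --values fs_values.txt --seed 1
```

`run` writes per-stage TSVs plus one consolidated `report.json`
(deterministic: identical config + seed ⇒ identical bytes). All reported
p-values are uncorrected.

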