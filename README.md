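# cytodelim

Integrative evidence chain for delimiting a diploid/tetraploid species pair —
the situation found in *Cyclocarya*, where a narrow, high-elevation diploid
(*C. serrata*) and a widespread autotetraploid (*C. paliurus*) were long
lumped under one name. The package re-implements, as tested and reusable
components, the three quantitative legs such a taxonomic split stands on:

1. **Climatic-niche comparison.** Occurrence records are deduplicated by
   great-circle distance (haversine, 1 km threshold), bioclimatic layers are
   sampled at the retained points, collinear predictors (|Pearson r| > 0.8)
   are pruned, and the z-scored matrix is projected onto its first two
   principal components. Species densities in this plane are estimated with a
   Gaussian kernel density on a shared 100 × 100 grid, from which the package
   computes

   - Schoener's overlap  D = 1 − ½ Σ |p₁ − p₂|  (0 = disjoint, 1 = identical),
   - standardized Levins' breadth  B = (1/Σp² − 1)/(n − 1)  (0 = one cell,
     1 = uniform),
   - the 50% isopleth (highest-density region holding half the mass), and
   - a label-permutation null distribution of D for a one-tailed lower test.

2. **Morphometrics.** Wilcoxon rank-sum tests (exact enumeration for small
   untied samples, tie-corrected normal approximation otherwise) for leaflet
   dimensions, Welch/Student t tests for flower diameters, leaflet-pair-count
   tabulation, and a determination-key classifier that assigns a specimen
   only on a unanimous vote of its provided characters.

3. **Mixed-ploidy population genomics.** A ploidy-aware neutral-SNP cascade —
   site depth within [mean/3, 2·mean]; removal of sites in coding sequence
   ± 2 kb flanks or transposable elements; removal of singleton
   polymorphisms counted over allele copies (a tetraploid 0/0/0/1 carries one
   copy); greedy 20-kb spacing — plus allele-copy Dxy between groups of
   arbitrary ploidy, a mixed-ploidy STRUCTURE export (diploids padded with
   two −9 rows), and 1-kb fragment sampling at 20-kb intervals from consensus
   alignments (> 50 N per sample or monomorphic fragments discarded) for
   coalescent species-tree input.

A synthetic-data module generates occurrences, correlated environmental
rasters, trait tables, and mixed-ploidy variant matrices with known ground
truth, so the whole chain is testable without any downloads.

## Worked example

```python
import numpy as np
from cytodelim import (
    NicheSimConfig, gen_occurrences, thin, extract_at_points,
    prune_correlated, zscore, pca_fit, permutation_test,
)

occ, layers, truth = gen_occurrences(NicheSimConfig(seed=1))
thinned, report = thin(occ, threshold_km=1.0)
env = zscore(prune_correlated(extract_at_points(layers, thinned), 0.8))
pca = pca_fit(env, n_components=2)
res = permutation_test(pca.scores.to_numpy(), pca.species.to_numpy(),
                       grid_size=100, replicates=1000, seed=1)
print(f"kept {len(thinned)}/{len(occ)} records after 1-km thinning")
print(f"PC1 {pca.explained_variance_ratio[0]:.1%}, "
      f"PC2 {pca.explained_variance_ratio[1]:.1%}")
print(f"Schoener's D = {res.schoeners_d:.3f}, p = {res.p_value:.4g}")
for sp, b in res.levins_b.items():
    print(f"Levins' B ({sp}) = {b:.3f}")
```

Output:

```
kept 305/360 records after 1-km thinning
PC1 61.2%, PC2 17.2%
Schoener's D = 0.026, p = 0.000999
Levins' B (C. paliurus) = 0.160
Levins' B (C. serrata) = 0.047
```

The thinning step removed the ~15% of records planted within 1 km of an
existing conspecific point; the two simulated species overlap very little in
climate space (D near 0, with the permutation p at its minimum 1/1001), and
the widespread species' niche breadth is several times the narrow one's —
the qualitative pattern the method is designed to resolve.

The same stages are available from the shell:

```bash
cytodelim simulate --out-dir data --seed 1
cytodelim thin --input data/occurrences.csv --threshold-km 1.0 \
    --output thinned.csv --report thin.json
cytodelim vcf-filter --vcf data/variants.vcf --cds data/cds.bed \
    --te data/te.bed --out-dir filtered
cytodelim morph --leaflets 12 --stamens 19 --diameter 3.5
```

## Documentation

`docs/methods.md` describes the statistical model behind each stage, the
defaults and their units, what the synthetic generators do and do not
emulate, and known limitations.
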