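# Methods

This note documents the statistical procedures implemented in `cytodelim`,
the defaults they ship with, and the design choices made where the underlying
analysis admits more than one reasonable reading.

## Occurrence thinning

Occurrence records are deduplicated by great-circle distance computed with
the haversine formula on a sphere of radius 6371.0 km (configurable; the
formula itself is radius-agnostic). The scan is greedy and first-wins in
input order: a record is dropped if it lies closer than the threshold
(default 1 km, matching the ~1 km footprint of 30 arc-second climate cells)
to an already-kept record. First-wins makes the operation deterministic,
order-stable, and idempotent.

Thinning is **per-species by default**: the analysis compares
species-specific niches, and letting a record of one species suppress a
record of the other would bias the species' sample sizes against each other.
A `per_species=False` switch performs global thinning for workflows that
want one record per site regardless of taxon.

## Environmental extraction, pruning, standardization

Raster values are taken from the **containing cell** (no interpolation) —
the standard choice for 30 arc-second bioclimatic sampling, and bit-exactly
reproducible. Records falling outside any layer's extent, or hitting a
nodata cell, are dropped and itemized in the report rather than imputed.
Layers are read and written as ESRI ASCII grids, a plain-text single-band
raster format; the in-memory `EnvLayer` uses the usual north-up row
convention.

Collinear predictors are pruned against a threshold on **absolute** Pearson
r (default 0.8): a strong negative correlation is exactly as redundant as a
positive one. The threshold alone does not determine which member of a
violating pair goes, so the rule is: iteratively drop the variable with the
largest mean |r| over the pairs still violating the threshold, ties broken
toward the later column. A `keep_list` pins variables that must survive
(e.g. to reproduce a published retained set — note that published accounts
sometimes leave the retained list ambiguous, such as announcing nine
retained predictors while listing eight named ones; an explicit keep list
sidesteps the ambiguity). Constant columns carry no information and are
dropped first with a warning. The pruning decision is invariant to affine
rescaling of the inputs, so raw and standardized matrices give the same
retained set; the greedy rule is validated in the tests against an
exhaustive-subset oracle.

Standardization is a z-score per column with denominator n − 1, computed on
the **pooled two-species matrix**: the ordination is fit on one combined
niche space, so each species must be expressed in the same units of pooled
variation.

## PCA niche space

PCA is fit on the standardized matrix (equivalent to correlation-matrix PCA
on the raw predictors), retaining two components. Eigenvector sign is
mathematically arbitrary; each loading vector is flipped so its
largest-magnitude element is positive, making scores reproducible across
runs and linear-algebra backends. Degeneracy is judged on input columns:
fewer than two non-constant variables cannot span a plane (perfectly
collinear but varying columns can — the projection is then rank-deficient
but well-defined).

## Kernel density, overlap, breadth, permutation inference

Species densities in the PC1/PC2 plane are estimated with a **Gaussian
product kernel** (diagonal bandwidth matrix), evaluated at the centers of a
shared regular grid (default 100 × 100) and renormalized to sum to one —
the niche becomes a discrete probability mass function over cells, which is
the object Schoener's D and Levins' B are defined on. Bandwidths follow
Scott's rule per axis (h_j = sd_j · n^(−1/6) in two dimensions; Silverman's
rule coincides with Scott's at d = 2) computed on **each group's own
points**; a fixed numeric bandwidth is accepted where a sensitivity analysis
wants one.

The grid is **shared between species** — D is undefined across different
grids — and spans the pooled score range padded by three pooled bandwidths
so kernel tails are captured; total truncation error is well below the
1e−9 mass-normalization tolerance enforced by `DensityGrid`.

- Schoener's D = 1 − ½ Σ|p₁ − p₂| over the full grid. Whether a published D
  was computed over the full grid or within an isopleth is often unstated;
  the full grid is the default here, and `schoeners_d(..., restrict_mask=)`
  exposes the isopleth-restricted variant (each distribution renormalized
  within the mask).
- Levins' B uses the standardized form (1/Σp² − 1)/(n − 1), which maps to
  [0, 1] regardless of grid size; the unstandardized 1/Σp² would scale with
  the number of cells and is not comparable across grids.
- The 50% isopleth is a highest-density region: cells are accumulated in
  decreasing density order until half the mass is covered, with ties at the
  cut density all included.
- The permutation test exchanges **species labels** over the pooled scores,
  preserving group sizes (so per-group bandwidths behave comparably), and
  recomputes both KDEs and D on the same grid per replicate (default 1000).
  The p-value is one-tailed lower with the add-one correction,
  p = (1 + #{D_null ≤ D_obs}) / (1 + replicates): the scientific question is
  whether the species overlap *less* than arbitrary labelling would produce.
  Under identical niches the test is slightly conservative (measured type-I
  error ≈ 0.04 at nominal 0.05 over 600 simulated datasets).

Densities are occurrence densities only; no background-environment
(availability-corrected) conditioning enters D. Display conventions that
contour "50% of the background environments" are a plotting matter and do
not change the statistic.

## Morphometrics

The Wilcoxon rank-sum test reports the rank sum W of the first sample with
midranks for ties. With a combined n ≤ 12 and no ties the p-value is exact
(full enumeration of rank assignments); otherwise a normal approximation
with tie and continuity corrections is used. The two regimes agree to well
under 0.01 by n = 30 + 30. Tests are two-sided by default — published
significance statements rarely pin a tail — and no multiple-testing
correction is applied across leaflet position classes, matching how such
comparisons are conventionally presented; callers needing familywise control
should apply it downstream. The t test defaults to Welch (no equal-variance
assumption), with Student's pooled variant selectable. Degenerate inputs
(all values identical; zero variance in both samples with equal means)
return p = 1 with a warning rather than NaN.

The determination-key classifier treats the printed character ranges as
inclusive. Ranges genuinely overlap: 9 leaflets, a 4.0 mm flower, and
flowering in May each match both species, so such a character is simply
indecisive rather than evidence. A specimen is assigned only when every
decisive character names the same species and no character falls outside
both ranges; anything else returns "ambiguous" with a per-character vote
report. The key's "rarely 11" / "rarely 15" extensions are not encoded: the
core ranges are the discriminating claim, and stretching them would blur the
boundary the key exists to draw.

## Neutral-SNP filter cascade

Stage order is **depth → region → singleton → spacing**, mirroring the
narrative order of the underlying protocol; spacing runs last because any
earlier removal could only widen gaps, and thinning first would discard
sites whose neighbours were about to be removed anyway.

- **Depth.** Sites are kept when depth lies in [mean/3, 2·mean], both bounds
  inclusive. "Depth" defaults to the site-level total over samples, with the
  mean taken across input sites (`site_total`); a `per_sample` mode applies
  the same window to each sample's own depth against that sample's mean and
  requires all samples to pass. Which of the two a published pipeline used
  is often unstated — both are configuration here, not assumptions.
- **Region.** A site is removed iff its 0-based position lies in the union
  of TE intervals and CDS intervals expanded by the flank (default 2 kb) on
  both sides. BED half-open convention throughout; GFF3 features are
  converted on read; overlapping intervals are merged so nothing is
  double-counted. Flanks apply to CDS only — the TE annotation's boundaries
  are taken as given.
- **Singleton.** Allele copies are counted over all non-missing genotype
  slots (a tetraploid 0/0/0/1 contributes one alternate copy) and the site
  is removed when the **minor** allele count is exactly 1 — symmetric, so a
  site where the reference survives in a single copy is equally a singleton.
  Monomorphic sites are not singletons and pass this stage.
- **Spacing.** Greedy left-to-right per chromosome: keep the first site,
  then each site ≥ 20 kb (default) from the last kept one. Unsorted input is
  sorted with a warning.

## Ploidy-aware Dxy

Per site, Dxy is the fraction of differing alleles over all inter-group
pairs of non-missing allele copies — every copy of every individual enters
the pairing, which generalizes naturally to mixed and arbitrary ploidy. Site
values are averaged over **all sites supplied**: monomorphic sites
contribute zero, so the caller controls the denominator (and hence the
scale) by the site set passed in. A site where one group has no called
copies contributes zero; a group with no called copies at any site is an
error.

## STRUCTURE export

Every individual occupies four rows. Tetraploids write their four allele
copies; diploids write two genotype rows followed by two rows of −9 across
all loci, so diploids and tetraploids are format-compatible in one
tetraploid-shaped matrix. Missing genotypes are −9; alleles are coded 0/1
consistently within each locus column.

## Fragment sampling

Per-sample consensus sequences aligned to shared reference coordinates are
cut into fragments of 1000 bp starting at 0, 20 kb, 40 kb, … per chromosome
(reference-anchored; 0-based half-open). A fragment is discarded when any
sample's sub-sequence contains more than 50 N bases, or when no column is
variable — with columns containing an N in any sample excluded from the
polymorphism check, since ambiguity must not fake variation. Survivors are
written as one FASTA alignment per fragment for gene-tree inference.

## Synthetic data: what it does and does not emulate

**Occurrences/rasters.** Layers are linear mixes of smooth low-frequency
random fields, orthonormalized over grid cells and recombined through the
Cholesky factor of a target correlation matrix — realized inter-layer
correlations over cells equal the target exactly, and spatial
autocorrelation comes free from the smooth basis. The default scenario
includes one near-duplicate layer pair (r = 0.97, the kind of redundancy
same-season temperature summaries produce) so pruning is exercised.
Occurrences invert the environment-to-space mapping: a target environmental
vector drawn from the species' Gaussian is matched to the grid cell with the
nearest environmental profile (KD-tree), and the point is placed uniformly
in that cell. Empirical covariance converges to the configured one as n
grows (verified at n = 2000 within 10% on a fine grid); cell-snapping adds a
small discretization error that shrinks with cell size and effective
environmental dimension. A configured fraction of records (default 15%) is
re-placed within 0.05–0.9 km of an existing conspecific point, emulating
repeated collection at one site. Defaults give two species with distinct
optima, the widespread one about twice the breadth of the narrow one, and
240/120 records — herbarium-scale numbers. Not emulated: sampling bias along
roads, georeferencing error, raster nodata seas, non-Gaussian niches.

**Traits.** One row per measured leaflet (position-class sample sizes
38/104/37 and 47/92/46, mirroring the measured specimen series), with
species-specific length/width normals (redrawn on the rare nonpositive
draw), leaflet-pair counts sampled from the observed spectra, and flower
diameters per row. Not emulated: within-tree correlation (rows are
independent), measurement error structure, allometry.

**Variants.** Mixed panel (default 6 diploids + 10 tetraploids), 5000 sites
on three 2-Mb chromosomes, negative-binomial per-sample depths (k = 5)
modulated by a shared lognormal per-site factor (σ = 0.6) emulating
mappability/copy-number variation — the very reason a depth window exists;
without it, summing many independent sample depths concentrates site totals
so tightly the window never fires. A configured fraction of sites (default
10%) is generated as true singletons; the rest have minor allele count ≥ 2
among called copies. CDS and TE tracks are non-overlapping interval walks at
15% density each. The generator records per-stage survivor counts by direct
arithmetic on its own arrays — deliberately re-derived with plain loops,
independent of the filter implementations — and the cascade must match them
exactly. Not emulated: linkage disequilibrium, allele-frequency spectra
under drift/selection, genotyping error correlated with depth, indels.

## Validation problem sizes

The test suite and acceptance script run at desk scale, chosen to make every
check independent and fast: KDE-vs-analytic overlap at n = 2000 per species
against 500 × 500 numeric integration of the true densities (agreement
within 0.05); permutation type-I error over 50 datasets × 200 replicates;
the filter cascade at 5000 sites; Dxy by explicit enumeration of copy pairs
on toy matrices; fragment arithmetic on 100-kb chromosomes. Independent
oracles (dense integration, brute-force loops, exhaustive subset search)
never share code with the implementation they check.

## Known limitations

- Niche comparison is occurrence-based; it does not correct for
  environmental availability, so D conflates range overlap with niche
  overlap when backgrounds differ strongly.
- KDE-grid D is mildly upward-biased at small n (kernel smoothing inflates
  overlap); the bias is within 0.05 at n = 2000 under the tested scenarios
  but grows as samples shrink.
- The exact Wilcoxon path is limited to untied samples with combined n ≤ 12;
  beyond that the corrected normal approximation is used.
- `region_exclude` holds merged interval unions in memory per chromosome —
  fine for annotation-scale inputs, not engineered for hundreds of millions
  of intervals.
- The fragment sampler assumes consensus sequences are already aligned to
  reference coordinates; it performs no alignment itself.
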