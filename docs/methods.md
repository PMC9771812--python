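# Methods

This note documents the models implemented in `tmeco`, the defaults that
matter, the numerical choices made where the design was genuinely open, and
what the synthetic generators do and do not emulate.

## Data model

Cells are rows of a pandas DataFrame (`cell_id`, `sample_id`, `patient_id`,
`site`, `sort_fraction`, `cluster`, plus QC metrics). Per-sample cluster
counts live in a `ClusterCountTable` (samples × clusters contingency with
per-sample metadata). Allele counts are an AnnData (cells × SNPs) with sparse
`ref`/`alt` layers and an `arm` column in `.var`. mpIF cells are rows with
µm coordinates, per-marker mean intensities and an FOV id; interface
geometry is a shapely polygon per FOV whose interior is the tumour region.
Genomic tables (segments, variants, breakpoints) are plain DataFrames;
blacklists are BED (0-based half-open) and are converted to 1-based
inclusive semantics internally — the conversion is covered by tests.

## Cell QC and cluster exclusion

Cells are retained when they have at least 500 expressed genes and 1,000
UMIs, under 25% mitochondrial expression (strict `<`) and a doublet score of
at most 0.25. The comparisons implement "minimum of" as `>=` and "greater
than" (for doublet removal) as keep-`<=`.

Patient-private clusters are excluded by relative entropy: the empirical
Shannon entropy of a cluster's patient composition divided by `ln` of the
cohort's patient count, flagged below 0.8. The denominator deliberately uses
the cohort size, not the number of patients observed in the cluster, so a
cluster confined to few patients scores low. Natural log is used throughout;
the ratio is base-invariant. `0·log 0` terms contribute zero.

## Composition GLM

Counts are modelled as `N_c ~ Binomial(p_c, N)` per (sample, cluster) row
with a logit link over treatment-coded cluster, covariate and cluster ×
covariate interaction terms. Reference levels default to the alphabetically
first level and are recorded in the design; models can exclude sites (e.g.
ascites) before encoding. The fit is an ordinary maximum-likelihood binomial
GLM (statsmodels, proportion response with the sample total as variance
weight). A formulation with Gaussian noise on the logit scale is emulated in
the generator; on the inference side an optional quasi-binomial scale
(`scale="X2"`) serves as the practical surrogate for that observation-level
noise — point estimates are identical, Wald tests widen. Exact
logistic-normal fitting is out of scope.

The enrichment table reports, per (cluster, covariate level), the cluster's
log odds ratio between the level and its reference: the covariate main
effect plus the cluster interaction, i.e. the change in `logit p_c`
attributable to the level. This is the quantity the enrichment dot plots
colour, and it is the estimand the generator plants: under a softmax
generator, an effect `β` added to one cluster's logit changes exactly that
cluster's one-vs-rest odds by `e^β`. The raw interaction coefficient alone
would instead measure a difference-in-differences against the reference
cluster and is biased for the planted effect when compositions are coupled.
Three-way (cluster × site × signature) rows report the raw modulation
coefficient, as no site × signature base term exists in the model.
Bonferroni correction uses as family the number of rows actually reported.

Separation is flagged when a coefficient exceeds 15 in absolute value or its
standard error is not finite; such coefficients are excluded from the report
rather than penalized (a small ridge is available via `ModelSpec.ridge` for
robustness, trading away the Wald covariance). Samples are treated as
independent replicates — patients contributing several samples are not
down-weighted, which the model formulation implies; mixed-effects patient
intercepts are deliberately out of scope.

## Diversity, dissimilarity, patient specificity

Shannon entropy uses natural log. Bray–Curtis follows the min-sum form and
equals `Σ|x−y| / Σ(x+y)` for non-negative counts (cross-checked against
scipy in tests). Rarefaction subsamples each retained sample to exactly 400
cells without replacement (multivariate hypergeometric draw from its cluster
counts) and averages the pairwise matrix over 100 iterations; samples below
the floor are dropped with a warning rather than resampled with replacement.
At these settings the iteration mean is stable to < 0.01 entrywise, and two
multinomial draws from the same 5-cluster uniform composition sit near
D ≈ 0.055 — the rarefaction noise floor that "identical composition" reaches
at n = 400.

Patient specificity operates on a k-nearest-neighbour graph (default
k = 20, Euclidean, self excluded, exact ties broken by row order) as the
neighbour-set reading of a shared-nearest-neighbour graph; the SNN edge
weighting itself is not modelled, and scores (not their sign structure)
depend on k. The score is `log₂((obs + δ)/(exp + δ))` with pseudocount
δ = 1/k preventing `log 0` for cells with no same-patient neighbours; the
expected fraction is the patient's global share of cells.

KDE enrichment evaluates Gaussian kernel densities (Scott's rule by
default) for two cell groups on a 200 × 200 grid over the embedding bounding
box padded by 5%, normalizes each to unit mass on the grid and subtracts, so
the signed field integrates to zero.

## Arm-level allelic imbalance

The B allele is designated per SNP as the pseudobulk minor allele over all
cells (a subset can be supplied for sensitivity analysis); an exact 0.5 tie
resolves to `alt`, matching the convention that the reference allele is the
default major allele. Per cell and arm, BAF is the pooled ratio
`Σ b_count / Σ total_count` over the arm's SNPs — read-weighted, not the
mean of per-SNP fractions (the per-SNP mean is noisier at scRNA-seq depth;
the pooled ratio is the read-weighted mean and is what the thresholds are
calibrated against). Cells with fewer than 10 reads on the arm are kept as
`missing` so denominators stay explicit. States: balanced BAF ≥ 0.35,
imbalanced 0.15 ≤ BAF < 0.35, LOH < 0.15; sample clonality from the LOH
fraction among informative cancer cells: ≤ 20% heterozygous, (20, 80]
subclonal, > 80% clonal.

At the simulation default of ~90 reads per arm per cell (30 SNPs × Poisson
mean 3), per-cell state accuracy against generator truth exceeds 99%; at the
10-read floor, single-cell calls degrade but sample-level LOH percentages
remain within a few points for clonal fixtures.

## Spatial topology

Marker positivity is `intensity >= threshold` (thresholds are per-slide
inputs; the manual thresholding step is not modelled). Objects positive for
several lineage markers (panCK, CD68, CD8) are duplicated once per lineage
at identical coordinates; within a lineage the most specific matching
phenotype definition wins and lineage-positive cells matching no definition
keep the bare lineage label. Duplicated records enter all denominators.

Signed interface distance is the Euclidean distance to the tumour polygon's
boundary, positive inside the tumour. Density profiles bin signed distance
into half-open 10 µm bands `[10k, 10(k+1))` tiling the observed range, pool
across FOVs and normalize by the phenotype's total count (densities sum
to 1). The banded standard error is `√(p(1−p)/N)` with, by default, `p` the
phenotype's share of all cells in the band and `N` the band's total cell
count — the reading under which the formula is a binomial proportion SE; a
`phenotype_total` mode uses the plotted density with the phenotype total
instead. Nearest-neighbour distances and proximity counts (default radius
30 µm) are FOV-local, exact (KD-tree, no approximation), exclude self when
source and target phenotypes coincide, and leave sources in target-free FOVs
as missing with a logged count. A 250 µm cut-off sometimes used when drawing
interaction edges is visualization-only and is not applied in statistics.

## Co-expression networks

Expressing fractions are the share of cells with count > 0. A
(patient, sender, receiver) pair is flagged when any ligand exceeds the 10%
fraction in the sender cluster and the receptor exceeds it in the receiver
cluster — both strict inequalities. A patient enters a pair's denominator
only when both clusters are observed for that patient with at least 10 cells
(configurable), so absent clusters are not counted as non-co-expressing; a
`denominator="group"` mode uses all patients of the group instead. Edges
require support in at least 50% of denominator patients.

## Genomic rules

The signature classifier is a plain kNN majority vote in Euclidean space
over signature-probability vectors: k = 30 neighbours, assignment only when
the modal label holds ≥ 25 votes, else Undetermined; distance ties break by
reference order, and a modal tie (possible only when m ≤ k/2) resolves
alphabetically. Reference labels are inputs — strata discovery and signature
inference are out of scope.

Focal WGS amplifications require membership in the top 2% of the
genome-wide copy-number distribution of bins (computed over bins; gene-level
mapping is left to the caller) and `log₂(cn/ploidy) > 1`. WGS homozygous
deletions require length ≥ 10 kb (1-based inclusive) and mean copy number
strictly below 0.5. Panel events first restrict to segments < 10 Mb with
≤ 10 genes to suppress arm-level events, then call cn > 8 amplifications and
cn = 0 deletions.

The SNV filter keeps variants called by both callers with probability
≥ 0.9, outside blacklist intervals and not in the known-variant set. The
breakpoint filter keeps calls made by both callers with break distance
> 30 bp, excludes deletions < 1 kb, requires ≥ 5 tumour-supporting reads and
zero normal reads, removes blacklisted loci, and finally drops calls
combining a small break distance with few reads — quantified here as
distance < 100 bp with < 10 tumour reads, exposed as parameters because the
original rule states no numbers.

## Synthetic generators

All generators are pure functions of (spec, seed) with a single explicit
RNG stream; fixed seeds reproduce outputs bitwise.

- **Composition**: per-sample logits `baseline + site + signature (+ 3-way)
  (+ Normal(0, σ²))`, softmax, multinomial counts. A multinomial softmax is
  used rather than independent per-cluster binomials so counts sum to the
  sample total; per-cluster binomial margins match the logit model, and a
  single-cluster effect shifts exactly that cluster's one-vs-rest odds.
  Defaults follow the recovery conditions exercised in the tests: 60 samples
  × 2,000 cells for effect recovery, 20 samples × 500 cells for the null
  calibration (200 replicates keep the run in seconds while pinning the
  rejection rate to a few tenths of a percent).
- **Allele counts**: per-(cell, SNP) totals Poisson(3) across 30 SNPs per
  arm (~90 reads per arm), B reads binomial with q = 0.5 (balanced),
  0.25 (imbalanced, configurable in [0.15, 0.35)) or ε = 0.01 (LOH, the
  allele error rate); clonal structure via per-clone arm states and clone
  fractions.
- **Spatial**: inhomogeneous point processes thinned from a uniform
  proposal, with per-phenotype intensity a function of signed interface
  distance only; marker intensities can be attached consistently with the
  phenotype labels for gating tests.
- **Expression**: per (patient, cluster, gene) expressing fractions set
  exactly in expectation, nonzero counts ≥ 1.
- **Signatures**: Gaussian clouds around stratum centroids clipped and
  renormalized onto the simplex.
- **Genomic fixtures**: deterministic tables with exactly one record per
  filter decision boundary.

The generators emulate only the statistical structure the downstream stages
consume. They do not model transcriptome covariance, ambient RNA, doublets,
segmentation artefacts, SNP phasing or mappability structure, and spatial
intensities depend on nothing but interface distance. Passing tests
therefore demonstrate correctness of the implemented statistics under their
stated sampling models — not robustness to the full messiness of real
tissue data.

## Numerical choices and degenerate inputs

Entropy of an all-zero vector, Bray–Curtis with a zero total, single-patient
cohorts, k ≥ n neighbour queries, degenerate (zero-length) interface
geometry, zero informative cells and malformed intervals all raise errors;
empty QC inputs and empty pair groups warn and return empty. Half-open band
and BED conventions, tie-breaks (B allele to `alt`, kNN by row order) and
separation sentinels are fixed and tested. Problem sizes in the test-suite
and acceptance script (e.g. 500-cell FOVs × 20, 500-cell allele matrices,
200 GLM replicates) were chosen as the smallest sizes at which Monte-Carlo
error is comfortably below the asserted tolerances.

## Known limitations

- No patient random effects in the GLM; repeated samples per patient are
  treated as independent.
- The quasi-binomial scale approximates, but does not fit, logit-normal
  observation noise.
- Patient-specificity scores depend on k, which the neighbour-graph source
  does not pin down; k is exposed and defaults to 20.
- Gene-level mapping of WGS focal amplification percentiles (bins vs genes)
  is computed over bins; a gene-level aggregation is not built in.
- VCF/BEDPE serialization is not provided; filters operate on DataFrames
  with documented columns.
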