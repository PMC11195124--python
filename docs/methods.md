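# Methods

`visig` implements a complete analysis pipeline for deriving, scoring,
validating, and stress-testing a transcriptomic signature of vascular
invasion (VI) in stage I lung adenocarcinoma. Because no patient-level data
ship with the package, a first-class synthetic-data module generates every
input with planted ground truth; the pipeline itself is agnostic to where
its counts come from.

## Models and procedures

### Normalization and harmonization (`visig.preprocess`)

Library-size normalization is trimmed-mean-of-M-values (TMM): the reference
column is the sample whose 75th-percentile count fraction is closest to the
cohort mean; for each sample, genes expressed in both it and the reference
contribute M (log2 ratio of depth-normalized counts) and A (average log
abundance); 30% of each M tail and 5% of each A tail are trimmed, the
surviving M values are averaged with delta-method precision weights, and the
factors are rescaled to geometric mean one. Expression is carried as log2
CPM with a library-size-proportional pseudo-count (default 2). Both match
the reference implementation in the established count-normalization package
to printed precision (verified during development; the shipped tests pin a
brute-force oracle instead).

Cross-cohort harmonization is a reference-batch location/scale adjustment on
the logCPM scale: non-reference batches are standardized against the
reference batch's per-gene mean and SD and mapped onto it, with optional
parametric empirical-Bayes pooling of the per-gene batch effects (normal
prior on locations, inverse-gamma on scales, moment-matched, iterated).
The reference batch is returned bit-identical. The same code path serves
both the within-discovery site correction and external-cohort validation —
one harmonization mechanism rather than two.

Gene filtering keeps genes with CPM > 1 in at least `ceil(0.10 * n)`
samples. Sample QC removes samples whose quality score deviates from the
cohort mean by more than 2 SD, computed in a single pass. (A four-sample
cohort with one gross outlier cannot trip this rule — the outlier inflates
the SD it is compared against — which is why the tests exercise it at
n = 10.)

### Differential expression (`visig.diffexpr`)

Counts are modeled as negative binomial with Var = mu + phi mu^2, log-linear
in a design containing the three-level grade factor (low-malignant-potential
reference) and optionally a lymphatic-invasion indicator, with the log
effective library size as offset. Per-gene dispersions maximize the
Cox–Reid adjusted profile likelihood on a log-spaced grid (parabolically
refined) at means fitted under the Poisson limit, then shrink on the log
scale toward the all-gene common maximizer with fixed weight 0.25 on the
gene-wise value. The VI-vs-reference contrast is tested per gene by
refitting the model constrained to the contrast's null space and referring
the deviance difference to chi-square (1 df), with Benjamini–Hochberg
adjustment; non-converged genes get NA and leave the FDR denominator.

All fits are IRLS batched across genes (einsum-assembled per-gene normal
equations), so a 2000-gene x 100-sample pass takes about a second — which is
what makes re-deriving the signature inside every cross-validation fold
practical. Under a null simulation the observed type-I rate at p < 0.05 is
0.054 and a phi = 0.4 truth is recovered with median 0.40 at n = 50.

### Signature clustering and scoring (`visig.signature`)

Significant genes (FDR < 0.01) are clustered by Ward-criterion hierarchical
clustering on Euclidean distances of per-gene z-scored logCPM, cut at k = 4,
with cluster indices reordered by descending mean log fold-change so the
down-regulated cluster is always cluster 4. Bulk samples are scored by the
mean per-gene z-score against frozen training-cohort statistics; spots are
scored with the binned-control module score (24 abundance bins, 100 control
genes per set gene, seeded sampling, score = mean set expression minus mean
control expression). Gene z-scoring before clustering follows the
heatmap-scaling convention of the source analysis.

### Enrichment (`visig.enrichment`)

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hits
weighted by |score|^1, misses by 1/(N−Nh)); significance comes from seeded
gene-label permutations, one-sided toward the observed ES sign and
normalized within the same-sign permutations with a +1 pseudo-count (this
normalization is what makes null p-values uniform; normalizing by all
permutations compresses them below ~0.5). The ranking metric for
association-driven rankings is −log10(p) · sign(logFC) with lexicographic
tie-breaks. Over-representation is the one-sided Fisher exact test against
a supplied universe; hosted enrichment databases are out of scope, so all
gene sets arrive as GMT.

### Spatial statistics (`visig.spatial`)

Spots with fewer than 250 detected genes are removed; expression is
depth-normalized to 10,000 counts and log1p-transformed. The spatially
weighted correlation assigns each spot a kernel-weighted Pearson coefficient
(bisquare default, bandwidth 5 spot-pitches, i.e. 500 µm at 100 µm pitch)
over its sample's spots, after a global rank transform when the Spearman
analogue is requested; per-sample means are averaged with equal sample
weights. The bandwidth is interpreted in spot-pitch units because the
source protocol's "bandwidth five" is unitless.

Region association fits a Gaussian linear mixed model (value ~ annotation,
random intercept per sample, REML) after dropping annotations with fewer
spots than the downsampling target and downsampling the rest (200 by
default; the shipped small-section analysis uses 100 and says so), with
Wald contrasts against normal lung and Bonferroni adjustment. The
"generalized binomial" wording in the source's methods is internally
inconsistent with its figure legends ("linear mixed model"); the Gaussian
model is implemented. The high-grade contrast restricts to
solid/cribriform/micropapillary spots and LR-tests the tumor VI-status term
(ML fits) with pattern as a fixed covariate.

Distance binning labels a spot proximal when its Euclidean distance to the
nearest invaded-focus spot center is <= 1 mm (annotated spots are at
distance 0), and distal otherwise; a section with no focus in the capture
area is entirely proximal. Spot centers, not polygon boundaries, are the
only geometry in the data model.

### Predictor (`visig.predictor`)

The panel has exactly 48 genes, apportioned to the four clusters in
proportion to each cluster's share of the significant genes by the
largest-remainder method, capped at cluster availability with shortfall
redistributed the same way; within a cluster genes enter by ascending
p-value (ties: |logFC| descending, then ID). The model is a binomial-logit
GLM with an L2 penalty on the standardized gene coefficients (intercept
unpenalized), fit by Newton/IRLS; the penalty is chosen from 30 log-spaced
points in [1e-3, 1e3] to maximize mean AUROC over stratified 5-fold inner
CV.

Nested cross-validation repeats, for each of 100 stratified 70/30 outer
splits: gene filtering, TMM, DE, clustering, panel selection, inner penalty
search, and final fit — on the outer-training samples only. Test-cohort
logCPM is computed within the test cohort (per-sample quantities; no label
information crosses the split), and the model applies its frozen training
standardization. A dedicated test verifies byte-identical model
serialization when held-out labels are corrupted with the split fixed.

AUROC is the normalized Mann–Whitney U with half-credit ties; its 95% CI is
a 2000-replicate percentile bootstrap of (score, label) pairs, and the
accompanying p-value is the two-sided rank-sum test (null AUROC = 0.5).
Feature importance ranks genes by |standardized coefficient|; per-cluster
concentration toward the top is tested by a two-sided two-sample KS test of
the cluster's ranks against the remaining panel's ranks, which handles total
ties exactly (all-equal coefficients give D = 0, p = 1 — a one-sample
uniformity test cannot satisfy that contract).

Predicted probabilities are the reported score. Because the AUROC-driven
penalty search is indifferent to calibration, a near-separable training set
can yield an almost unpenalized fit whose probabilities saturate at 0/1; the
survival and heterogeneity analyses therefore use the standardized linear
predictor (`scale="link"`), which is monotone-identical but unsaturated —
this is the package's reading of "score per standardized unit".

### Heterogeneity (`visig.ith`)

Each tumor is downsampled to one random pair of regions (tumors with fewer
than two regions are excluded); inter-tumor pairs are drawn, one per tumor,
from two distinct tumors. Intra vs inter absolute score differences are
compared two-sided by Wilcoxon rank-sum; the paired-region correlation is
Spearman with randomized A/B assignment. Gene-level stability ranks every
filtered gene by its Spearman correlation across tumors between paired
regions and feeds the ranking to preranked GSEA with the 48-gene panel as
the query set.

### Survival (`visig.survival`)

Cox proportional hazards (Efron ties) and Kaplan–Meier with the standard
log-rank test are delegated to lifelines; the tests pin the contracts
against a brute-force partial-likelihood maximization and hand-computed
lifetables rather than the library. Predictor-score hazard ratios are
reported per SD of score; follow-up horizons are applied as administrative
censoring.

## The synthetic-data generator (`visig.simulate`)

The generator emulates exactly the structure the analysis assumes, and no
more:

- **Bulk cohorts.** 2000 genes, log-normal relative abundances (sigma 1.2),
  log-normal library sizes (median 5e5), gene-wise NB dispersions
  log-normal around 0.15. Four planted modules of 115/37/182/140 genes
  (the sizes the source analysis reports; rescaled proportionally only if
  they would not fit the gene count). Grades are drawn LMP/NST/VI at
  0.22/0.54/0.24; VI samples express the full per-module log2 effect
  (+1/+1/+1/−1), NST 40% of it, LMP none. Each module's per-sample
  activity is the grade effect plus N(0, 0.5) — without this
  module-specific component the three up-modules would be statistically
  exchangeable and no clustering could separate them; with it the planted
  partition is recoverable (ARI ~1). A two-site batch effect (per-gene
  N(0, 0.15) log2 shifts) exercises harmonization. Gene-level parameters
  live on their own seeded stream so a validation cohort can measure the
  same genes on new patients, optionally with a cohort-wide per-gene shift
  (sigma 0.3) for the reference-batch adjustment to remove.
- **Spot grids.** A square lattice (100 µm pitch — hexagonal geometry adds
  nothing to the statistics being tested), painted with labeled rectangles
  and discs (later paint wins, logged); each region has a fixed per-cluster
  activity profile, strongest cluster-1/3 elevation and cluster-4
  suppression in the invaded focus. VI-positive sections add a
  section-wide background shift (+0.5/+0.3/+0.5/−0.5 log2) on top of the
  regional profiles — the tumor-level angioinvasive phenotype that makes
  the signature detectable distal to the focus; purely regional painting
  cannot produce that contrast because per-spot depth normalization
  renormalizes composition within each region. Spot depths are log-normal
  (median 8000).
- **Multi-region tumors.** A per-tumor latent score ~ U(0,1); each region
  expresses the planted modules at tumor latent + N(0, 0.1). No
  module-specific noise here — the region perturbation is the single latent
  the heterogeneity analysis is about.
- **Survival.** Exponential event times with hazard 0.01 · exp(beta ·
  score); censoring times U(0, tau) with tau solved by bisection on the
  realized event times so the expected censored fraction matches the
  requested rate. The acceptance study plants beta = 2.0 per unit latent
  (latent SD ≈ 0.36, so a per-SD hazard ratio near 2 — an association of
  the same kind as the reported prognostic effect); the parameter-recovery
  tests use beta = 0.7 on continuous N(0,1) scores.

What the generator does **not** emulate: realistic transcriptome-wide
covariance beyond the planted modules, cell-type mixtures, spatial
autocorrelation within regions, hexagonal spot geometry, or histology
images. Passing tests therefore demonstrate that the pipeline recovers the
structure it assumes when that structure is present — calibration,
correctness of the numerics, and absence of leakage — not that the
signature generalizes to real tumors.

## Numerical choices

- IRLS: deviance-relative tolerance 1e-11, max 100 iterations, step-halving
  on deviance increases, linear predictors clipped at ±50; non-convergence
  flags the gene rather than crashing.
- Dispersion floor 1e-8; grid 1e-6…10^1.5 in 45 points.
- Ward clustering delegates the linkage to scipy; an exhaustive
  Lance–Williams merge oracle pins the merge sequence in the tests.
- Ridge IRLS: Newton steps to |step| < 1e-10; penalty grid as above.
- Seeds: every randomized stage derives `crc32(stage) XOR global_seed mod
  2^31`, so stages are reproducible in isolation and independent of one
  another.
- Degenerate inputs: constant mixed-model responses short-circuit to a null
  result; zero-SD reference genes are dropped from z-scores with a warning;
  all-censored survival data raise.

## Problem sizes

The shipped analysis runs at desk scale: 2000 genes, 103 discovery / 60
validation samples, two 576-spot sections, 63 two-region tumors, and the
full 100-iteration outer CV (about 80 s end to end in
`scripts/acceptance.py`). These sizes are the package's own choice of a
small but structurally faithful study; every stage accepts larger inputs
unchanged.

## Known limitations

- Dispersion estimation profiles the APL at Poisson-fit means rather than
  re-fitting means per candidate dispersion; the approximation is excellent
  at these design sizes but is not the exact edgeR scheme, and the
  moderation is a fixed-weight shrink, not an abundance trend.
- The permutation GSEA is gene-label permutation only; phenotype
  permutation would require sample-level expression at the enrichment
  stage.
- The mixed models inherit statsmodels' boundary warnings when the random
  intercept variance is near zero; estimates remain valid for the contrasts
  tested.
- `filter_samples_quality` applies the 2-SD rule in one pass; masked
  outliers in very small cohorts are by design not re-screened.
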