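# Methods

`stromatlas` re-implements, as a tested library, the computational analysis
of a colonic mesenchyme single-cell RNA-seq atlas spanning two platforms
(droplet/10x UMI counts and deep Fluidigm C1 read counts), two species, and
health vs. inflammation. This note documents the models, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that a maintainer would otherwise have
to reverse-engineer.

## Barcode calling and QC

Cell-containing droplets are separated from ambient gel beads in two steps:
a hard floor of 250 UMIs, then a Gaussian kernel density (Silverman
bandwidth, 512-point grid) over log10 totals of the surviving barcodes; the
threshold is the **first interior local minimum** scanning from low to high
totals, never below the floor. A unimodal density falls back to the floor
with a warning. The grid/neighbor-comparison definition of "local minimum"
makes the rule deterministic and unit-testable. Cells with **> 5%**
mitochondrial UMIs (strict inequality; a cell at exactly 5% is retained)
are then removed. Spiked-in control cells carrying a lentiviral
selection-marker transgene are removed **cluster-wise**: an initial SNN
clustering is computed and any cluster in which more than half of cells
detect the transgene feature is dropped entirely. A stray control cell that
never co-clusters with the control population is, by construction, not
removable by this rule. C1 libraries are screened by robust outlier rules
(below median − 3·MAD on log totals or genes detected; caps on ERCC and
mitochondrial read fractions), since only the metric panel, not the
cutoffs, is fixed by the protocol.

## Normalization

Per-cell scaling factors use a pooling/deconvolution estimator: cells are
ranked by total count on a ring; overlapping pools of sizes
{21, 26, 31, 36, 41} are summed and compared with the average-profile
reference pseudo-cell via the **median** ratio over expressed genes (robust
to a minority of differentially expressed genes); the per-cell factors
solve the resulting sparse linear system by least squares, with a
heavily-weighted anchor row fixing the mean factor at 1. Fewer cells than
the smallest pool, or non-positive solutions, fall back to library-size
factors with a warning. Expression is `log2(count/factor + 1)`.

Technical **control genes** are those whose total variance falls below a
loess trend (span 0.3) of variance against mean; variance strictly below
the fitted value is required. Their leading singular vector(s) over cells
estimate unwanted variation, which is regressed out of every gene
(residual plus gene mean); the number of unwanted factors defaults to 1.
RUV residuals may dip below zero; the NMF stage clips them at zero because
factorization needs a non-negative basis.

Droplet-track variable genes follow the fixed window
`0.0125 < mean of non-zero values < 4` and `SD > 0.5` (log scale, SD over
all cells), after removing genes detected in fewer than 3 cells. The C1
track instead uses "biologically variable" genes: the complement of the
control-gene set (variance above the trend), which is what a mean–variance
decomposition of deep read-count libraries supports.

Covariate regression (total UMIs, batch, cycle scores) is per-gene ordinary
least squares with an intercept, one-hot categorical encoding, and
collinear-column dropping; output is residual + gene mean, so the operation
is idempotent.

## Co-expression network and NMF consensus (C1 track)

The gene network is **signed hybrid**: `a_ij = max(cor, 0)^4`. Edge
confidence pruning removes pairs co-detected above a *normalized-count*
threshold (default 6, midpoint of the stated 5–8 range) in fewer than 3
cells; the log-scale expression is de-logged before thresholding. Genes are
clustered by average linkage on `1 − a` and modules cut by a "tree"-variant
dynamic cut: the dendrogram is cut at a fixed fraction of its merge-height
**range** (deep-split 0–4 maps to 0.64/0.73/0.82/0.91/0.95; default 3 →
0.91). Quantiles of the raw height distribution were rejected because
background merges pile up within 1e-3 of the maximum dissimilarity and
swallow the cut point. A branch qualifies as a module if it holds at least
`min_module_size` (default 30) genes and its mean internal dissimilarity
stays below the cut; members loosely attached to a branch (mean
dissimilarity above the midpoint between the branch core median and the cut
height) are returned to the unassigned pool, as in adaptive branch pruning.

Cells are clustered by 50 randomly initialized NMF runs (KL-divergence
multiplicative updates, max 300 iterations, tolerance 1e-5) per candidate
rank; each run assigns cells to their arg-max basis component and the
consensus matrix records co-assignment frequencies. Per rank we report the
cophenetic correlation of the consensus dendrogram, the average silhouette
width on `1 − consensus`, the dispersion `mean 4(c − ½)²` over off-diagonal
entries (so an uninformative all-½ consensus scores 0), and the best-run
Frobenius RSS. The chosen rank is the smallest that is simultaneously a
local maximum of the first three metrics; "local maximum" carries a noise
tolerance of `max(1e-3, 5% of the metric's range over the survey)` because
cophenetic correlation saturates near 1 and its informative differences
shrink with it. Ties break toward the RSS inflection (maximal absolute
second difference). The same survey on per-gene-permuted data is the
negative control; its cophenetic correlation sits far below the observed
one when real structure exists. Final labels cut the consensus dendrogram
at the chosen rank, consistent with how the cophenetic metric is computed.

## Graph clustering, jackstraw, t-SNE (droplet track)

PCA is computed on centered, unit-scaled genes with a deterministic sign
convention (largest-magnitude loading positive). Jackstraw significance
permutes a small fraction (default 1%) of genes per repetition, recomputes
the decomposition, and pools the permuted genes' squared loadings as the
null; because every gene contributes to the observed components, observed
loadings are slightly overfit relative to held-out permuted genes, so the
observed statistics are rescaled by the ratio of null to observed medians
(the bulk of genes is null) before per-gene p-values are taken. A PC is
significant when the fraction of gene p-values below α=0.05 exceeds α by a
one-sided binomial test, and the largest significant prefix PC1..PCk is
used downstream.

The SNN graph links **any** pair of cells sharing nearest neighbors
(k = 20, self included), weighted by Jaccard overlap and pruned below 1/15;
restricting edges to direct k-NN pairs makes modularity optimization shred
homogeneous clusters, while the shared-neighbor closure renders tight
clusters near-complete. Communities come from modularity optimization
(configuration-model null, resolution 0.8, seeded), labels renumbered by
decreasing size. t-SNE runs 10 random initializations and keeps the lowest
final KL divergence; all KL values are logged.

## Markers and differential expression

Marker AUC is the rank-sum statistic with midranks (ties count ½); each
gene's target cluster is the one with the highest mean, and the top 200
genes per cluster are candidates. Filtered testing requires detection in
≥ 25% of cells inside or outside the cluster and |log fold change| ≥ 0.25,
where log fold changes are natural-log ratios of de-logged means. In AUC
mode, reported genes need discriminative power |AUC − ½| ≥ 0.2 (the
reporting threshold 0.3 interpreted as the distance-from-chance rule of the
ROC test it configures). The NB GLM uses a log link with log size-factor
offset, group plus latent covariates (total UMIs, cycle scores, batch;
numeric covariates standardized), per-gene dispersion by method of moments
followed by one Newton refinement of the NB likelihood in the size
parameter, and a Wald test on the group coefficient with BH adjustment.
All-zero genes are skipped; non-converged fits report p = NaN. Gene-set
enrichment is the upper-tail hypergeometric test over a user-supplied GMT
against the expressed-gene background; marker-set overlap between two
clusterings uses one-sided Fisher tests (enrichment screen).

## Cross-species random-forest transfer

The ortholog map keeps only one-to-one rows whose *minimum* directional
sequence identity reaches 75% (conservative reading of "identity between
pairs"), then removes any residual multi-mapping so the output is a
bijection. Class balancing down-samples majority clusters to the median
class size and up-samples minorities by SMOTE (new point = x + λ(x_nn − x),
λ ~ U(0,1), among k = 5 same-class Euclidean neighbors). Feature selection
is recursive elimination by impurity importance with stratified 10-fold CV;
the selected size is the smallest within one SD of the best CV accuracy.
Forests use 1000 trees and mtry = ⌊√p⌋ with OOB error reported. Evaluation:
row-normalized confusion matrices, one-vs-rest AUC from vote fractions,
per-feature per-cluster specificity (one-vs-rest AUC, 0.5 = nonspecific)
and its per-cluster Pearson correlation across species. Balancing and RFE
run before cross-validation, matching the stated ordering of the original
workflow; the selection is therefore not leakage-free with respect to the
training species, which is acceptable because evaluation happens in the
other species.

## Diffusion maps, pseudotime, cell cycle

The diffusion map uses a Gaussian kernel on the symmetrized k-NN graph
(k = 500, clamped to n−1) with per-cell bandwidth set to the distance to
the ⌈k/100⌉-th (at least 5th) nearest neighbor, density normalization with
α = 1, and a row-normalized transition operator solved through its
symmetric conjugate. Trivial eigenvectors (λ numerically 1, one per
connected component) are dropped. Pseudotime is the Euclidean distance from
the root in components scaled by λ/(1−λ); the root is exactly 0. k-NN
boundary tie-breaking can perturb the coordinates of exactly duplicated
cells at the ~1e-3 level; this is inherent to truncated-neighborhood
kernels.

Cell-cycle phase is read from marker gene pairs: a pair (g_hi, g_lo)
belongs to a phase when its strict ordering holds in ≥ 70% of that phase's
reference cells and ≤ 30% of others (training searches the 150 most
variable genes; the search is quadratic in genes). Scores are the fraction
of a phase's pairs strictly satisfied, ties excluded from the denominator;
the original method's permutation normalization is omitted — the
fraction-of-pairs score with the half-majority phase rule (G1 if
g1 ≥ ½ > g2m; G2M if g2m ≥ ½ > g1; else S) is deterministic and directly
testable.

## Batch diagnostics, pseudo-bulk comparison, trees

Entropy of batch mixing: per bootstrap (100 of them), 100 cell locations
are sampled and the normalized Shannon entropy −Σ p ln p / ln B of batch
proportions within each location's 100 nearest embedding neighbors is
averaged. Fixed-size neighborhoods were chosen for determinism; ln B
normalization makes controls comparable across batch counts. The negative
control shuffles batch labels; the positive control uses cluster labels as
batches. Pseudo-bulk profiles are per-gene means over normalized log
expression (the comparison target is normalized array intensities, not raw
counts). Quantile normalization maps each column rank-wise onto the
reference column's sorted values with midrank averaging for ties, hence is
idempotent. The empirical-Bayes batch adjustment standardizes per gene,
shrinks per-batch location (normal prior) and scale (inverse-gamma prior)
by an iterative parametric solve, and back-transforms; it reproduces the
reference ComBat implementation to ~1e-3 on planted shifts (the two differ
only in stopping rules). Cluster trees are hierarchical (complete linkage,
Euclidean) over cluster average cells, exported as Newick with
parent-minus-child branch lengths; per-node confidence is the OOB error of
a forest classifying member cells into left vs right branch.

## Synthetic data: what it emulates, what it does not

Counts are gamma-Poisson (NB) with variance μ + φμ², φ = 0.3 by default,
matching droplet overdispersion. The droplet generator plants: cluster
structure with disjoint marker sets (log2FC 2 by default) drawn from
mid-abundance genes (30th–90th percentile of the base profile — a fold
change on a near-zero or saturating base would be undetectable or
implausible, and marker genes are in practice moderately expressed); a
bimodal barcode-total mixture (cell mode 5,000 UMIs, ambient mode 100,
lognormal depth spread 0.25/0.30); 13 mitochondrial genes (`MT-` prefix)
with per-cell Beta-distributed mitochondrial fractions (mean 2%,
concentration 80); gene-wise multiplicative batch factors (log2 SD 0.1 over
2 batches); and a transgene-bearing control cluster at 5% of cells with the
transgene at ~1% of its transcriptome. Ambient barcodes draw Poisson counts
from the library-mean profile, so they are transcriptionally uninformative.
The C1-scale configuration used in validation raises depth to 1e5
counts/cell — C1 libraries are sequenced orders of magnitude deeper than
droplet libraries, and the 5–8 normalized-count confidence threshold
presupposes such depth.

The two-species generator shares conserved clusters' markers through
one-to-one ortholog pairs; a divergent cluster carries species-private
markers plus *discordant* ortholog-gene signatures, and in the query
species additionally a half-strength copy of one conserved cluster's
markers ("mimic"). This is what makes the divergent class genuinely
confusable across species: absence of all conserved markers would itself
be a perfectly conserved signature. Trajectories move a fraction of genes
along sigmoid/linear programs of a latent time in [0,1] with an optional
branch at t = 0.5; cell-cycle simulations plant phase-specific gene pairs
with ~30:1 expected ratios (so orderings hold in ≥90%/≤10% of cells) and
one proliferative cluster with G2M probability 0.6 vs 0.2 elsewhere.

Not emulated: doublets, read-level structure (FASTQ), ambient RNA
contamination *within* cells, per-gene dispersion trends, spatial or
lineage-coupled batch confounding, and dropout beyond what NB sampling
implies. Passing tests therefore demonstrate correctness of the algorithms
under the stated statistical assumptions, not robustness to every artifact
of real tissue data.

## Validation battery and problem sizes

The benchmark suite (`stromatlas.benchmarks`, reported by
`scripts/acceptance.py`) runs: barcode calling on 10 replicates of the
1,000-cell/4,000-ambient mixture; C1 rank recovery on 10 replicates of a
4-cluster, 300-cell, 2,000-gene simulation (50-run consensus over ranks
2–7, permuted-data control evaluated at the planted rank); module detection
on 4 planted blocks of 60 genes (within-module r = 0.8) plus 200 background
genes; a 100-instance exact AUC oracle; NB GLM calibration on 2,000 null
genes and 300 planted-effect genes at 200 cells/group; cross-species
transfer on 4 clusters × 120 cells/species with 500 orthologs (one
divergent, mimicking class); ortholog-map filtering against the planted
bijection; diffusion pseudotime on a 500-cell linear trajectory; gene-pair
phase calling on 360 cells; entropy diagnostics on a 500-cell mixed
embedding; and quantile normalization plus batch adjustment on a planted
3-unit shift. These sizes keep the full battery within minutes on one CPU
while leaving each check's signal-to-noise far from the threshold being
asserted.

## Known limitations

* The dynamic tree cut is the "tree" (top-down) variant; the hybrid
  PAM-stage variant is out of scope, so module boundaries in borderline
  cases can differ from the full algorithm.
* The NB GLM uses per-gene free dispersion with a single Newton
  refinement; no information is shared across genes.
* SMOTE and RFE run once on the full training species (see above).
* `rank_select` assumes the surveyed rank range brackets the true rank;
  with no simultaneous local maximum it returns the smallest rank with a
  warning rather than guessing.
* The C1 per-library QC applies generic robust-outlier defaults; real
  studies tune these against bulk and empty-well controls.
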