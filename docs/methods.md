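# Methods

This note documents the statistical model behind `treevote`, the choices
made where the procedure admits more than one reasonable reading, and
what the synthetic-data tests do and do not demonstrate about real data.

## The selection model

The input is a genes × samples expression matrix with binary sample
labels (tumor/normal) in which the tumor class heavily outnumbers the
normal class. Selection proceeds through three screens.

**Preprocessing.** Three rules, applied in order: (1) a gene is dropped
when its zero-fraction strictly exceeds 50% of samples — exactly half is
kept; (2) each surviving gene is min–max rescaled to [0, 1]; (3) every
remaining zero is replaced by an independent uniform draw from the open
interval (0, min/10), with min the gene's smallest non-zero value in the
current matrix. Because step (3) runs after step (2), every gene's
minimum entry is a zero at that point, so after the full pipeline all
values lie in (0, 1] and no gene is constant. Two readings of the
zero-replacement rule are defensible (raw scale vs normalized scale);
the listed order is the default and `replace_zeros_first=True` provides
the other. Constant genes, which min–max cannot rescale and which carry
no class information, are dropped with a logged warning. Missing entries
in input files are coerced to zero and counted.

**Relevance: Fisher ratio.** Per gene, `FR = (μ₁−μ₂)²/(σ₁²+σ₂²)` with
class means and unbiased (n−1) variances; the estimator is switchable to
the population form via `ddof`. Genes with FR < 0.5 are deleted; a score
exactly at the threshold is kept ("below" is strict). Degenerate genes
(both class variances zero) rank at +∞ when the means differ and at 0
otherwise. FR is invariant to per-gene affine maps, so it is unaffected
by the min–max step.

**Redundancy: Spearman + classified information index.** Spearman rank
correlation (mid-rank Pearson, all samples pooled) is computed among the
genes that survive the relevance screen. Pairs with |ρ| > 0.7 are
redundant; within a pair the gene with the lower classified information
index `d = ½|μ₁−μ₂|/(σ₁+σ₂) + ½ln((σ₁²+σ₂²)/(2σ₁σ₂))` is deleted. The
second term is a log variance-disparity penalty that keeps equal-mean,
unequal-variance genes distinguishable — the property that motivates
using d rather than FR to arbitrate. The deletion order is greedy by
decreasing |ρ| (strongest redundancy resolved first), with CII ties
broken against the lexicographically later gene ID; afterwards no
surviving pair exceeds the threshold. This ordering is a determinism
choice — the pairwise rule itself does not prescribe one.

**Ensemble selection.** Each of `n_trees` (500 reference, 100 at desk
scale) balanced subsets takes every minority sample plus an equal-size
bootstrap (with replacement) draw of the majority. Per subset, a
stratified `CV`-fold loop (5 reference) trains a fold tree, records its
validation accuracy `ACC_ik`, overwrites gene j's validation values with
the gene's training-fold mean ("mean perturbation"), and records the
perturbed accuracy `ACCF_ijk`; the per-tree importance is
`FI_ij = Σ_k (ACC_ik − ACCF_ijk)/CV`, which may be negative. A full tree
trained on each subset votes on every sample; the ensemble label is the
majority vote with ties going to the tumor (majority) class, and the
tree weight is `w_i = agreement_i × Acc_Ensemble ∈ [0, 1]`. The combined
score is `FI_j = Σ_i FI_ij·w_i`, and genes with `FI_j` strictly positive
(beyond a 1e−12 tolerance) are the selected DEGs, annotated up- or
down-regulated in tumor by the sign of the tumor-minus-normal mean.

Resolved ambiguities, each switchable: the perturbation operator is
training-fold-mean replacement (`perturbation="permute"` gives the
permutation variant); accuracies are measured on the validation part
(`acc_on="train"` gives the training-side variant, but note unlimited-
depth trees memorize their training folds, making every baseline 1.0 and
every drop non-negative); tree weights are computed over all samples;
negative combined importances are excluded from the DEG list and logged;
trees use Gini impurity at unlimited depth; the balanced subsets use
bootstrap under-sampling by default with a `sampling="hybrid"` mode that
reuses the SMOTE + k-means sampler instead.

An exact shortcut keeps the perturbation loop cheap: a gene that no node
of a fold tree consults cannot change that tree's predictions when
perturbed, so its fold contribution is identically zero and only the
features present in the fitted fold tree are perturbed.

**Null behaviour of FI_j.** `FI_j` is a weighted *sum* over trees, so on
label-uninformative data the per-tree noise (sd ≈ 0.1 for a used gene)
accumulates rather than averages out: feeding thousands of pure-noise
genes directly to the ensemble yields a handful of genes with |FI_j| >
0.05 by chance. The pipeline never does this — the Fisher-ratio screen
precedes the ensemble, and under a global null it retains nothing (the
selection raises an explicit empty-retention error), so the pipeline
selects zero genes. The specificity claim verified by the tests is
therefore a property of the filter + ensemble combination, not of the
ensemble in isolation.

## Panel validation

Stratified 80/20 train/test split. From the training split,
`n_datasets` (9) balanced datasets of `size` (100) samples are built:
size/2 synthetic minority vectors from SMOTE (each `x + λ(x_nn − x)`
with λ ~ U(0,1) and x_nn one of the k = 5 nearest minority neighbours,
clipped to n−1 when the minority is tiny) and size/2 majority
representatives from k-means with k = size/2, taking the nearest real
sample to each centroid (medoids keep features in the observed value
space; duplicates fall through to the next-nearest unused sample). Per
dataset a Gaussian naive-Bayes member (constant features dropped,
logged) and an RBF-kernel SVM member are fitted; all members vote with
flat pooling, a sample's score is its tumor-vote fraction, the hard
label is tumor at score ≥ 0.5. ROC curves use all unique thresholds and
the AUC is the tie-corrected Mann–Whitney rank statistic. Synthetic
vectors never enter any evaluation split.

The permutation null for the AUC fixes the fitted classifier's scores
and permutes the evaluation labels — the standard permutation test for
ROC significance. Two tempting alternatives are statistically
uninformative here and are not used: a held-out-only null is bound by
small-sample variance (with 8 minority test samples the null AUC sd is
≈ 0.11, so no implementation can concentrate it in [0.4, 0.6]), and
retraining on permuted labels then scoring against true labels inherits
the panel's dominant separation axis and is wildly dispersed.

## Downstream analyses

Tumor samples are clustered on the DEG panel by Ward-linkage
agglomerative clustering (deterministic, no tuning) behind a pluggable
`backend(X, k, seed) → labels` contract; the within-cluster dispersion
is reported for every k in 2..8 without endorsing one, and labels are
renumbered 1..k by decreasing size. Representative genes per subtype
come from one-vs-rest two-sided Welch t-tests over all genes (not only
the panel), top 100 by ascending p, overlaps allowed; degenerate genes
get p = 1. PCA is centered, scores on the first two components plus the
full explained-variance spectrum for scree inspection. Survival uses
the Kaplan–Meier product-limit estimator and the k-group log-rank test
(lifelines), requiring at least two groups and one event.
Expression–methylation association is per-gene Spearman over
inner-joined samples, flagged at ρ < −0.3. Mutation enrichment builds a
2×2 table per gene per subtype (groupwise one-vs-rest, or all pairs in
pairwise mode), tests with two-sided Fisher's exact, adjusts within
mode by Benjamini–Hochberg, and reports both raw p and q; never-mutated
genes get p = 1 without a test.

## The synthetic-data generator

The generator emulates the target data regime, not any particular
cohort. Defaults: 2000 genes; 371 tumor vs 50 normal samples; 20
informative genes with a class-mean shift of 2 within-class SD on the
log scale (≈ 80% upregulated in tumor); 50 redundant genes, each a noisy
copy of an informative parent calibrated through the bivariate-normal
identity ρ_s = (6/π)·asin(r/2) so the expected Spearman correlation hits
0.8; three latent subtypes at proportions 0.54/0.21/0.25 with ±1
signature patterns over the informative genes at 1.5 SD, centred so the
planted tumor-vs-normal mean difference is exact; exponential survival
with per-subtype hazard ratios (1, 1, 3) around a 5-year baseline
median and independent uniform censoring calibrated to a 30% rate;
Bernoulli mutations at 5% background vs 50% in each enriched gene's
target subtype; and beta-valued methylation anti-correlated with
expression for 80% of the informative genes. Expression is log-normal
(non-negative, right-skewed); 5% dropout zeros are confined to noise
genes so planted effects stay exact, and 2% of genes are mostly silent
to exercise the unexpressed-gene filter. Every generator is a pure
function of (spec, seed).

What the generator does **not** model: read-count noise, library-size
and batch effects, gene–gene correlation beyond the planted redundancy,
microarray/RNA-seq platform differences, or methylation array
chemistry. Passing tests therefore demonstrate that the implementation
recovers what it is designed to recover under its own assumptions — not
that those assumptions describe any real cohort.

## Problem sizes and numerical choices

The verification suite runs the full selection at 2000 genes, 300 vs 40
samples, 100 trees and 5 folds (20 seeds for recovery and for the null),
a size the package's exact unused-feature shortcut makes comfortable on
one CPU; the reference setting of 500 trees changes runtime, not
structure. Formula implementations (Fisher ratio, CII, fold-mean
importance, tree weight, weighted combination, Spearman, Fisher's exact
p, log-rank statistic) are checked against independent brute-force
oracles to 1e−10 or better. Seeds fan out from one master seed by
SHA-256 hashing of stage names, so stages are decoupled and every run is
bit-reproducible; reruns with the same configuration produce
byte-identical output tables.

## Known limitations

FI_j depends on tree count and fold count through its summation
structure, so importance magnitudes are comparable only within one
configuration. The greedy redundancy filter can delete a weakly
redundant gene that a different resolution order would keep. Ward
clustering replaces the original spike-and-slab Bayesian clustering the
subtyping contract was written around; any clustering satisfying the
backend contract can be plugged in. The uniform-censoring calibration
targets the *average* hazard, so per-subtype censoring rates deviate
slightly when hazard ratios are extreme.
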