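# Methods

## The selection problem

Two-class expression data (tumour vs normal, or two tumour subtypes) has
N samples and G genes with G ≫ N. Univariate screens rank genes by marginal
class separation and therefore cannot find genes that discriminate only
*jointly* — e.g. a pair whose product, but neither member, carries the class
signal. The Binary Matrix Shuffling Filter (BMSF) implemented here is a
wrapper-style selector that scores many random gene *combinations* and asks,
for each gene, whether its inclusion helps conditionally on the inclusion
states of all other genes.

## The filtering engine

One round over the current gene set (size G_cur):

1. **Inclusion scheme.** Draw a K × G_cur binary matrix X; each column is an
   independent permutation of K/2 ones and K/2 zeros, so every gene is
   included in exactly half the rows. Rows define candidate gene subsets of
   average size G_cur/2.
2. **Row scoring.** For each row, 5-fold stratified cross-validation of an
   RBF-SVM on that row's genes; the pooled predictions over all N samples
   give one Matthews correlation coefficient (MCC) per row, the vector Ø₀.
   MCC = (TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)), defined as 0
   whenever a marginal sum vanishes.
3. **Surrogate.** Fit one support-vector regression m₀: inclusion row → MCC.
4. **Per-gene paired comparison.** For gene i, complement column i of X and
   predict the flipped rows with m₀ (vector Ø₁). Pair the scores so that
   Z₀ collects, for every row, the score with gene i excluded (observed
   where x_ki = 0, predicted where x_ki = 1) and Zᵢ the score with it
   included. Gene i is eliminated iff mean(Z₀) > mean(Zᵢ), strictly;
   decisions for all genes are taken against the same X and m₀ and applied
   together at round end.

The round costs exactly K cross-validated classifier trainings plus one SVR
training; predictions are reused K·G_cur times. Rounds use K = 500, 450,
400, 350, then 300 (the floor). The 15-round schedule therefore trains
5001 classification models (ΣK + the initial full-set evaluation) and 15
regression models — 5016 in total; `count_trainings` reproduces this
accounting and an instrumented counter verifies it at run time.

**Stopping.** Before round 1 and after every round the survivor set's
cross-validated MCC (μ) is checkpointed. A strict drop stops filtering and
returns the pre-round (better-scoring) set. A *tied* checkpoint continues
from the reduced set: pooled MCC on a few dozen samples is quantised in
steps of ~2/N, ties are common, and equal performance with fewer genes is
progress, which is the stated rationale for stopping in the first place.
Guard stops: a round that eliminates nothing, survivors at or below a floor
(default 2), and a round cap (default 30).

The checkpoint is averaged over 5 seeded fold partitions (configurable).
A single-partition checkpoint has noise ≈ 0.05 on these sample sizes, which
makes the continue/stop comparison a coin flip as soon as μ plateaus;
averaging only stabilises the decision and does not enter the
training-budget accounting, which counts row CVs, the initial evaluation
and SVR fits.

## Numerical choices that matter

- **Kernel width of the untuned filtering SVM.** Inside filtering the SVM is
  deliberately untuned (one CV training per row). With the libsvm default
  γ = 1/p the RBF kernel is nearly linear at p ≈ 100 features, and a purely
  interacting pair is *invisible*: its measured joint inclusion effect on
  row MCC is ≈ 0, so both members are eliminated at chance. With
  γ = 4/p the same pair shows a clear positive joint effect (≈ +0.03 MCC on
  the synthetic conditions below) while marginal-gene effects and
  noise-gene neutrality are unchanged. The default is therefore
  `kernel_width_factor = 4` (γ = 4/|subset|, C = 1); any fixed gamma can be
  supplied instead.
- **Surrogate kernel.** The surrogate's inputs are binary inclusion
  indicators, and the flip comparison interrogates main effects and
  pairwise inclusion interactions; a degree-2 polynomial kernel spans
  exactly that space and is the default (C = 1, ε = 0.01). An ε as large as
  0.1 would swallow most of the row-MCC spread (sd ≈ 0.15) inside the
  insensitive tube. RBF and other SVR settings are configurable.
- **Common fold partition.** All subset scorings in one run — scheme rows,
  checkpoints, and every subset visited by the refinement stage — share the
  fold partition drawn from the master seed. Score differences between
  subsets are then paired comparisons: they reflect the genes, not fold
  reshuffling, and identical subsets always score identically, so greedy
  decisions cannot flap. Runs are bit-reproducible given (data, seed).
- **Ties.** Backward elimination removes the candidate with the first
  (lowest-index) maximal leave-one-out score; elimination continues on
  exact score ties (the stop test requires the best leave-one-out score to
  be *strictly* below the full-set score).
- **Degenerate inputs.** The empty gene subset scores MCC 0 (it is the
  empty model, which occurs legitimately as the all-zeros row of the
  significance design); zero-variance genes get p = 1 in the t-test
  prescreen and are excluded from correlation diagnostics, with warnings.

## Refinement of the surviving genes

- **Fine evaluation** (10-fold CV): repeatedly score the candidate set and
  all leave-one-gene-out subsets; stop when every removal is strictly
  worse, otherwise remove the gene whose removal scores best. Never returns
  an empty set.
- **Importance ordering**: repeatedly remove the most dispensable gene
  (exclusion maximises CV MCC), prepending it to the order; the last
  survivor is the most important gene.
- **Significance**: over the final k₀ genes build a design of inclusion
  patterns — all 2^k₀ patterns when k₀ ≤ 9, otherwise a K-row balanced
  scheme plus an all-ones row and the k₀×k₀ identity (one univariate row
  per gene). Score every row by CV MCC, fit the surrogate, flip each
  column, and report a two-sided paired t-test p-value comparing the
  included vs excluded score vectors. No multiplicity correction is
  applied (the raw paired-t p-values are the interface).

## The synthetic generator

`bmsf.synthetic.generate` emulates the feature landscape the selector is
designed for, with all randomness under one seed:

- **noise genes**: i.i.d. Normal(0, σ²), σ = 1 by default;
- **marginal genes** (default 2): class means separated by
  `marginal_effect` σ (default 1.0);
- **pure-interaction pairs** (default 1): each member is a symmetric
  bimodal mixture scaled to unit variance (modes ±0.97 σ, mode width
  0.26 σ), so a member is marginally indistinguishable from a noise gene —
  same mean in both classes by exact within-class sign balancing, same
  variance — while the *sign product* of the pair equals the class label
  flipped with probability 0.1. The member signs are balanced exactly
  within each class in every realization, not merely in expectation;
  without this, sampling noise at N = 60 gives one member accidental
  marginal signal in a non-trivial fraction of datasets and the planted
  structure is no longer purely interacting.
- **redundant blocks** (default 0): equicorrelated genes (correlation ρ)
  sharing one latent, optionally class-shifted, signal.

Default study conditions are 30 samples per class and 200 genes. What the
generator does *not* emulate: array/batch effects, intensity-dependent
variance, heavy-tailed noise, realistic gene-gene correlation beyond the
explicit blocks. Passing recovery tests therefore demonstrate the
algorithm's behaviour under clean planted signal, not performance on real
microarray data.

## Evaluation harnesses

`loocv_accuracy` implements leave-one-out accuracy with an inner stratified
5-fold grid search per left-out sample for the SVM (C ∈ 2^{−5..15},
γ ∈ 2^{−15..3}, powers of 4); LDA, QDA and Gaussian naive Bayes are fit
without tuning and raise informative errors when sample counts cannot
support their covariance estimates. `repeated_kfold_accuracy` reports the
mean and SD of pooled stratified k-fold accuracy over repeated seeded
partitions. `prescreen_ttest` is Welch's two-sided test by default (pooled
variant available); `aac` reports the mean absolute pairwise Pearson
correlation of a gene set.

## Problem sizes used in the shipped experiments

The test suite's recovery protocol runs the full pipeline on ten seeded
60 × 200 datasets (2 marginal genes at 1 σ, one interaction pair), and the
reproduction script (`scripts/acceptance.py`) runs five such datasets plus
a 1000-gene null calibration; these sizes exercise every stage at full
fidelity while keeping a complete run in the minutes range on one core.

## Known limitations

- With N ≈ 60, pooled-MCC quantisation limits the resolution of both the
  stopping rule and backward elimination; final list sizes are sensitive to
  the fold partition in a way the paper-scale datasets (hundreds to
  thousands of genes, slowly climbing μ) are not.
- A gene whose only signal is a pure two-gene interaction has a per-round
  elimination risk of roughly 5–15% under the default K; survival of both
  members through several rounds is therefore not guaranteed even when the
  pair alone classifies well.
- Two-class only; no multi-class extension. No normalisation is applied to
  input matrices (an explicit standardisation step is the caller's choice).
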