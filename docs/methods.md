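# Methods

## The question and the pipeline

Given two expression atlases registered to one brain-region ontology, we
ask how much of the region-level expression signal of one dataset
replicates in the other. The unit of analysis is the unordered pair of
leaf regions; the statistic is the rank-based AUROC of a linear model's
scores. The pipeline is: filter → stratified 50/50 split → all-pairs
model fitting (one fold) and scoring (the other fold, both directions
averaged) → cross-dataset scoring of the entire opposite dataset with the
trained model bank → summaries (means, distance trends, dendrograms).

## Statistics

**Analytic AUROC.** With ascending midranks of all scores, AUROC =
Σ ranks(pos)/(N₊N₋) − (N₊+1)/(2N₋). Midranks make the statistic coincide
with tie-corrected Mann–Whitney pair counting (ties worth ½), guarantee
AUROC(y) + AUROC(1−y) = 1 to double precision, and give exactly 0.5 for
constant scores — the property the permutation control relies on. Any
other tie rule breaks at least one of these.

**Precision at full recall.** Threshold = minimum positive score;
precision = N₊ / #{scores ≥ threshold}. Used to characterize whether a
perfect-recall operating point exists without false positives.

**Identity-line distance.** For paired performances (x, y) the mean
perpendicular distance |x−y|/√2 to the line y = x. The vertical variant
|x−y| (same up to √2) is available via `perpendicular=False`.
Correlation is deliberately not used here: two performance vectors can
correlate highly while differing substantially in value.

**Mann–Whitney DE ranking.** Per-gene two-sided MWU with the
tie-corrected normal approximation and continuity correction; constant
genes get p = 1. P-values are never corrected for multiplicity — they
only order genes to pick an extreme top-500 pool.

## Models

**LASSO.** Objective (1/2n)‖Xw + b − y‖² + λ‖w‖₁, unpenalized intercept,
no feature standardization; solved by scikit-learn coordinate descent
(tol 1e−4, max 10,000 iterations; exhausting the cap raises rather than
silently returning). Targets are coded 0/1 with the positive class the
lexicographically smaller region id — AUROC is invariant to the coding,
the convention only pins determinism. λ = 0 delegates to minimum-norm
least squares (pseudoinverse on centered data), which shares the
penalty-free objective's predictions and is the canonical solution when
genes ≫ samples.

**Penalty selection.** Pairs where both regions exceed 100 samples are
eligible; within the training fold, 3 random stratified 80/20 sub-splits
score each λ ∈ {0.01, 0.05, 0.1, 0.2, 0.5, 0.9} by mean validation
AUROC; argmax with ties to the smallest λ (grid order — most pairs tie at
or near 1, so the tie rule matters). Brain-wide runs use a fixed λ = 0.1.

**k-NN comparator.** k = 5, Euclidean, uniform weights, trained jointly
over all regions; predictions are one-hot expanded and each region's 0/1
column is scored as an AUROC against true membership (midranks absorb
the massive ties). Vote ties resolve to the smallest region label.

**CFS.** Greedy panel construction per pair: seed gene uniform from the
top-500 DE pool; candidates are *all* filtered genes (only the seed is
DE-restricted); the next candidate minimizes the mean signed Pearson
correlation (on the pair's training samples) with the accepted genes —
signed, not absolute, so an anticorrelated gene whose average cancels
shared nuisance is the most attractive candidate, which is what makes
complementary half-informative gene pairs combine; the candidate is
accepted only if the AUROC of the equal-weight average of raw expression
values strictly improves, and the first rejection stops the build.
Correlations use the pair's training samples (not the whole fold) for
symmetry with the pair-restricted model fitting. A Spearman option
exists. Ensembles build n sets from consecutive seeds and either carry
the best-training set forward or average per-set evaluations.

## Filtering and splitting conventions

* "Expressed" means strictly greater than zero. A gene is dropped when
  its nonzero count is strictly below 0.1% of samples (a gene at exactly
  the threshold is kept); then all samples of regions with fewer than 5
  samples are dropped. Gene filter first, then area filter, applied once
  (not iterated); the result is a fixed point of the filter.
* Harmonization keeps regions with ≥ 5 samples in *each* dataset and the
  gene intersection (first-dataset order), after duplicate-series
  averaging. Filtering always precedes splitting.
* The 50/50 split shuffles each region's samples (seeded) and deals them
  alternately; odd counts leave the extra sample in fold 0. Every
  within-dataset AUROC matrix is the element-wise mean over the two fold
  directions.
* AUROC entries of exactly 0 are excluded from summary means (they mark
  degenerate evaluations); skipped pairs are stored as missing (NaN),
  which is distinct from 0.

## Cross-dataset evaluation

Models trained within dataset X score *all* samples of dataset Y (not a
fold of it) — the opposite dataset was never seen in training, so no
fold discipline is needed and the larger evaluation set stabilizes the
estimate. The matched within-dataset number is the held-out-fold mean
over the same harmonized genes and regions.

**Batch adjustment.** Each dataset is z-scored per gene (zero-variance
genes stay centered), then each batch's per-gene mean and variance are
mapped onto the pooled values — a location/scale adjustment, i.e. the
non-empirical-Bayes core of ComBat-style correction. A hook
(`batch_adjust(..., adjuster=f)`) lets a full empirical-Bayes
implementation be substituted; the location/scale map is sufficient here
because per-gene affine maps barely move rank-based pairwise AUROCs.

## Distances and clustering

* Semantic distance = tree path length, depth(a) + depth(b) −
  2·depth(LCA).
* Physical distance = Euclidean distance between the two closest voxels
  of the regions, after discarding voxels at or beyond the hemisphere
  midline (strictly-below rule) on a configurable axis; computed in
  input coordinate units.
* Distance trends: integer bins for path length; equal-count decile bins
  (remainder to the first bins) for physical distance, plus the overall
  Pearson r across pairs. Matrix entries are already
  orientation-normalized, so no reorientation precedes binning.
* Region dendrograms use dissimilarity d = |AUROC − 0.5|: pairs the
  classifier cannot separate merge first. Average linkage by default
  (configurable); the transform makes clustering invariant to the
  orientation flip M → 1−M.

## PCA dimensionality and coexpression

Per shared region, the samples-by-genes block is centered and SVD'd; the
report is the smallest k with cumulative explained variance ≥ 80%. When
the first dataset has more samples of a region it is down-sampled
(seeded, without replacement) to the other's count; regions where it is
already smaller keep their size. Global curves report the first 200 PCs
of each whole dataset. Coexpression is the Spearman rho over all
unordered gene pairs (exact up to 2,000 genes; beyond that a seeded
uniform subsample of ≥ 10⁶ pairs, flagged in the output).

## The synthetic-atlas generator

Expression of sample s in region r of dataset d:

x[s, g] = max(0, baseline + Σ_{nodes on root→r path} effect_d[node, g]
               + z_s · L_dᵀ[g] + ε) , then a fraction of entries is zeroed.

* **Signatures.** Per-node gene effects are Gaussian with variance
  signature_scale²; a fraction `shared_signal_fraction` of that variance
  is drawn once and shared across datasets, the rest is redrawn per
  dataset. Summing along the path makes expression divergence grow with
  tree distance, so AUROC rises with semantic distance by construction.
* **Factor structure.** z_s ~ N(0, I_r); loadings L_d are Gaussian with
  per-factor variance factor_scale²/rank, so per-gene factor variance is
  rank-independent and only the *dimensionality* of the nuisance differs
  between datasets. The first factor's loadings are made all-positive —
  a global intensity/capture-efficiency axis — which is what gives the
  low-rank dataset its strong, positively skewed gene–gene correlation,
  as in ISH energy data.
* **Why rank creates the asymmetry.** A 2-dimensional nuisance can be
  projected out by a linear model fitted on 40 samples, and the same two
  directions persist in the held-out fold — within-dataset performance
  is inflated. Transferred to the high-rank dataset, those models face
  50 fresh nuisance directions plus the unshared 40% of the signatures
  and drop sharply; models trained under high-rank noise were never able
  to exploit such structure and transfer with a much smaller loss.
* **Sparsity.** Zero-inflation zeroes entries uniformly at random after
  signal generation (the simplest mechanism that matches a global
  percentage) and expression is clipped at zero (ISH energy and counts
  are nonnegative; keeps "expressed = nonzero" meaningful). Uniform
  zeroing is high-rank noise: at a sagittal-like 53.9% rate it would
  erase the low-rank structure that defines dataset A — real sagittal
  sparsity is structured by gene and section, which this generator does
  not model. The default *pair* therefore uses the coronal-like 7.5%
  rate for both datasets, keeping sparsity out of the rank contrast,
  while the sagittal-like 53.9% rate is exercised in the three-dataset
  configuration (coronal-like, sagittal-like, ST-like), where transfer
  out of the sparse dataset degrades as expected.
* **Geometry.** The grid is recursively sliced along its longest axis
  following the tree, so each leaf owns a contiguous axis-aligned block
  and siblings are adjacent (`layout="nested"`); `layout="shuffled"`
  permutes the leaf→block assignment, decoupling physical from semantic
  distance — the configuration used to show that classification
  difficulty tracks the ontology rather than geometry. Blocks straddle
  the z midline so the single-hemisphere distance rule is exercised.
* **Duplicates.** `inject_duplicate_series` replicates random genes under
  the same id with an optional fresh noise draw; duplicate averaging
  restores the original exactly at noise 0.
* **Determinism.** All randomness flows from one `SeedSequence`;
  identical configs give bit-identical outputs.

### Default configuration and rationale

24 leaves (6 top-level branches × 4), 40 samples per leaf, 600 genes —
small enough that the entire study (all-pairs LASSO in two datasets,
both transfer directions) runs in seconds per seed, large enough that
per-pair AUROCs are stable. latent_rank = (2, 50) gives the low-/
high-dimensional contrast; factor_scale = 4 makes the factor nuisance
the dominant within-region variance (median PCs to 80% ≈ 6 vs ≈ 23;
mean Spearman rho ≈ 0.2 vs ≈ 0.01); noise_sd = (1, 2) reflects the
noisier per-spot measurements of ST arrays and separates the
within-dataset means (≈ 0.998 vs ≈ 0.97); shared_signal_fraction = 0.6
leaves a substantial non-replicating component; baseline 5 keeps
expression mostly positive so clipping adds few zeros beyond the
injected ones.

### What the generator does not emulate

Count/intensity likelihoods (noise is Gaussian on a common scale — the
real datasets' ISH-energy vs UMI-count noise families are not modeled),
structured sparsity, registration error, within-region spatial gradients,
and hemispheric asymmetry. Passing tests therefore demonstrate that the
pipeline recovers planted low-rank/transfer/dimensionality structure,
not that real atlases exhibit it.

## Numerical notes and limitations

* Permutation controls land slightly above 0.5 (≈ 0.507–0.535 across
  seeds at this problem size): a single global label permutation keeps
  each permuted group's true-region composition, and the
  region-stratified folds preserve that composition across folds, so a
  trace of real signal survives. The same effect is visible in real
  atlas controls; it shrinks with region count and sample size.
* `pairwise_classify` skips pairs lacking both classes in a fold
  (logged, stored as NaN) rather than recording 0.
* k-NN and CFS ties, fold assignment of odd samples, and the positive-
  class coding are all fixed by documented deterministic conventions; no
  analysis depends on dict ordering or solver nondeterminism.
* AUROC-of-0 exclusion only affects genuinely computed zeros, which at
  these problem sizes essentially never occur; it exists for parity with
  the convention used on real atlases.
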