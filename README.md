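# atlasrep

Cross-dataset replicability of spatial brain-atlas gene expression.

Spatial atlases of the brain — ISH energy voxel grids, spatial
transcriptomics (ST) spot arrays — assign every sample a leaf region of an
anatomical ontology tree. A natural question for anyone reusing such an
atlas is whether its region-level expression signal is a property of the
brain or of the dataset: a classifier that separates two regions almost
perfectly within one atlas may carry very little over to a second atlas of
the same tissue. `atlasrep` implements the machinery to ask that question
quantitatively, and a synthetic-atlas generator with known ground truth to
exercise it end to end.

## What it computes

**Pairwise region classification.** For every unordered pair of leaf
regions \(i, j\), a linear model is fitted to the region's samples with an
L1 penalty (LASSO),

```
min_{w, b}  1/(2n) ||X w + b − y||²  +  λ ||w||₁ ,
```

with unpenalized intercept and unstandardized expression features
(λ = 0 falls back to minimum-Euclidean-norm least squares, the natural
solution when genes outnumber samples). Models train on one fold of a
region-stratified 50/50 split and are scored on the other; both fold
directions are averaged.

**Analytic AUROC.** Classifier scores are evaluated by the rank-based
area under the ROC curve, computed analytically from midranks:

```
AUROC = Σ ranks(positives) / (N_pos · N_neg) − (N_pos + 1) / (2 N_neg),
```

the tie-corrected Mann–Whitney estimate of P(score⁺ > score⁻).

**Cross-dataset transfer.** After harmonizing two datasets to their shared
genes and mutually well-sampled regions, every pair model trained in one
dataset scores the *entire* other dataset. The drop from within-dataset
held-out AUROC to cross-dataset AUROC measures how much of the signal
replicates.

**Supporting analyses.** Label-permutation chance controls; per-pair
penalty selection over λ ∈ {0.01, …, 0.9}; a k-NN multiclass comparator;
greedy correlation-based feature selection (CFS) marker panels;
one-vs-all vs one-vs-one identifiability summarized by mean distance from
the identity line; AUROC trends against semantic (tree path length) and
physical (minimum inter-voxel Euclidean) distance; per-region PCA
dimensionality; gene–gene Spearman coexpression; AUROC-based region
dendrograms; a location/scale batch adjustment.

**Synthetic paired atlases.** The generator emulates two (optionally
three) atlases registered to one region tree: hierarchical region
signatures whose divergence grows with tree distance, a controllable
fraction of signal shared between datasets, per-dataset latent-factor
structure (low rank ⇒ strong, positively skewed coexpression, as in ISH
energy data; high rank ⇒ weak coexpression, as in ST counts), uniform
zero-inflation, duplicate assay series, and voxel-grid coordinates with a
hemisphere midline. See `docs/methods.md` for the model and its defaults.

## Worked example

The numbered scripts under `analysis/` run the full study on the default
synthetic pair — dataset A low-rank/high-coexpression, dataset B
high-rank — writing tables under `results/`. For example:

```
$ python analysis/03_cross_dataset.py --seed 0
           raw A->B: within-test 0.998, cross 0.866, drop +0.132
           raw B->A: within-test 0.971, cross 0.917, drop +0.054
batch_adjusted A->B: within-test 0.990, cross 0.790, drop +0.200
batch_adjusted B->A: within-test 0.942, cross 0.893, drop +0.049
transfer asymmetry (drop A->B minus drop B->A) = +0.078
```

Reading: within its own dataset the low-rank atlas A classifies region
pairs nearly perfectly (mean AUROC 0.998, vs 0.971 in B), but its models
lose more than twice as much AUROC when transferred to B (−0.132) as B's
models lose in the opposite direction (−0.054) — A's within-dataset
performance is inflated by dataset-specific low-dimensional structure,
and batch adjustment does not rescue it. The companion scripts show the
diagnosis:

```
$ python analysis/05_dimensionality_coexpression.py --seed 0
median PCs to 80% variance per region: A = 6, B = 23
mean gene-gene Spearman rho in A: 0.226
mean gene-gene Spearman rho in B: 0.007

$ python analysis/02_within_dataset.py --seed 0
A: mean pairwise AUROC = 0.998, permuted-label control = 0.507, ...
B: mean pairwise AUROC = 0.971, permuted-label control = 0.510, ...
```

and `analysis/04_distance_trends.py` shows that difficulty tracks the
ontology (mean AUROC 0.993 for sibling regions vs 0.999 across major
branches) but not physical distance (Pearson r = +0.015).

A `atlasrep` command-line tool exposes the same operations on datasets
stored as TSV directories (`atlasrep simulate`, `filter`, `harmonize`,
`split`, `classify-pairwise`, `permute-control`, `select-lambda`, `knn`,
`cfs`, `transfer`, `one-vs-all`, `trend`, `dimensionality`,
`coexpression`).

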