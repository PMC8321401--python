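"""Mann-Whitney differential-expression ranking and greedy CFS.

Correlation-based feature selection (CFS) builds a small panel of mutually
uncorrelated marker genes for one region pair:

1. seed with a random gene from the top 500 genes ranked by two-sided
   Mann-Whitney U p-value (uncorrected — the p-values only order genes);
2. repeatedly propose the candidate gene least correlated on average
   (signed Pearson correlation, computed on the pair's training samples)
   with the genes already accepted — an anticorrelated candidate is the
   most attractive, since averaging it in cancels shared nuisance;
3. score the equal-weight average of the accepted-plus-candidate columns
   by AUROC on the training samples and accept only on strict improvement;
4. stop at the first candidate that does not improve.

An ensemble repeats this from many random seeds and either carries forward
the single best-training set or averages the per-set evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .rank_metrics import auroc

__all__ = ["FeatureSet", "mwu_de_rank", "cfs_build_set", "cfs_ensemble"]


@dataclass
class FeatureSet:
    """Ordered accepted genes with the training-AUROC trajectory."""

    genes: list[str]
    seed_gene: str
    train_auroc_trajectory: list[float]
    final_train_auroc: float
    gene_indices: list[int] = field(default_factory=list)


def mwu_pvalues(X_pos: np.ndarray, X_neg: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney U p-value per gene (normal approximation).

    Uses the tie-corrected normal approximation on midranks; a gene
    constant across both groups gets p = 1.
    """
    n1, n2 = X_pos.shape[0], X_neg.shape[0]
    n = n1 + n2
    both = np.vstack([X_pos, X_neg])
    ranks = np.apply_along_axis(rankdata, 0, both)
    u1 = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction: sum over tie groups of (t^3 - t) per gene
    tie_term = np.zeros(both.shape[1])
    for j in range(both.shape[1]):
        _, counts = np.unique(both[:, j], return_counts=True)
        tie_term[j] = (counts**3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    p = np.ones(both.shape[1])
    ok = var_u > 0
    z = np.zeros_like(p)
    # continuity correction of 0.5, as in the standard asymptotic test
    numer = np.abs(u1[ok] - mean_u) - 0.5
    z[ok] = np.maximum(numer, 0.0) / np.sqrt(var_u[ok])
    p[ok] = np.minimum(2.0 * norm.sf(z[ok]), 1.0)
    return p


def mwu_de_rank(
    X_pos: np.ndarray, X_neg: np.ndarray, gene_ids: list[str]
) -> tuple[list[str], np.ndarray]:
    """Genes ordered by ascending MWU p-value (ties broken by gene id).

    No multiple-testing correction is applied: the ranking is only used to
    pick extreme differentially expressed genes, not to report
    significance.  Returns ``(ordered gene ids, p-values in input order)``.
    """
    p = mwu_pvalues(np.asarray(X_pos, float), np.asarray(X_neg, float))
    order = sorted(range(len(gene_ids)), key=lambda j: (p[j], gene_ids[j]))
    return [gene_ids[j] for j in order], p


def _train_auroc(columns: np.ndarray, y: np.ndarray) -> float:
    """AUROC of the equal-weight average of raw expression columns."""
    score = columns.mean(axis=1) if columns.ndim == 2 else columns
    return auroc(score, y)


def cfs_build_set(
    X_train: np.ndarray,
    y_train: np.ndarray,
    gene_ids: list[str],
    seed: int,
    de_top: int = 500,
    correlation: str = "pearson",
) -> FeatureSet:
    """Build one greedy CFS feature set for a two-class training problem.

    ``X_train`` holds the pair's training samples only; ``y_train`` is the
    0/1 region coding.  The seed gene is drawn uniformly from the top
    ``de_top`` MWU-ranked genes; candidates come from all genes.
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train).astype(int)
    ordered, _ = mwu_de_rank(X_train[y_train == 1], X_train[y_train == 0], gene_ids)
    pool = ordered[: min(de_top, len(ordered))]
    rng = np.random.default_rng(seed)
    seed_gene = pool[int(rng.integers(len(pool)))]
    pos = {g: j for j, g in enumerate(gene_ids)}

    if correlation == "spearman":
        C = np.apply_along_axis(rankdata, 0, X_train)
    elif correlation == "pearson":
        C = X_train
    else:
        raise ValueError("correlation must be 'pearson' or 'spearman'")
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = C.std(axis=0)
        Z = (C - C.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0  # constant genes: define correlation as 0

    accepted = [pos[seed_gene]]
    current = _train_auroc(X_train[:, accepted], y_train)
    trajectory = [current]
    remaining = np.ones(len(gene_ids), dtype=bool)
    remaining[accepted[0]] = False
    mean_corr = (Z.T @ Z[:, accepted[0]]) / X_train.shape[0]
    while remaining.any():
        cand = int(np.flatnonzero(remaining)[np.argmin(mean_corr[remaining])])
        score = _train_auroc(X_train[:, accepted + [cand]], y_train)
        if score <= current:
            break
        accepted.append(cand)
        current = score
        trajectory.append(score)
        remaining[cand] = False
        k = len(accepted)
        mean_corr = (
            mean_corr * (k - 1) + (Z.T @ Z[:, cand]) / X_train.shape[0]
        ) / k
    return FeatureSet(
        genes=[gene_ids[j] for j in accepted],
        seed_gene=seed_gene,
        train_auroc_trajectory=trajectory,
        final_train_auroc=current,
        gene_indices=accepted,
    )


def cfs_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    gene_ids: list[str],
    eval_sets: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    n_sets: int = 100,
    mode: str = "best",
    seed: int = 0,
    de_top: int = 500,
) -> dict:
    """Build ``n_sets`` CFS sets from consecutive seeds and evaluate them.

    ``eval_sets`` maps a name (e.g. "test", "cross") to ``(X, y)`` with
    columns in ``gene_ids`` order.  ``mode="best"`` evaluates only the set
    with the highest training AUROC (first of ties); ``mode="average"``
    reports the mean of the per-set evaluations.  Deterministic in
    ``seed``.
    """
    if mode not in ("best", "average"):
        raise ValueError("mode must be 'best' or 'average'")
    if n_sets < 1:
        raise ValueError("n_sets must be at least 1")
    sets = [
        cfs_build_set(X_train, y_train, gene_ids, seed=seed + i, de_top=de_top)
        for i in range(n_sets)
    ]
    record: dict = {
        "mode": mode,
        "n_sets": n_sets,
        "sets": sets,
        "train_aurocs": [fs.final_train_auroc for fs in sets],
        "set_sizes": [len(fs.genes) for fs in sets],
    }
    eval_sets = eval_sets or {}

    def _eval(fs: FeatureSet, X, y) -> float:
        return _train_auroc(np.asarray(X, float)[:, fs.gene_indices], np.asarray(y).astype(int))

    if mode == "best":
        best = sets[int(np.argmax(record["train_aurocs"]))]
        record["best_set"] = best
        record["train_auroc"] = best.final_train_auroc
        for name, (X, y) in eval_sets.items():
            record[name] = _eval(best, X, y)
    else:
        record["train_auroc"] = float(np.mean(record["train_aurocs"]))
        for name, (X, y) in eval_sets.items():
            record[name] = float(np.mean([_eval(fs, X, y) for fs in sets]))
    return record
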