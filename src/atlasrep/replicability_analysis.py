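"""Cross-dataset experiments and derived diagnostics.

Given two harmonized atlases (same genes, same leaf regions), the central
experiment takes the bank of pairwise models trained within one dataset
and scores the *entire* opposite dataset with them, comparing the
cross-dataset AUROCs with the matched within-dataset held-out AUROCs.  A
replicable atlas pair loses little performance in transfer; an atlas whose
within-dataset performance is inflated by dataset-specific structure loses
a lot.

Supporting analyses: a location/scale batch adjustment (z-score each
dataset, then align each batch's per-gene mean and variance to the pooled
values — the non-empirical-Bayes reduction of ComBat-style correction,
with a hook for substituting a full implementation), one-vs-all versus
one-vs-one generalization summarized by distance from the identity line,
AUROC trends against semantic (tree path) and physical (voxel) distance,
per-region PCA dimensionality, and the gene-gene Spearman coexpression
summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .atlas_data import ExpressionDataset, SplitFolds
from .linear_classifiers import AurocMatrix, PairModelBank, _fit
from .rank_metrics import auroc, identity_line_distance
from .region_ontology import RegionTree, min_region_distance, path_length

__all__ = [
    "TransferResult",
    "TrendSummary",
    "cross_dataset_transfer",
    "batch_adjust",
    "one_vs_all_generalization",
    "trend_by_path_length",
    "trend_by_distance",
    "pca_dimensionality",
    "coexpression_summary",
    "region_pair_distances",
]

logger = logging.getLogger(__name__)


@dataclass
class TransferResult:
    """Within- vs cross-dataset pairwise performance for one direction."""

    direction: tuple[str, str]
    within_test: AurocMatrix
    cross: AurocMatrix
    means: dict = field(default_factory=dict)


@dataclass
class TrendSummary:
    """Binned AUROC against a pair-level covariate (path length or distance)."""

    table: pd.DataFrame  # columns: bin, mean_auroc, sd_auroc, n_pairs
    correlation: float | None = None  # Pearson r for the distance analysis
    meta: dict = field(default_factory=dict)


def cross_dataset_transfer(
    bank: PairModelBank,
    within_test: AurocMatrix,
    ds_other: ExpressionDataset,
) -> TransferResult:
    """Score another dataset with a bank of pairwise models.

    Every fold model of every pair scores all samples of the two regions
    in the opposite dataset (the whole dataset, not a fold); the pair's
    cross AUROC is the mean over the fold models.  ``within_test`` must be
    the matched within-dataset evaluation over the same harmonized genes
    and regions.
    """
    regions = within_test.regions
    pos = {r: i for i, r in enumerate(regions)}
    values = np.full((len(regions), len(regions)), np.nan)
    for (ri, rj), per_fold in bank.models.items():
        if ri not in pos or rj not in pos:
            continue
        idx = np.flatnonzero(np.isin(ds_other.labels, (ri, rj)))
        y = (ds_other.labels[idx] == ri).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            logger.info("transfer: pair (%s, %s) lacks a class in %s", ri, rj, ds_other.tag)
            continue
        first_model = next(iter(per_fold.values()))
        if first_model.coef.shape[0] != ds_other.n_genes:
            raise ValueError(
                f"gene mismatch: models have {first_model.coef.shape[0]} coefficients, "
                f"dataset {ds_other.tag!r} has {ds_other.n_genes} genes"
            )
        vals = [auroc(m.predict(ds_other.X[idx]), y) for m in per_fold.values()]
        values[pos[ri], pos[rj]] = values[pos[rj], pos[ri]] = float(np.mean(vals))
    cross = AurocMatrix(
        regions=list(regions),
        values=values,
        meta={**bank.meta, "scored_on": ds_other.tag, "evaluation": "entire dataset"},
    )
    direction = (bank.meta.get("tag", "train"), ds_other.tag)
    result = TransferResult(direction=direction, within_test=within_test, cross=cross)
    result.means = {
        "within_test_mean": within_test.summary_mean(),
        "cross_mean": cross.summary_mean(),
    }
    result.means["drop"] = result.means["within_test_mean"] - result.means["cross_mean"]
    return result


# --- batch adjustment ------------------------------------------------------


def batch_adjust(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    adjuster=None,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Z-score each dataset, then align per-gene batch moments to pooled values.

    Step 1 normalizes each dataset independently per gene (a gene with zero
    variance is left centered at 0).  Step 2 treats each dataset as a
    batch of the concatenated matrix and maps each batch's per-gene mean
    and variance onto the pooled per-gene mean and variance — a
    location/scale adjustment.  ``adjuster``, if given, replaces step 2:
    it receives ``(X_combined, batch_labels)`` and must return the
    adjusted combined matrix (hook for a full empirical-Bayes ComBat).
    """
    if ds_a.gene_ids != ds_b.gene_ids:
        raise ValueError("batch adjustment requires harmonized (identical) gene lists")

    def _zscore(X):
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        return (X - mu) / np.where(sd > 0, sd, 1.0)

    za, zb = _zscore(ds_a.X), _zscore(ds_b.X)
    combined = np.vstack([za, zb])
    if adjuster is not None:
        batches = np.array([ds_a.tag] * za.shape[0] + [ds_b.tag] * zb.shape[0])
        adjusted = np.asarray(adjuster(combined, batches), dtype=float)
    else:
        pooled_mu = combined.mean(axis=0)
        pooled_sd = combined.std(axis=0)
        adjusted_parts = []
        for Z in (za, zb):
            mu = Z.mean(axis=0)
            sd = Z.std(axis=0)
            scale = np.where(sd > 0, pooled_sd / np.where(sd > 0, sd, 1.0), 0.0)
            adjusted_parts.append((Z - mu) * scale + pooled_mu)
        adjusted = np.vstack(adjusted_parts)
    na = ds_a.n_samples
    out_a, out_b = ds_a.copy(), ds_b.copy()
    out_a.X, out_b.X = adjusted[:na], adjusted[na:]
    return out_a, out_b


# --- one-vs-all generalization ---------------------------------------------


def one_vs_all_generalization(
    ds: ExpressionDataset,
    folds: SplitFolds,
    lam: float = 0.0,
    model: str = "linreg",
    ds_other: ExpressionDataset | None = None,
    train_fold: int = 0,
) -> tuple[pd.DataFrame, float]:
    """One-vs-all training versus one-vs-one evaluation, per region.

    For each region ``r`` a model trains on the training fold with
    positives = ``r`` and negatives = everything else.  ``x`` is its
    one-vs-all AUROC on the held-out fold; ``y`` is the mean over all
    other regions ``q`` of the AUROC scoring only held-out samples of
    ``{r, q}`` (or, when ``ds_other`` is given, all samples of the
    opposite dataset — the cross-dataset variant).  Returns the per-region
    (x, y) records and their mean distance from the identity line.
    """
    regions = sorted(set(ds.labels))
    if len(regions) < 2:
        raise ValueError("one-vs-all needs at least two regions")
    tr = folds.indices(train_fold)
    te = folds.indices(1 - train_fold)
    eval_ds, eval_idx = (ds, te) if ds_other is None else (ds_other, np.arange(ds_other.n_samples))
    rows = []
    for r in regions:
        y_tr = (ds.labels[tr] == r).astype(float)
        if y_tr.sum() == 0 or y_tr.sum() == y_tr.size:
            logger.info("one-vs-all: region %s untrainable, skipped", r)
            continue
        m = _fit(ds.X[tr], y_tr, lam, model)
        y_te = (ds.labels[te] == r).astype(int)
        scores_te = m.predict(ds.X[te])
        x_val = auroc(scores_te, y_te)
        scores_ev = m.predict(eval_ds.X[eval_idx])
        labels_ev = eval_ds.labels[eval_idx]
        one_vs_one = []
        for q in regions:
            if q == r:
                continue
            mask = np.isin(labels_ev, (r, q))
            y_pair = (labels_ev[mask] == r).astype(int)
            if y_pair.sum() == 0 or y_pair.sum() == y_pair.size:
                continue
            one_vs_one.append(auroc(scores_ev[mask], y_pair))
        if not one_vs_one:
            continue
        rows.append((r, x_val, float(np.mean(one_vs_one)), m.n_nonzero))
    records = pd.DataFrame(
        rows, columns=["region", "one_vs_all_auroc", "mean_one_vs_one_auroc", "n_nonzero"]
    )
    dist = identity_line_distance(
        records[["one_vs_all_auroc", "mean_one_vs_one_auroc"]].to_numpy()
    )
    return records, dist


# --- trends ----------------------------------------------------------------


def trend_by_path_length(matrix: AurocMatrix, tree: RegionTree) -> TrendSummary:
    """Mean/sd AUROC per integer semantic distance (tree path length)."""
    pairs = matrix.pair_values()
    pairs["path_length"] = [
        path_length(tree, ri, rj) for ri, rj in zip(pairs.region_i, pairs.region_j)
    ]
    grouped = pairs.groupby("path_length")["auroc"]
    table = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "mean_auroc": grouped.mean().to_numpy(),
            "sd_auroc": grouped.std(ddof=1).to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        }
    )
    if pairs.path_length.nunique() > 1 and pairs.auroc.nunique() > 1:
        rho = spearmanr(pairs.path_length, pairs.auroc).statistic
    else:
        rho = np.nan
    return TrendSummary(table=table, meta={"kind": "path_length", "spearman": float(rho)})


def region_pair_distances(
    ds: ExpressionDataset, regions: list[str], midline: float | None, axis: str = "z"
) -> dict[tuple[str, str], float]:
    """Minimum inter-voxel Euclidean distance for every region pair."""
    coords = {r: ds.coords[ds.labels == r] for r in regions}
    out = {}
    for i, ri in enumerate(regions):
        for rj in regions[i + 1:]:
            out[(ri, rj)] = min_region_distance(coords[ri], coords[rj], midline, axis)
    return out


def trend_by_distance(
    matrix: AurocMatrix, distances: dict[tuple[str, str], float], n_bins: int = 10
) -> TrendSummary:
    """AUROC against physical distance: decile bins plus the overall Pearson r.

    Pairs are sorted by distance and cut into ``n_bins`` equal-count bins
    (any remainder spread over the first bins).  Fewer pairs than bins
    degrades gracefully to one pair per bin.
    """
    pairs = matrix.pair_values()
    pairs["distance"] = [
        distances.get((ri, rj), distances.get((rj, ri)))
        for ri, rj in zip(pairs.region_i, pairs.region_j)
    ]
    if pairs["distance"].isna().any():
        raise ValueError("a distance is missing for some evaluated pair")
    n = len(pairs)
    if n < n_bins:
        logger.info("only %d pairs for %d bins; using %d bins", n, n_bins, n)
        n_bins = max(n, 1)
    order = np.argsort(pairs["distance"].to_numpy(), kind="stable")
    sizes = np.full(n_bins, n // n_bins)
    sizes[: n % n_bins] += 1
    bins = np.empty(n, dtype=int)
    start = 0
    for b, s in enumerate(sizes):
        bins[order[start: start + s]] = b + 1
        start += s
    pairs["bin"] = bins
    grouped = pairs.groupby("bin")["auroc"]
    table = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "mean_auroc": grouped.mean().to_numpy(),
            "sd_auroc": grouped.std(ddof=1).to_numpy(),
            "n_pairs": grouped.size().to_numpy(),
        }
    )
    r = float(np.corrcoef(pairs["distance"], pairs["auroc"])[0, 1]) if n > 1 else np.nan
    return TrendSummary(table=table, correlation=r, meta={"kind": "distance"})


# --- dimensionality & coexpression -----------------------------------------


def _pcs_to_variance(X: np.ndarray, threshold: float) -> int:
    """Smallest number of PCs whose cumulative explained variance >= threshold."""
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    var = s**2
    total = var.sum()
    if total == 0:
        return 1
    cum = np.cumsum(var) / total
    return int(np.searchsorted(cum, threshold - 1e-12) + 1)


def pca_dimensionality(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    variance_threshold: float = 0.8,
    n_global_pcs: int = 200,
    seed: int = 0,
) -> dict:
    """Per-region PCA dimensionality and global explained-variance curves.

    Each shared region's samples-by-genes block is analysed separately;
    when dataset A has more samples of a region than B, A's block is
    first down-sampled (uniform, seeded, without replacement) to B's
    count so the comparison is sample-size matched; regions where A is
    the smaller side keep their original size.  Reported per region: the
    smallest number of PCs reaching ``variance_threshold`` cumulative
    explained variance.  Globally: the cumulative explained-variance curve
    of the first ``n_global_pcs`` components of each whole dataset.
    """
    rng = np.random.default_rng(seed)
    regions = sorted(set(ds_a.labels) & set(ds_b.labels))
    rows = []
    for r in regions:
        Xa = ds_a.X[ds_a.labels == r]
        Xb = ds_b.X[ds_b.labels == r]
        if Xa.shape[0] < 2 or Xb.shape[0] < 2:
            logger.info("dimensionality: region %s has < 2 samples, skipped", r)
            continue
        if Xa.shape[0] > Xb.shape[0]:
            Xa = Xa[rng.choice(Xa.shape[0], size=Xb.shape[0], replace=False)]
        rows.append(
            (r, _pcs_to_variance(Xa, variance_threshold),
             _pcs_to_variance(Xb, variance_threshold), Xa.shape[0], Xb.shape[0])
        )
    per_region = pd.DataFrame(
        rows, columns=["region", f"pcs_{ds_a.tag}", f"pcs_{ds_b.tag}",
                       f"n_{ds_a.tag}", f"n_{ds_b.tag}"]
    )

    def _global_curve(X):
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        var = s**2
        cum = np.cumsum(var) / var.sum()
        k = min(n_global_pcs, cum.size)
        return cum[:k]

    return {
        "per_region": per_region,
        "median_pcs": {
            ds_a.tag: float(per_region[f"pcs_{ds_a.tag}"].median()),
            ds_b.tag: float(per_region[f"pcs_{ds_b.tag}"].median()),
        },
        "global_curves": {ds_a.tag: _global_curve(ds_a.X), ds_b.tag: _global_curve(ds_b.X)},
        "variance_threshold": variance_threshold,
    }


def coexpression_summary(
    ds: ExpressionDataset,
    max_exact_genes: int = 2000,
    n_subsample_pairs: int = 1_000_000,
    seed: int = 0,
    n_hist_bins: int = 40,
) -> dict:
    """Gene-gene Spearman correlation over the whole dataset.

    Exact over all unordered gene pairs up to ``max_exact_genes`` genes;
    beyond that a seeded uniform subsample of pairs is used and flagged in
    the output.  Returns the mean rho and a histogram table.
    """
    if ds.n_genes < 2:
        raise ValueError("coexpression needs at least 2 genes")
    R = np.apply_along_axis(rankdata, 0, ds.X)
    sd = R.std(axis=0)
    Z = (R - R.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    Z[:, sd == 0] = 0.0
    g = ds.n_genes
    exact = g <= max_exact_genes
    if exact:
        C = (Z.T @ Z) / ds.n_samples
        rhos = C[np.triu_indices(g, k=1)]
    else:
        rng = np.random.default_rng(seed)
        n_pairs = min(n_subsample_pairs, g * (g - 1) // 2)
        i_parts, j_parts, collected = [], [], 0
        while collected < n_pairs:  # rejection-sample unordered pairs
            draw = max(1024, int((n_pairs - collected) * 2.2))
            ii = rng.integers(0, g, size=draw)
            jj = rng.integers(0, g, size=draw)
            keep = ii < jj
            i_parts.append(ii[keep])
            j_parts.append(jj[keep])
            collected += int(keep.sum())
        i = np.concatenate(i_parts)[:n_pairs]
        j = np.concatenate(j_parts)[:n_pairs]
        rhos = np.einsum("si,si->i", Z[:, i], Z[:, j]) / ds.n_samples
    hist, edges = np.histogram(rhos, bins=n_hist_bins, range=(-1.0, 1.0))
    return {
        "mean_rho": float(rhos.mean()),
        "rhos": rhos,
        "histogram": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
        ),
        "exact": exact,
        "tag": ds.tag,
    }
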