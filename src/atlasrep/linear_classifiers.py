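"""Linear models and the all-pairs region-classification engine.

Pairwise classification treats every unordered pair of leaf regions as a
two-class problem scored by a linear model: either L1-regularized linear
regression (LASSO, objective ``1/(2n) ||X w + b - y||^2 + lambda ||w||_1``
with an unpenalized intercept and no feature standardization) or plain
least squares, which in the usual genes >> samples regime returns the
minimum-Euclidean-norm solution.  Targets are coded 0/1 with the positive
class the lexicographically smaller region id — AUROC is invariant to the
coding, the convention only fixes determinism.

Each pair is fitted on one fold of the stratified 50/50 split, scored on
the other, then the folds are swapped and the two AUROCs averaged; the
resulting matrix is symmetric with an undefined diagonal.  A label
permutation applied before pair restriction provides the chance control,
and a k-nearest-neighbour multiclass comparator is included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.neighbors import KNeighborsClassifier

from .atlas_data import ExpressionDataset, SplitFolds
from .rank_metrics import auroc

__all__ = [
    "LinearModel",
    "AurocMatrix",
    "PairModelBank",
    "fit_lasso",
    "fit_minimum_norm",
    "pairwise_classify",
    "permutation_control",
    "select_lambda",
    "knn_area_auroc",
    "LAMBDA_GRID",
]

logger = logging.getLogger(__name__)

LAMBDA_GRID = (0.01, 0.05, 0.1, 0.2, 0.5, 0.9)


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LinearModel:
    """Coefficients of one fitted pairwise (or one-vs-all) linear model."""

    coef: np.ndarray
    intercept: float
    lam: float
    trained_on: tuple = ()

    def predict(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coef))


@dataclass
class AurocMatrix:
    """Symmetric fold-averaged pairwise AUROC matrix (NaN = not computed)."""

    regions: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def pair_values(self) -> pd.DataFrame:
        rows = []
        n = len(self.regions)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isnan(self.values[i, j]):
                    rows.append((self.regions[i], self.regions[j], self.values[i, j]))
        return pd.DataFrame(rows, columns=["region_i", "region_j", "auroc"])

    def summary_mean(self, drop_exact_zeros: bool = True) -> float:
        """Mean over computed off-diagonal pairs.

        Entries equal to exactly 0 are excluded from summaries by
        convention (they indicate a degenerate evaluation, not genuine
        anti-performance); missing pairs are always excluded.
        """
        iu = np.triu_indices(len(self.regions), k=1)
        v = self.values[iu]
        v = v[~np.isnan(v)]
        if drop_exact_zeros:
            v = v[v != 0.0]
        return float(v.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.regions, columns=self.regions)


@dataclass
class PairModelBank:
    """Fitted models per region pair and training fold."""

    models: dict[tuple[str, str], dict[int, LinearModel]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, pair: tuple[str, str], fold: int, model: LinearModel) -> None:
        self.models.setdefault(pair, {})[fold] = model

    def coefficient_table(self) -> pd.DataFrame:
        """Long-form table of nonzero coefficients for serialization."""
        rows = []
        for (ri, rj), per_fold in self.models.items():
            for fold, m in per_fold.items():
                for g in np.flatnonzero(m.coef):
                    rows.append((ri, rj, fold, g, m.coef[g], m.intercept, m.lam))
        return pd.DataFrame(
            rows,
            columns=["region_i", "region_j", "fold", "gene_index", "weight",
                     "intercept", "lambda"],
        )


# --- model fitting ---------------------------------------------------------


def fit_lasso(
    X,
    y,
    lam: float,
    fit_intercept: bool = True,
    tol: float = 1e-4,
    max_iter: int = 10_000,
) -> LinearModel:
    """L1-regularized least squares by coordinate descent.

    Minimizes ``1/(2 n) ||X w + b - y||^2 + lam ||w||_1`` with the
    intercept ``b`` unpenalized and features unstandardized.  ``lam = 0``
    falls back to :func:`fit_minimum_norm`, whose predictions the
    penalty-free objective shares.  Raises :class:`ConvergenceError` if
    coordinate descent exhausts ``max_iter`` without reaching ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if lam == 0:
        return fit_minimum_norm(X, y, fit_intercept=fit_intercept)
    est = Lasso(alpha=lam, fit_intercept=fit_intercept, tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.filterwarnings("error", category=ConvergenceWarning)
        try:
            est.fit(X, y)
        except ConvergenceWarning as w:  # pragma: no cover - defensive
            raise ConvergenceError(
                f"coordinate descent did not converge within {max_iter} iterations "
                f"(tol={tol}): {w}"
            ) from w
    return LinearModel(
        coef=np.asarray(est.coef_, dtype=float),
        intercept=float(est.intercept_) if fit_intercept else 0.0,
        lam=lam,
    )


def fit_minimum_norm(X, y, fit_intercept: bool = True) -> LinearModel:
    """Least squares; among minimizers, the coefficient vector of minimal L2 norm.

    In the underdetermined genes > samples case the residuals are exactly
    zero and the pseudoinverse solution is returned (intercept, when
    fitted, is absorbed by centering and never penalized).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if fit_intercept:
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        coef, *_ = np.linalg.lstsq(X - x_mean, y - y_mean, rcond=None)
        intercept = float(y_mean - x_mean @ coef)
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept = 0.0
    return LinearModel(coef=np.asarray(coef), intercept=intercept, lam=0.0)


def _fit(X, y, lam: float, model: str) -> LinearModel:
    if model == "lasso":
        return fit_lasso(X, y, lam)
    if model == "linreg":
        return fit_minimum_norm(X, y)
    raise ValueError(f"unknown model kind {model!r}")


# --- all-pairs engine ------------------------------------------------------


def pairwise_classify(
    ds: ExpressionDataset,
    folds: SplitFolds,
    lam: float = 0.1,
    model: str = "lasso",
    return_models: bool = False,
):
    """Fold-averaged AUROC for every unordered pair of leaf regions.

    For each pair the model trains on one fold's samples of the two
    regions (positive class = smaller region id), scores the other fold,
    and the two fold-directions are averaged.  Pairs lacking both classes
    in either fold are skipped with a log message and left missing (NaN),
    which is distinct from a computed AUROC of 0.
    """
    regions = sorted(set(ds.labels))
    n = len(regions)
    values = np.full((n, n), np.nan)
    bank = PairModelBank(meta={"lambda": lam, "model": model, "tag": ds.tag})
    fold_idx = {f: folds.indices(f) for f in (0, 1)}
    region_fold: dict[tuple[str, int], np.ndarray] = {}
    for r in regions:
        mask = np.flatnonzero(ds.labels == r)
        in_fold0 = np.isin(mask, fold_idx[0])
        region_fold[(r, 0)] = mask[in_fold0]
        region_fold[(r, 1)] = mask[~in_fold0]
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = regions[i], regions[j]
            if any(
                len(region_fold[(r, f)]) == 0 for r in (ri, rj) for f in (0, 1)
            ):
                logger.info("skipping pair (%s, %s): a fold lacks a class", ri, rj)
                continue
            per_fold = []
            for train_fold in (0, 1):
                tr = np.concatenate(
                    [region_fold[(ri, train_fold)], region_fold[(rj, train_fold)]]
                )
                te = np.concatenate(
                    [region_fold[(ri, 1 - train_fold)], region_fold[(rj, 1 - train_fold)]]
                )
                y_tr = (ds.labels[tr] == ri).astype(float)
                y_te = (ds.labels[te] == ri).astype(int)
                m = _fit(ds.X[tr], y_tr, lam, model)
                m.trained_on = (ds.tag, train_fold, ri, rj)
                per_fold.append(auroc(m.predict(ds.X[te]), y_te))
                if return_models:
                    bank.add((ri, rj), train_fold, m)
            values[i, j] = values[j, i] = float(np.mean(per_fold))
    mat = AurocMatrix(
        regions=regions,
        values=values,
        meta={"lambda": lam, "model": model, "tag": ds.tag, "seed": folds.seed},
    )
    return (mat, bank) if return_models else mat


def permutation_control(
    ds: ExpressionDataset,
    folds: SplitFolds,
    lam: float = 0.1,
    seed: int = 0,
    model: str = "lasso",
) -> AurocMatrix:
    """Chance control: permute all region labels once, then classify all pairs.

    The permutation is applied over the whole dataset before any pair
    restriction, so every "region" becomes a random sample of the brain
    and all pairwise AUROCs should concentrate at 0.5.
    """
    rng = np.random.default_rng(seed)
    permuted = ds.copy()
    permuted.labels = ds.labels[rng.permutation(ds.n_samples)]
    mat = pairwise_classify(permuted, folds, lam=lam, model=model)
    mat.meta["permutation_seed"] = seed
    return mat


# --- hyperparameter selection ----------------------------------------------


def select_lambda(
    ds: ExpressionDataset,
    folds: SplitFolds,
    grid=LAMBDA_GRID,
    n_splits: int = 3,
    test_size: float = 0.2,
    min_area_n: int = 100,
    train_fold: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair penalty selection by repeated stratified validation splits.

    Only pairs whose regions both exceed ``min_area_n`` samples are
    eligible.  Within the training fold, ``n_splits`` random stratified
    80/20 sub-splits score each candidate penalty by mean validation
    AUROC; the winner is the argmax with ties broken toward the smallest
    penalty (grid order).  Returns one row per eligible pair with the
    selected penalty and the per-penalty mean AUROCs.
    """
    grid = list(grid)
    counts = ds.region_counts()
    eligible = sorted(counts.index[counts > min_area_n])
    pairs = [
        (eligible[i], eligible[j])
        for i in range(len(eligible))
        for j in range(i + 1, len(eligible))
    ]
    if not pairs:
        raise ValueError(
            f"no region pair has more than {min_area_n} samples in both regions"
        )
    rng = np.random.default_rng(seed)
    tr_all = folds.indices(train_fold)
    rows = []
    for ri, rj in pairs:
        idx = tr_all[np.isin(ds.labels[tr_all], (ri, rj))]
        y = (ds.labels[idx] == ri).astype(float)
        scores = {lam: [] for lam in grid}
        for _ in range(n_splits):
            val = _stratified_holdout(y, test_size, rng)
            tr = ~val
            for lam in grid:
                m = fit_lasso(ds.X[idx[tr]], y[tr], lam) if lam > 0 else fit_minimum_norm(
                    ds.X[idx[tr]], y[tr]
                )
                scores[lam].append(auroc(m.predict(ds.X[idx[val]]), y[val].astype(int)))
        means = [float(np.mean(scores[lam])) for lam in grid]
        best = grid[int(np.argmax(means))]  # argmax returns the first of ties
        rows.append((ri, rj, best, *means))
    return pd.DataFrame(
        rows,
        columns=["region_i", "region_j", "best_lambda"]
        + [f"auroc_lambda_{lam}" for lam in grid],
    )


def _stratified_holdout(y: np.ndarray, test_size: float, rng) -> np.ndarray:
    """Boolean validation mask with ~test_size per class (at least 1 each)."""
    val = np.zeros(y.size, dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        k = max(1, int(round(test_size * idx.size)))
        val[rng.choice(idx, size=k, replace=False)] = True
    return val


# --- k-NN comparator -------------------------------------------------------


def knn_area_auroc(
    ds: ExpressionDataset, folds: SplitFolds, k: int = 5
) -> pd.Series:
    """Per-region AUROC of a k-NN multiclass classifier (fold-averaged).

    A k-nearest-neighbour vote (Euclidean metric, uniform weights; ties
    resolved toward the smallest region id) predicts every test sample's
    region jointly over all regions.  The 1-D prediction vector is
    expanded to a one-hot sample x region matrix and each region's column
    is scored as an AUROC against true membership (midranks absorb the
    massive ties of 0/1 scores).  Returns the per-region AUROC vector,
    averaged over the two fold directions; its mean is the headline k-NN
    number.
    """
    regions = sorted(set(ds.labels))
    per_fold = []
    for train_fold in (0, 1):
        tr = folds.indices(train_fold)
        te = folds.indices(1 - train_fold)
        est = KNeighborsClassifier(n_neighbors=k, weights="uniform", algorithm="auto")
        est.fit(ds.X[tr], ds.labels[tr].astype(str))
        pred = est.predict(ds.X[te])
        onehot = pred[:, None] == np.asarray(regions)[None, :]
        vals = {}
        for jr, r in enumerate(regions):
            truth = (ds.labels[te] == r).astype(int)
            if truth.sum() == 0 or truth.sum() == truth.size:
                logger.info("k-NN: region %s absent from a test fold, skipping", r)
                continue
            vals[r] = auroc(onehot[:, jr].astype(float), truth)
        per_fold.append(pd.Series(vals))
    return pd.concat(per_fold, axis=1).mean(axis=1)
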