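"""Expression dataset container, TSV I/O, filtering rules and the 50/50 split.

A dataset is a sample x gene matrix of nonnegative expression values with a
leaf-region label and a 3-D coordinate per sample.  Filtering follows the
atlas-analysis conventions:

* genes expressed (strictly greater than zero) in fewer than a fraction
  ``min_gene_prevalence`` of samples are dropped (strict "less than" rule);
* then all samples of leaf regions with fewer than ``min_area_samples``
  samples are dropped.

Cross-dataset analyses first harmonize a pair of datasets to the leaf
regions sampled adequately in both and to the shared gene set.  Train/test
uses a 50/50 two-fold split stratified by region; downstream analyses run
both fold directions and report the mean.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .region_ontology import RegionTree

__all__ = [
    "ExpressionDataset",
    "SplitFolds",
    "load_dataset",
    "write_dataset",
    "filter_dataset",
    "average_duplicate_genes",
    "harmonize_pair",
    "stratified_split",
]


class DatasetValidationError(ValueError):
    pass


@dataclass
class ExpressionDataset:
    """Sample x gene expression with per-sample leaf-region labels and coordinates."""

    sample_ids: list[str]
    gene_ids: list[str]
    X: np.ndarray
    labels: np.ndarray
    coords: np.ndarray
    tag: str = "dataset"
    tree: RegionTree | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n, g = self.X.shape
        if len(self.sample_ids) != n:
            raise DatasetValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix rows"
            )
        if len(self.gene_ids) != g:
            raise DatasetValidationError(
                f"{len(self.gene_ids)} gene ids for {g} matrix columns"
            )
        if self.labels.shape != (n,):
            raise DatasetValidationError("one label per sample required")
        if self.coords.shape != (n, 3):
            raise DatasetValidationError("coords must be n_samples x 3")
        if not np.isfinite(self.X).all():
            raise DatasetValidationError("expression matrix contains non-finite values")
        if not np.isfinite(self.coords).all():
            raise DatasetValidationError("coordinates contain non-finite values")
        if self.tree is not None:
            leaves = set(self.tree.leaves)
            bad = sorted({l for l in self.labels if l not in leaves})
            if bad:
                raise DatasetValidationError(
                    f"labels not found among tree leaves: {bad[:10]}"
                )

    # --- basic views -------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def region_counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()

    def subset_samples(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            sample_ids=[self.sample_ids[i] for i in idx],
            X=self.X[idx],
            labels=self.labels[idx],
            coords=self.coords[idx],
        )

    def subset_genes(self, idx) -> "ExpressionDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            gene_ids=[self.gene_ids[i] for i in idx],
            X=self.X[:, idx],
        )

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            sample_ids=list(self.sample_ids),
            gene_ids=list(self.gene_ids),
            X=self.X.copy(),
            labels=self.labels.copy(),
            coords=self.coords.copy(),
        )


@dataclass(frozen=True)
class SplitFolds:
    """Per-sample fold assignment (0/1) for the stratified 50/50 split."""

    assignments: np.ndarray
    seed: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)


# --- I/O -------------------------------------------------------------------


def write_dataset(ds: ExpressionDataset, out_dir) -> None:
    """Write matrix.tsv / labels.tsv / coords.tsv (and tree.json if attached)."""
    os.makedirs(out_dir, exist_ok=True)
    mat = pd.DataFrame(ds.X, index=ds.sample_ids, columns=ds.gene_ids)
    mat.index.name = "sample_id"
    # %.17g round-trips doubles exactly
    mat.to_csv(os.path.join(out_dir, "matrix.tsv"), sep="\t", float_format="%.17g")
    pd.DataFrame({"sample_id": ds.sample_ids, "region_id": ds.labels}).to_csv(
        os.path.join(out_dir, "labels.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {
            "sample_id": ds.sample_ids,
            "x": ds.coords[:, 0],
            "y": ds.coords[:, 1],
            "z": ds.coords[:, 2],
        }
    ).to_csv(os.path.join(out_dir, "coords.tsv"), sep="\t", index=False)
    if ds.tree is not None:
        ds.tree.to_json(os.path.join(out_dir, "tree.json"))


def load_dataset(
    matrix_path,
    labels_path,
    coords_path,
    tree: RegionTree | None = None,
    tag: str = "dataset",
) -> ExpressionDataset:
    """Load and validate a dataset from its three TSV tables.

    Sample ids must agree across the three tables; labels must resolve to
    leaves of ``tree`` when a tree is given.
    """
    try:
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        lab = pd.read_csv(labels_path, sep="\t", dtype=str)
        coo = pd.read_csv(coords_path, sep="\t")
    except pd.errors.ParserError as exc:
        raise DatasetValidationError(f"failed to parse input table: {exc}") from exc
    sample_ids = [str(s) for s in mat.index]
    for name, frame in (("labels", lab), ("coords", coo)):
        ids = [str(s) for s in frame["sample_id"]]
        if ids != sample_ids:
            missing = sorted(set(sample_ids) - set(ids))
            extra = sorted(set(ids) - set(sample_ids))
            raise DatasetValidationError(
                f"sample ids in {name} do not match matrix "
                f"(missing: {missing[:5]}, unexpected: {extra[:5]})"
            )
    labels = lab["region_id"].to_numpy(dtype=object)
    if tree is not None:
        leaves = set(tree.leaves)
        bad = sorted({l for l in labels if l not in leaves})
        if bad:
            raise DatasetValidationError(f"unknown region labels: {bad}")
    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=[str(g) for g in mat.columns],
        X=mat.to_numpy(dtype=float),
        labels=labels,
        coords=coo[["x", "y", "z"]].to_numpy(dtype=float),
        tag=tag,
        tree=tree,
    )


def load_dataset_dir(path, tree: RegionTree | None = None, tag=None) -> ExpressionDataset:
    """Load a dataset written by :func:`write_dataset` from a directory."""
    tree_path = os.path.join(path, "tree.json")
    if tree is None and os.path.exists(tree_path):
        tree = RegionTree.from_json(tree_path)
    return load_dataset(
        os.path.join(path, "matrix.tsv"),
        os.path.join(path, "labels.tsv"),
        os.path.join(path, "coords.tsv"),
        tree=tree,
        tag=tag or os.path.basename(os.path.normpath(path)),
    )


# --- filtering -------------------------------------------------------------


def filter_dataset(
    ds: ExpressionDataset,
    min_gene_prevalence: float = 0.001,
    min_area_samples: int = 5,
) -> ExpressionDataset:
    """Apply the gene-prevalence filter, then the leaf-area size filter.

    A gene is kept when its nonzero count is at least
    ``min_gene_prevalence * n_samples`` (drop rule is strictly-less).  The
    area filter then removes every sample of a region represented fewer
    than ``min_area_samples`` times.  The filters are applied once, in this
    order, and the result is a fixed point of the same filter.
    """
    nonzero = (ds.X > 0).sum(axis=0)
    keep_genes = np.flatnonzero(~(nonzero < min_gene_prevalence * ds.n_samples))
    out = ds.subset_genes(keep_genes)
    counts = out.region_counts()
    small = set(counts.index[counts < min_area_samples])
    keep_samples = np.flatnonzero([l not in small for l in out.labels])
    out = out.subset_samples(keep_samples)
    if out.n_samples == 0 or out.n_genes == 0:
        raise DatasetValidationError("filtering removed the entire dataset")
    return out


def average_duplicate_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Average columns that share a gene id; order follows first occurrence."""
    if len(set(ds.gene_ids)) == len(ds.gene_ids):
        return ds
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, g in enumerate(ds.gene_ids):
        if g not in groups:
            groups[g] = []
            order.append(g)
        groups[g].append(j)
    X = np.column_stack([ds.X[:, groups[g]].mean(axis=1) for g in order])
    return replace(ds, gene_ids=order, X=X)


def harmonize_pair(
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    min_area_samples: int = 5,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict two datasets to shared genes and mutually well-sampled regions.

    Duplicate gene columns are averaged first.  Only leaf regions with at
    least ``min_area_samples`` samples in each dataset survive; the gene
    columns of both outputs are the intersection, in ``ds_a`` order.
    Three-way harmonization is obtained by applying this pairwise.
    """
    a = average_duplicate_genes(ds_a)
    b = average_duplicate_genes(ds_b)
    shared_genes = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared_genes:
        raise DatasetValidationError("datasets share no genes")
    counts_a, counts_b = a.region_counts(), b.region_counts()
    regions = {
        r
        for r in counts_a.index
        if counts_a[r] >= min_area_samples
        and counts_b.get(r, 0) >= min_area_samples
    }
    if not regions:
        raise DatasetValidationError("no region is adequately sampled in both datasets")
    b_pos = {g: j for j, g in enumerate(b.gene_ids)}
    a_pos = {g: j for j, g in enumerate(a.gene_ids)}
    a = a.subset_genes([a_pos[g] for g in shared_genes])
    b = b.subset_genes([b_pos[g] for g in shared_genes])
    a = a.subset_samples(np.flatnonzero([l in regions for l in a.labels]))
    b = b.subset_samples(np.flatnonzero([l in regions for l in b.labels]))
    return a, b


# --- train/test split ------------------------------------------------------


def stratified_split(ds: ExpressionDataset, seed: int) -> SplitFolds:
    """50/50 two-fold split, stratified by region.

    Within each region, samples are shuffled and dealt alternately to the
    folds; an odd count leaves the extra sample in fold 0.  Every region
    must have at least 2 samples.
    """
    counts = ds.region_counts()
    too_small = sorted(counts.index[counts < 2])
    if too_small:
        raise DatasetValidationError(
            f"regions with fewer than 2 samples cannot be split: {too_small}"
        )
    rng = np.random.default_rng(seed)
    assignments = np.empty(ds.n_samples, dtype=int)
    labels = ds.labels
    for region in sorted(counts.index):
        idx = np.flatnonzero(labels == region)
        idx = rng.permutation(idx)
        assignments[idx[0::2]] = 0
        assignments[idx[1::2]] = 1
    return SplitFolds(assignments=assignments, seed=seed)
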