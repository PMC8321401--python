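import numpy as np
import pytest

from atlasrep import AtlasConfig, ExpressionDataset, simulate_paired_atlases
from atlasrep.region_ontology import RegionTree


def make_dataset(X, labels, tag="toy", coords=None, gene_ids=None, tree=None):
    """Assemble a small ExpressionDataset from raw arrays."""
    X = np.asarray(X, dtype=float)
    n, g = X.shape
    if coords is None:
        coords = np.zeros((n, 3))
    return ExpressionDataset(
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(g)],
        X=X,
        labels=np.asarray(labels, dtype=object),
        coords=coords,
        tag=tag,
        tree=tree,
    )


@pytest.fixture
def toy_tree():
    """root -> (a, b); a -> (a1, a2, a3); b -> (b1, b2)."""
    return RegionTree.from_records(
        [
            {"id": "root", "parent_id": None},
            {"id": "a", "parent_id": "root", "major_structure": "a"},
            {"id": "b", "parent_id": "root", "major_structure": "b"},
            {"id": "a1", "parent_id": "a"},
            {"id": "a2", "parent_id": "a"},
            {"id": "a3", "parent_id": "a"},
            {"id": "b1", "parent_id": "b"},
            {"id": "b2", "parent_id": "b"},
        ]
    )


SMALL_CONFIG = dict(
    n_genes=80,
    tree_branching=(2, 3),
    samples_per_leaf=(16, 16),
    grid_shape=(12, 9, 6),
    midline=3.0,
)


@pytest.fixture(scope="session")
def small_pair():
    """A fast low-rank/high-rank pair used across integration tests."""
    cfg = AtlasConfig(seed=7, **SMALL_CONFIG)
    a, b, truth = simulate_paired_atlases(cfg)
    return a, b, truth, cfg
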