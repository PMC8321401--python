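"""Brain-region ontology tree and distances between regions.

Regions are organised as a rooted tree (the atlas naming hierarchy);
classifiable regions are the leaves.  Two notions of distance are used:

* semantic distance — the number of tree edges on the path between two
  nodes (``depth(a) + depth(b) - 2 * depth(lca)``);
* physical distance — the Euclidean distance between the two closest
  voxels of two regions, restricted to one hemisphere by dropping
  coordinates at or beyond a midline value on one axis.

Pairwise classification performance (an AUROC matrix) can be turned into a
region dendrogram: pairs near AUROC 0.5 are indistinguishable and should
merge first, so the clustering dissimilarity is ``|AUROC - 0.5|``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import cdist, squareform

__all__ = ["RegionTree", "path_length", "min_region_distance", "auroc_region_clustering"]

_AXES = {"x": 0, "y": 1, "z": 2}


class UnknownRegionError(KeyError):
    pass


@dataclass
class RegionTree:
    """Rooted region ontology; node records carry id, name, parent, major structure."""

    nodes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        roots = []
        for nid, rec in self.nodes.items():
            parent = rec.get("parent_id")
            if parent is None:
                roots.append(nid)
            else:
                if parent not in self.nodes:
                    raise ValueError(f"node {nid!r} has unknown parent {parent!r}")
                self._children[parent].append(nid)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self._depth: dict[str, int] = {}
        stack = [(self.root, 0)]
        while stack:
            nid, d = stack.pop()
            if nid in self._depth:
                raise ValueError("tree contains a cycle")
            self._depth[nid] = d
            stack.extend((c, d + 1) for c in self._children[nid])
        if len(self._depth) != len(self.nodes):
            raise ValueError("tree is not connected")

    @property
    def leaves(self) -> list[str]:
        return [nid for nid in self.nodes if not self._children[nid]]

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def depth(self, node_id: str) -> int:
        self._check(node_id)
        return self._depth[node_id]

    def parent(self, node_id: str) -> str | None:
        self._check(node_id)
        return self.nodes[node_id].get("parent_id")

    def major_structure(self, node_id: str) -> str | None:
        self._check(node_id)
        return self.nodes[node_id].get("major_structure")

    def is_leaf(self, node_id: str) -> bool:
        self._check(node_id)
        return not self._children[node_id]

    def _check(self, node_id: str) -> None:
        if node_id not in self.nodes:
            raise UnknownRegionError(f"unknown region id: {node_id!r}")

    # --- construction / serialization -------------------------------------

    @classmethod
    def from_records(cls, records) -> "RegionTree":
        """Build from an iterable of {id, name, parent_id, major_structure} dicts."""
        nodes = {}
        for rec in records:
            nid = str(rec["id"])
            if nid in nodes:
                raise ValueError(f"duplicate node id {nid!r}")
            nodes[nid] = {
                "name": rec.get("name", nid),
                "parent_id": None if rec.get("parent_id") is None else str(rec["parent_id"]),
                "major_structure": rec.get("major_structure"),
            }
        return cls(nodes)

    @classmethod
    def from_json(cls, path, field_map: dict | None = None) -> "RegionTree":
        """Load a tree from a JSON node list.

        ``field_map`` translates foreign field names, e.g. an ARA-style
        ontology dump can be read with
        ``{"id": "id", "parent_id": "parent_structure_id", "name": "acronym"}``.
        """
        with open(path) as fh:
            raw = json.load(fh)
        if isinstance(raw, dict) and "nodes" in raw:
            raw = raw["nodes"]
        fm = {"id": "id", "name": "name", "parent_id": "parent_id",
              "major_structure": "major_structure"}
        if field_map:
            fm.update(field_map)
        records = [
            {k: rec.get(src) for k, src in fm.items()}
            for rec in raw
        ]
        return cls.from_records(records)

    def to_json(self, path) -> None:
        records = [
            {"id": nid, "name": rec.get("name", nid), "parent_id": rec.get("parent_id"),
             "major_structure": rec.get("major_structure")}
            for nid, rec in self.nodes.items()
        ]
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)

    # --- semantics ---------------------------------------------------------

    def ancestors(self, node_id: str) -> list[str]:
        """Path from the node up to the root, inclusive."""
        self._check(node_id)
        path = [node_id]
        while (p := self.nodes[path[-1]].get("parent_id")) is not None:
            path.append(p)
        return path

    def lca(self, a: str, b: str) -> str:
        anc = set(self.ancestors(a))
        for node in self.ancestors(b):
            if node in anc:
                return node
        raise ValueError("nodes share no ancestor (malformed tree)")


def path_length(tree: RegionTree, a: str, b: str) -> int:
    """Semantic distance: number of tree edges between nodes ``a`` and ``b``."""
    lca = tree.lca(a, b)
    return tree.depth(a) + tree.depth(b) - 2 * tree.depth(lca)


def min_region_distance(
    coords_a,
    coords_b,
    midline: float | None = None,
    axis: str = "z",
) -> float:
    """Euclidean distance between the two closest points of two regions.

    When ``midline`` is given, points whose coordinate on ``axis`` is not
    strictly below it are discarded first (single-hemisphere restriction);
    an empty surviving set is an error.
    """
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if midline is not None:
        ax = _AXES[axis]
        a = a[a[:, ax] < midline]
        b = b[b[:, ax] < midline]
    if a.size == 0 or b.size == 0:
        raise ValueError("a region has no coordinates on the retained hemisphere")
    return float(cdist(a, b).min())


def auroc_region_clustering(matrix, region_ids=None, method: str = "average"):
    """Cluster regions from a pairwise AUROC matrix.

    Dissimilarity is distance from indistinguishability,
    ``d_ij = |AUROC_ij - 0.5|``: pairs the classifier cannot separate
    (AUROC near 0.5) merge first, perfectly separable pairs (AUROC near 0
    or 1) merge last.  Returns ``(linkage_table, leaf_order)`` where the
    linkage table is the standard (n-1) x 4 agglomerative merge table and
    ``leaf_order`` gives region ids in dendrogram order.
    """
    from .linear_classifiers import AurocMatrix  # local import to avoid a cycle

    if isinstance(matrix, AurocMatrix):
        region_ids = matrix.regions
        matrix = matrix.values
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"AUROC matrix must be square, got shape {m.shape}")
    if region_ids is None:
        region_ids = list(range(m.shape[0]))
    d = np.abs(m - 0.5)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        raise ValueError("AUROC matrix has missing off-diagonal entries")
    z = linkage(squareform(d, checks=False), method=method)
    order = [region_ids[i] for i in leaves_list(z)]
    return z, order
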