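"""UPGMA clustering of constitution groups by target incidence profiles.

Each group is represented by a vector over the union of target genes; the
entry for a gene counts the distinct surviving compound-target edges (from
that group's compounds) supporting the gene, with a binary variant
available. Groups are clustered by average linkage (UPGMA) on pairwise
cosine distances. Conventions the clustering contract fixes explicitly:

* merge height = pair distance / 2 (so the tree is ultrametric);
* ties between candidate merges break toward the lexicographically
  smallest label pair;
* topology equality between trees compares the unordered set of clades
  (leaf partitions per merge), ignoring heights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hct_network import HCTNetwork
from .target_sets import collect_targets


def incidence_matrix(network: HCTNetwork, binary: bool = False) -> pd.DataFrame:
    """Genes x groups matrix of compound-edge support counts."""
    groups = list(network.group_order)
    by_compound = network.edges_by_compound()
    counts: dict[str, dict[str, int]] = {g: {} for g in groups}
    for g in groups:
        for c in network.compounds_of_group(g):
            for e in by_compound.get(c, ()):
                counts[g][e.target_gene] = counts[g].get(e.target_gene, 0) + 1
    genes = sorted({gene for g in groups for gene in counts[g]})
    mat = pd.DataFrame(0, index=genes, columns=groups, dtype=int)
    for g in groups:
        for gene, n in counts[g].items():
            mat.at[gene, g] = n
    if binary:
        mat = (mat > 0).astype(int)
    return mat


def cosine_distance(u, v) -> float:
    """1 - cos(u, v); lies in [0, 1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


def group_distance_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise cosine distances between the group columns of ``mat``."""
    groups = list(mat.columns)
    for g in groups:
        if not mat[g].to_numpy().any():
            raise ValueError(f"group {g!r} has an all-zero incidence profile")
    d = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            d.at[a, b] = d.at[b, a] = cosine_distance(mat[a], mat[b])
    return d


@dataclass
class Dendrogram:
    """Binary merge tree over group labels.

    ``merges`` lists, root-last, tuples ``(left_clade, right_clade, height)``
    where clades are frozensets of leaf labels and ``height`` is the height
    of the new internal node.
    """

    leaves: list[str]
    merges: list[tuple[frozenset, frozenset, float]]

    @property
    def clades(self) -> set[frozenset]:
        """Unordered non-trivial clades; the topology fingerprint."""
        return {l | r for l, r, _ in self.merges}

    def same_topology(self, other: "Dendrogram") -> bool:
        return set(self.leaves) == set(other.leaves) and self.clades == other.clades

    def cophenetic(self, a: str, b: str) -> float:
        """Tree distance between two leaves (2x the merge height)."""
        if a == b:
            return 0.0
        for left, right, h in self.merges:
            if (a in left and b in right) or (a in right and b in left):
                return 2.0 * h
        raise KeyError(f"leaves {a!r}, {b!r} never merge")

    def to_newick(self) -> str:
        node_of: dict[frozenset, str] = {}
        height_of: dict[frozenset, float] = {}
        for leaf in self.leaves:
            node_of[frozenset([leaf])] = leaf
            height_of[frozenset([leaf])] = 0.0
        for left, right, h in self.merges:
            bl = h - height_of[left]
            br = h - height_of[right]
            # deterministic child order: by smallest member label
            kids = sorted(
                [(node_of[left], bl, min(left)), (node_of[right], br, min(right))],
                key=lambda t: t[2],
            )
            label = f"({kids[0][0]}:{kids[0][1]:g},{kids[1][0]}:{kids[1][1]:g})"
            node_of[left | right] = label
            height_of[left | right] = h
        root = frozenset(self.leaves)
        return node_of[root] + ";"


def upgma(dist: pd.DataFrame) -> Dendrogram:
    """Average-linkage hierarchical clustering of a symmetric distance matrix.

    Inter-cluster distance is the size-weighted mean of the member-pair
    distances of the original matrix; the closest pair merges first, ties
    broken by the lexicographically smallest (min-label, max-label) pair.
    """
    labels = list(dist.index)
    if list(dist.columns) != labels or len(labels) < 2:
        raise ValueError("need a square matrix over >= 2 labels")
    arr = dist.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T) or not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    clusters: dict[frozenset, int] = {frozenset([l]): 1 for l in labels}
    d: dict[frozenset, dict[frozenset, float]] = {}
    keys = list(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            val = float(dist.at[next(iter(a)), next(iter(b))])
            d.setdefault(a, {})[b] = val
            d.setdefault(b, {})[a] = val

    merges: list[tuple[frozenset, frozenset, float]] = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in d[a]:
                if b not in clusters:
                    continue
                key = (d[a][b], tuple(sorted((min(a), min(b)))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        height = d[a][b] / 2.0
        left, right = (a, b) if min(a) <= min(b) else (b, a)
        merges.append((left, right, height))
        na, nb = clusters.pop(a), clusters.pop(b)
        new = a | b
        d[new] = {}
        for c in clusters:
            val = (na * d[a][c] + nb * d[b][c]) / (na + nb)
            d[new][c] = val
            d[c][new] = val
        clusters[new] = na + nb
    return Dendrogram(leaves=labels, merges=merges)


def cluster_groups(
    network: HCTNetwork,
    caps: list[int | str],
    binary: bool = False,
) -> tuple[dict[int | str, Dendrogram], bool]:
    """Recluster the groups at each per-compound cap; flag topology stability.

    For each cap the score-filtered network is re-capped, the incidence
    matrix and cosine distances recomputed, and a UPGMA tree built. The
    second return value is True when all trees share the same unordered
    clade set.
    """
    if not caps:
        raise ValueError("caps must be non-empty")
    trees: dict[int | str, Dendrogram] = {}
    for cap in caps:
        net = network.with_cap(cap)
        mat = incidence_matrix(net, binary=binary)
        # drop groups absent from the run? No: an all-zero group is an error
        dist = group_distance_matrix(mat)
        trees[cap] = upgma(dist)
    first = trees[caps[0]]
    same = all(first.same_topology(t) for t in trees.values())
    return trees, same
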