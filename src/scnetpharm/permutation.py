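"""Permutation null for per-group target exclusivity.

The observed statistic per group is the exclusive-target proportion: the
fraction of the group's target genes found in no other group's set. The
null is built by shuffling the compound-target interactions and
recomputing the statistic; the empirical one-sided p-value uses the
standard +1 correction so it can never be exactly zero.

Two shuffle schemes are provided:

``endpoint``
    target endpoints are permuted uniformly across edges; compound degrees
    (pre-collapse) and the global multiset of target endpoints are both
    conserved. This is the least-structured null consistent with
    "shuffling the compound-target interactions".
``full-rewire``
    each edge independently draws a uniform target from the observed
    target universe; only compound degrees are conserved.

Duplicate (compound, target) pairs created by a shuffle are collapsed,
keeping the highest score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hct_network import CompoundTargetEdge, HCTNetwork
from .target_sets import collect_targets, exclusive_proportion


@dataclass
class PermutationResult:
    groups: list[str]
    observed: dict[str, float]
    observed_pooled: float
    null_samples: np.ndarray          # R x len(groups)
    p_values: dict[str, float]
    p_pooled: float
    R: int
    seed: int
    scheme: str


def _collapse(edges: list[CompoundTargetEdge]) -> list[CompoundTargetEdge]:
    best: dict[tuple[str, str], float] = {}
    for e in edges:
        key = (e.compound_id, e.target_gene)
        if key not in best or e.score > best[key]:
            best[key] = e.score
    return sorted(CompoundTargetEdge(c, t, s) for (c, t), s in best.items())


def shuffle_edges(
    network: HCTNetwork, rng: np.random.Generator, scheme: str = "endpoint"
) -> HCTNetwork:
    """Return a copy of the network with shuffled compound-target edges."""
    edges = sorted(network.compound_target_edges)
    if len(edges) < 2:
        return network.with_edges(list(edges))
    if scheme == "endpoint":
        perm = rng.permutation(len(edges))
        shuffled = [
            CompoundTargetEdge(
                edges[i].compound_id,
                edges[int(j)].target_gene,
                edges[int(j)].score,
            )
            for i, j in enumerate(perm)
        ]
    elif scheme == "full-rewire":
        universe = sorted({e.target_gene for e in edges})
        picks = rng.integers(0, len(universe), size=len(edges))
        shuffled = [
            CompoundTargetEdge(e.compound_id, universe[int(k)], e.score)
            for e, k in zip(edges, picks)
        ]
    else:
        raise ValueError(f"unknown shuffle scheme: {scheme!r}")
    return network.with_edges(_collapse(shuffled))


def permutation_test(
    network: HCTNetwork,
    R: int = 999,
    seed: int = 0,
    scheme: str = "endpoint",
) -> PermutationResult:
    """Empirical one-sided test that exclusivity exceeds the shuffle null.

    p = (#{null >= observed} + 1) / (R + 1), per group and for the pooled
    mean across groups.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    collection = collect_targets(network)
    groups = collection.groups
    observed = {g: exclusive_proportion(collection, g) for g in groups}
    obs_pooled = float(np.mean([observed[g] for g in groups]))

    null = np.empty((R, len(groups)), dtype=float)
    for r in range(R):
        shuffled = shuffle_edges(network, rng, scheme=scheme)
        coll_r = collect_targets(shuffled)
        for j, g in enumerate(groups):
            null[r, j] = exclusive_proportion(coll_r, g)

    p_values = {
        g: float((np.sum(null[:, j] >= observed[g]) + 1) / (R + 1))
        for j, g in enumerate(groups)
    }
    null_pooled = null.mean(axis=1)
    p_pooled = float((np.sum(null_pooled >= obs_pooled) + 1) / (R + 1))
    return PermutationResult(
        groups=groups,
        observed=observed,
        observed_pooled=obs_pooled,
        null_samples=null,
        p_values=p_values,
        p_pooled=p_pooled,
        R=R,
        seed=seed,
        scheme=scheme,
    )
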