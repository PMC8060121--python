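"""Per-group target gene sets and their overlap structure.

Each constitution type's target set is the union of target genes reached
through any compound of any herb in that group. Overlap structure is
summarised as exact Venn-region counts (one count per non-empty membership
pattern), pairwise shared counts, and per-group exclusive counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .hct_network import HCTNetwork

logger = logging.getLogger(__name__)


@dataclass
class TargetSetCollection:
    groups: list[str]
    sets: dict[str, set[str]]
    herb_counts: dict[str, int]


@dataclass
class OverlapTable:
    groups: list[str]
    #: membership pattern (sorted tuple of group labels) -> gene count
    region_counts: dict[tuple[str, ...], int]
    pairwise_shared: dict[tuple[str, str], int]
    exclusive: dict[str, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def collect_targets(network: HCTNetwork) -> TargetSetCollection:
    """Union of surviving target genes per constitution group."""
    groups = list(network.group_order)
    by_compound = network.edges_by_compound()
    sets: dict[str, set[str]] = {}
    herb_counts: dict[str, int] = {}
    for g in groups:
        members = [h for h, rec in network.herbs.items() if rec.group == g]
        herb_counts[g] = len(members)
        if not members:
            logger.warning("group %s has no herbs; target set is empty", g)
        genes: set[str] = set()
        for c in network.compounds_of_group(g):
            genes.update(e.target_gene for e in by_compound.get(c, ()))
        sets[g] = genes
    return TargetSetCollection(groups=groups, sets=sets, herb_counts=herb_counts)


def overlap_table(collection: TargetSetCollection) -> OverlapTable:
    """Exact Venn-region counts by per-gene membership tally."""
    groups = collection.groups
    if len(groups) < 2:
        raise ValueError("overlap_table needs at least 2 groups")
    universe = set().union(*collection.sets.values()) if collection.sets else set()
    region_counts: dict[tuple[str, ...], int] = {}
    for gene in universe:
        pattern = tuple(g for g in groups if gene in collection.sets[g])
        region_counts[pattern] = region_counts.get(pattern, 0) + 1
    pairwise = {
        (a, b): sum(
            n for pat, n in region_counts.items() if a in pat and b in pat
        )
        for a, b in combinations(groups, 2)
    }
    exclusive = {
        g: region_counts.get((g,), 0) for g in groups
    }
    return OverlapTable(
        groups=groups,
        region_counts=region_counts,
        pairwise_shared=pairwise,
        exclusive=exclusive,
    )


def exclusive_proportion(collection: TargetSetCollection, group: str) -> float:
    """Fraction of the group's genes found in no other group's set.

    Defined as 0 for an empty set (keeps the permutation statistic finite).
    """
    if group not in collection.sets:
        raise KeyError(f"unknown group: {group!r}")
    own = collection.sets[group]
    if not own:
        return 0.0
    others = set().union(
        *(s for g, s in collection.sets.items() if g != group)
    ) if len(collection.sets) > 1 else set()
    return len(own - others) / len(own)
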