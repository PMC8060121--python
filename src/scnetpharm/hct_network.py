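"""Herb-compound-target tripartite network: loading, validation, filtering.

The network links medicinal herbs (stratified into constitution-type groups)
to their chemical constituents, and constituents to predicted target genes.
Compound-target edges carry a 0-1000 confidence score; edges are kept only
when the score strictly exceeds a threshold (default 700), and each compound
is limited to a maximum number of surviving target edges (the "cap",
default 10) to prevent promiscuous compounds from dominating the analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("SE", "SY", "TE", "TY")

#: sentinel accepted wherever a per-compound cap is expected
UNLIMITED = "unlimited"


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class HerbRecord:
    herb_id: str
    group: str
    local_name: str
    latin_name: str


@dataclass(frozen=True, order=True)
class CompoundTargetEdge:
    compound_id: str
    target_gene: str
    score: float


@dataclass
class HCTNetwork:
    """Tripartite herb-compound-target network after score/cap filtering.

    ``raw_compound_target_edges`` holds the score-filtered but un-capped
    edges so the cap can be re-applied (``with_cap``) without re-reading
    the input tables — needed for the cap-robustness analysis.
    """

    herbs: dict[str, HerbRecord]
    herb_compound_edges: set[tuple[str, str]]
    compound_target_edges: list[CompoundTargetEdge]
    raw_compound_target_edges: list[CompoundTargetEdge]
    score_threshold: float
    cap: int | str
    group_order: tuple[str, ...] = DEFAULT_GROUPS
    orphan_compounds: set[str] = field(default_factory=set)

    @property
    def compounds(self) -> set[str]:
        return {c for _, c in self.herb_compound_edges}

    @property
    def targets(self) -> set[str]:
        return {e.target_gene for e in self.compound_target_edges}

    def compounds_of_group(self, group: str) -> set[str]:
        members = {h for h, rec in self.herbs.items() if rec.group == group}
        return {c for h, c in self.herb_compound_edges if h in members}

    def edges_by_compound(self) -> dict[str, list[CompoundTargetEdge]]:
        by_c: dict[str, list[CompoundTargetEdge]] = {}
        for e in self.compound_target_edges:
            by_c.setdefault(e.compound_id, []).append(e)
        return by_c

    def with_cap(self, cap: int | str) -> "HCTNetwork":
        """Re-apply a per-compound cap to the score-filtered edge list."""
        capped = apply_cap(self.raw_compound_target_edges, cap)
        surviving = {e.compound_id for e in capped}
        orphans = self.compounds - surviving
        return replace(
            self,
            compound_target_edges=capped,
            cap=cap,
            orphan_compounds=orphans,
        )

    def with_edges(self, edges: list[CompoundTargetEdge]) -> "HCTNetwork":
        surviving = {e.compound_id for e in edges}
        return replace(
            self,
            compound_target_edges=list(edges),
            raw_compound_target_edges=list(edges),
            orphan_compounds=self.compounds - surviving,
        )

    # -- JSON round-trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "score_threshold": self.score_threshold,
            "cap": self.cap,
            "group_order": list(self.group_order),
            "herbs": [vars(h) for h in sorted(self.herbs.values(), key=lambda h: h.herb_id)],
            "herb_compound_edges": sorted(list(e) for e in self.herb_compound_edges),
            "compound_target_edges": [
                {"compound_id": e.compound_id, "target_gene": e.target_gene, "score": e.score}
                for e in sorted(self.compound_target_edges)
            ],
            "raw_compound_target_edges": [
                {"compound_id": e.compound_id, "target_gene": e.target_gene, "score": e.score}
                for e in sorted(self.raw_compound_target_edges)
            ],
            "orphan_compounds": sorted(self.orphan_compounds),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "HCTNetwork":
        return cls(
            herbs={h["herb_id"]: HerbRecord(**h) for h in d["herbs"]},
            herb_compound_edges={tuple(e) for e in d["herb_compound_edges"]},
            compound_target_edges=[CompoundTargetEdge(**e) for e in d["compound_target_edges"]],
            raw_compound_target_edges=[
                CompoundTargetEdge(**e) for e in d["raw_compound_target_edges"]
            ],
            score_threshold=d["score_threshold"],
            cap=d["cap"],
            group_order=tuple(d["group_order"]),
            orphan_compounds=set(d["orphan_compounds"]),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "HCTNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


def packaged_herb_catalog() -> Path:
    """Path to the bundled 28-herb catalog (8 SE, 8 SY, 8 TE, 4 TY)."""
    return Path(str(resources.files("scnetpharm") / "data" / "herb_catalog.tsv"))


def load_herb_catalog(
    path: str | Path, groups: tuple[str, ...] = DEFAULT_GROUPS
) -> list[HerbRecord]:
    """Load the herb catalog TSV (herb_id, group, local_name, latin_name).

    Raises :class:`ValidationError` on duplicate herb ids or group labels
    outside the configured label set.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = ["herb_id", "group", "local_name", "latin_name"]
    if list(df.columns) != expected:
        raise ValidationError(f"herb catalog columns must be {expected}, got {list(df.columns)}")
    if df["herb_id"].duplicated().any():
        dupes = sorted(df.loc[df["herb_id"].duplicated(), "herb_id"])
        raise ValidationError(f"duplicate herb_id(s): {dupes}")
    unknown = sorted(set(df["group"]) - set(groups))
    if unknown:
        raise ValidationError(f"unknown group label(s): {unknown}; configured: {list(groups)}")
    return [HerbRecord(*row) for row in df.itertuples(index=False)]


def _cap_as_int(cap: int | str) -> int | None:
    if cap == UNLIMITED or cap is None:
        return None
    cap = int(cap)
    if cap < 1:
        raise ValueError(f"cap must be a positive integer or 'unlimited', got {cap}")
    return cap


def apply_cap(
    edges: list[CompoundTargetEdge], cap: int | str
) -> list[CompoundTargetEdge]:
    """Keep, per compound, the ``cap`` highest-scoring target edges.

    Ties at the score cutoff are broken by lexicographically ascending
    target gene symbol, so the result is deterministic.
    """
    n = _cap_as_int(cap)
    if n is None:
        return sorted(edges)
    by_c: dict[str, list[CompoundTargetEdge]] = {}
    for e in edges:
        by_c.setdefault(e.compound_id, []).append(e)
    kept: list[CompoundTargetEdge] = []
    for cid in sorted(by_c):
        ranked = sorted(by_c[cid], key=lambda e: (-e.score, e.target_gene))
        kept.extend(ranked[:n])
    return sorted(kept)


def build_network(
    herbs: list[HerbRecord],
    herb_compound_path: str | Path,
    compound_target_path: str | Path,
    score_threshold: float = 700.0,
    cap: int | str = 10,
    group_order: tuple[str, ...] = DEFAULT_GROUPS,
) -> HCTNetwork:
    """Assemble the filtered tripartite network from edge tables.

    Compound-target edges survive only with ``score > score_threshold``
    (strict); then each compound keeps at most ``cap`` edges (highest score
    first, ties by gene symbol). Compounds left without targets stay in the
    network as flagged orphan nodes. Gene symbols are upper-cased on load.
    """
    if not 0 <= score_threshold <= 1000:
        raise ValueError("score_threshold must lie in [0, 1000]")
    herb_ids = {h.herb_id for h in herbs}

    hc = pd.read_csv(herb_compound_path, sep="\t", comment="#", dtype=str)
    if list(hc.columns) != ["herb_id", "compound_id"]:
        raise ValidationError(f"herb_compound columns must be [herb_id, compound_id], got {list(hc.columns)}")
    unknown_herbs = sorted(set(hc["herb_id"]) - herb_ids)
    if unknown_herbs:
        raise ValidationError(f"herb_compound edges reference unknown herb(s): {unknown_herbs}")
    hc_edges = {(r.herb_id, r.compound_id) for r in hc.itertuples(index=False)}

    ct = pd.read_csv(compound_target_path, sep="\t", comment="#", dtype=str)
    if list(ct.columns) != ["compound_id", "target_gene", "score"]:
        raise ValidationError(
            f"compound_target columns must be [compound_id, target_gene, score], got {list(ct.columns)}"
        )
    try:
        scores = ct["score"].astype(float)
    except ValueError as exc:
        raise ValidationError(f"malformed score value in {compound_target_path}: {exc}") from exc
    if ((scores < 0) | (scores > 1000)).any():
        raise ValidationError("compound-target scores must lie in [0, 1000]")

    all_edges = [
        CompoundTargetEdge(cid, gene.upper(), s)
        for cid, gene, s in zip(ct["compound_id"], ct["target_gene"], scores)
    ]
    seen: dict[tuple[str, str], CompoundTargetEdge] = {}
    for e in all_edges:
        key = (e.compound_id, e.target_gene)
        if key in seen:
            raise ValidationError(f"duplicate compound-target pair: {key}")
        seen[key] = e

    filtered = [e for e in all_edges if e.score > score_threshold]
    logger.info(
        "compound-target edges: %d read, %d pass score > %s",
        len(all_edges), len(filtered), score_threshold,
    )
    capped = apply_cap(filtered, cap)
    logger.info("after per-compound cap %s: %d edges", cap, len(capped))

    compounds = {c for _, c in hc_edges}
    surviving = {e.compound_id for e in capped}
    unknown_compounds = sorted({e.compound_id for e in all_edges} - compounds)
    if unknown_compounds:
        raise ValidationError(
            f"compound_target edges reference compound(s) absent from herb_compound: {unknown_compounds}"
        )
    orphans = compounds - surviving
    if orphans:
        logger.info("%d compounds retained with no surviving targets", len(orphans))

    return HCTNetwork(
        herbs={h.herb_id: h for h in herbs},
        herb_compound_edges=hc_edges,
        compound_target_edges=capped,
        raw_compound_target_edges=sorted(filtered),
        score_threshold=score_threshold,
        cap=cap,
        group_order=group_order,
        orphan_compounds=orphans,
    )
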