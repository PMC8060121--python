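"""Top-scored disease extraction and ICD-10 chapter frequency profiles.

Gene-disease associations carry a 0-1 curation-confidence score. For each
target gene the k highest-scored diseases (default 3) are pooled over a
group's gene set — with multiplicity, so a disease contributed by several
genes counts once per gene — then binned into ICD-10 chapters and
normalised to a frequency profile. Diseases missing from the chapter map
are tallied separately and excluded from the proportions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .target_sets import TargetSetCollection

logger = logging.getLogger(__name__)

GDA_COLUMNS = ["gene", "disease_id", "disease_name", "score"]


@dataclass
class DiseaseProfile:
    group: str
    #: ICD-10 chapter label -> proportion among classified instances
    chapter_frequencies: dict[str, float]
    total_instances: int
    unmapped_instances: int


def read_gene_disease_table(path: str | Path) -> pd.DataFrame:
    """Gene-disease TSV (gene, disease_id, disease_name, score in [0,1])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"score": float}).astype(
        {"gene": str, "disease_id": str, "disease_name": str}
    )
    if list(df.columns) != GDA_COLUMNS:
        raise ValueError(f"gene-disease table columns must be {GDA_COLUMNS}, got {list(df.columns)}")
    if ((df["score"] < 0) | (df["score"] > 1)).any():
        raise ValueError("gene-disease scores must lie in [0, 1]")
    if df.duplicated(["gene", "disease_id"]).any():
        raise ValueError("duplicate (gene, disease_id) pairs in gene-disease table")
    df["gene"] = df["gene"].str.upper()
    return df


def read_icd_map(path: str | Path) -> dict[str, str]:
    """disease_id -> ICD-10 chapter label."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != ["disease_id", "chapter"]:
        raise ValueError(f"ICD map columns must be [disease_id, chapter], got {list(df.columns)}")
    return dict(zip(df["disease_id"], df["chapter"]))


def top_k_diseases(records: pd.DataFrame, k: int = 3) -> list[str]:
    """The k highest-scored disease ids for one gene.

    Ties at the cutoff break by lexicographically ascending disease_id;
    a gene with fewer than k diseases returns them all.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = records.sort_values(
        ["score", "disease_id"], ascending=[False, True], kind="mergesort"
    )
    return list(ranked["disease_id"].head(k))


def disease_profile(
    collection: TargetSetCollection,
    records: pd.DataFrame,
    icd_map: dict[str, str],
    k: int = 3,
    unique_diseases: bool = False,
) -> dict[str, DiseaseProfile]:
    """ICD-10 chapter frequency profile per group.

    ``unique_diseases=True`` switches from instance counting to set
    counting (each disease at most once per group).
    """
    by_gene = dict(tuple(records.groupby("gene", sort=True)))
    profiles: dict[str, DiseaseProfile] = {}
    for group in collection.groups:
        instances: list[str] = []
        for gene in sorted(collection.sets[group]):
            recs = by_gene.get(gene)
            if recs is None:
                continue
            instances.extend(top_k_diseases(recs, k=k))
        if unique_diseases:
            instances = sorted(set(instances))
        chapters = [icd_map.get(d) for d in instances]
        unmapped = sum(1 for c in chapters if c is None)
        if unmapped:
            logger.warning("group %s: %d disease instances missing from ICD map", group, unmapped)
        counts: dict[str, int] = {}
        for c in chapters:
            if c is not None:
                counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        freqs = {c: n / total for c, n in sorted(counts.items())} if total else {}
        profiles[group] = DiseaseProfile(
            group=group,
            chapter_frequencies=freqs,
            total_instances=len(instances),
            unmapped_instances=unmapped,
        )
    return profiles
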