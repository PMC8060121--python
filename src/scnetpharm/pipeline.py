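"""End-to-end orchestration: network construction, then functional analysis.

Stages communicate only through files in the output directory, so every
intermediate is auditable. The run is deterministic under a fixed seed and
fixed inputs; a machine-readable ``summary.json`` collects the headline
quantities (per-group target counts, pairwise shared counts, permutation
p-values, significant-term counts, cap-robustness flag).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, disease_profiles, enrichment, hct_network, permutation
from . import category_profiles as catprof
from . import target_sets

logger = logging.getLogger(__name__)

DEFAULT_CAPS = [10, 50, 100, 500, hct_network.UNLIMITED]


@dataclass
class PipelineConfig:
    herb_catalog: str
    herb_compound: str
    compound_target: str
    go_slim_gmt: str
    first_level_gmt: str
    gda: str
    icd_map: str
    out_dir: str
    score_threshold: float = 700.0
    cap: int | str = 10
    caps: list = field(default_factory=lambda: list(DEFAULT_CAPS))
    R: int = 999
    R_cal: int = 200
    alpha: float = 0.05
    k_diseases: int = 3
    seed: int = 0
    binary_incidence: bool = False
    shuffle_scheme: str = "endpoint"
    method: str = "fisher"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    @classmethod
    def for_bundle(cls, bundle_dir: str | Path, out_dir: str | Path, **kw) -> "PipelineConfig":
        """Config pointing at a directory written by the synthetic generator."""
        b = Path(bundle_dir)
        return cls(
            herb_catalog=str(b / "herb_catalog.tsv"),
            herb_compound=str(b / "herb_compound.tsv"),
            compound_target=str(b / "compound_target.tsv"),
            go_slim_gmt=str(b / "go_slim.gmt"),
            first_level_gmt=str(b / "first_level.gmt"),
            gda=str(b / "gda.tsv"),
            icd_map=str(b / "icd_map.tsv"),
            out_dir=str(out_dir),
            **kw,
        )


def _stage(name):
    logger.info("stage: %s", name)


def run_all(config: PipelineConfig) -> dict:
    """Run every stage; returns (and writes) the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _stage("network construction")
    herbs = hct_network.load_herb_catalog(config.herb_catalog)
    network = hct_network.build_network(
        herbs,
        config.herb_compound,
        config.compound_target,
        score_threshold=config.score_threshold,
        cap=config.cap,
    )
    network.to_json(out / "network.json")

    _stage("target collection")
    collection = target_sets.collect_targets(network)
    pd.DataFrame(
        [(g, gene) for g in collection.groups for gene in sorted(collection.sets[g])],
        columns=["group", "gene"],
    ).to_csv(out / "targets.tsv", sep="\t", index=False)

    _stage("overlap analysis")
    table = target_sets.overlap_table(collection)
    with open(out / "overlaps.tsv", "w") as fh:
        fh.write("kind\tmembers\tcount\n")
        for pat in sorted(table.region_counts):
            fh.write(f"region\t{'+'.join(pat)}\t{table.region_counts[pat]}\n")
        for (a, b), n in sorted(table.pairwise_shared.items()):
            fh.write(f"shared\t{a}+{b}\t{n}\n")
        for g, n in table.exclusive.items():
            fh.write(f"exclusive\t{g}\t{n}\n")

    _stage("clustering (cap robustness)")
    trees, stable = clustering.cluster_groups(
        network, config.caps, binary=config.binary_incidence
    )
    for cap, tree in trees.items():
        (out / f"dendrogram_cap_{cap}.nwk").write_text(tree.to_newick() + "\n")
    mat = clustering.incidence_matrix(network, binary=config.binary_incidence)
    mat.to_csv(out / "incidence.tsv", sep="\t")
    clustering.group_distance_matrix(mat).to_csv(out / "cosine_dist.tsv", sep="\t")

    _stage("permutation test")
    perm = permutation.permutation_test(
        network, R=config.R, seed=config.seed, scheme=config.shuffle_scheme
    )
    with open(out / "perm.tsv", "w") as fh:
        fh.write("group\tobserved\tp\tR\tseed\n")
        for g in perm.groups:
            fh.write(f"{g}\t{perm.observed[g]:.6f}\t{perm.p_values[g]:.6f}\t{perm.R}\t{perm.seed}\n")
        fh.write(f"pooled\t{perm.observed_pooled:.6f}\t{perm.p_pooled:.6f}\t{perm.R}\t{perm.seed}\n")

    _stage("overrepresentation")
    library = enrichment.read_gmt(config.go_slim_gmt)
    sig_counts: dict[str, int] = {}
    for g in collection.groups:
        rows = enrichment.overrepresentation(
            library,
            collection.sets[g],
            alpha=config.alpha,
            R_cal=config.R_cal,
            seed=config.seed,
            method=config.method,
        )
        sig_counts[g] = sum(r.significant for r in rows)
        pd.DataFrame([vars(r) for r in rows]).to_csv(
            out / f"enrich_{g}.tsv", sep="\t", index=False
        )

    _stage("category profiles")
    first_level = enrichment.read_gmt(config.first_level_gmt)
    profiles = [
        catprof.category_profile(first_level, collection.sets[g], g)
        for g in collection.groups
    ]
    pd.DataFrame(
        {p.group: p.proportions for p in profiles},
        index=profiles[0].categories,
    ).to_csv(out / "category_profiles.tsv", sep="\t")
    dist = catprof.profile_distances(profiles)
    dist.to_csv(out / "profile_dist.tsv", sep="\t")

    _stage("disease profiles")
    gda = disease_profiles.read_gene_disease_table(config.gda)
    icd = disease_profiles.read_icd_map(config.icd_map)
    dprofiles = disease_profiles.disease_profile(
        collection, gda, icd, k=config.k_diseases
    )
    rows = [
        (g, ch, f)
        for g, prof in dprofiles.items()
        for ch, f in prof.chapter_frequencies.items()
    ]
    pd.DataFrame(rows, columns=["group", "chapter", "frequency"]).to_csv(
        out / "disease_profiles.tsv", sep="\t", index=False
    )

    summary = {
        "n_herbs": len(network.herbs),
        "n_compounds": len(network.compounds),
        "n_edges": len(network.compound_target_edges),
        "target_counts": {g: len(collection.sets[g]) for g in collection.groups},
        "pairwise_shared": {f"{a}-{b}": n for (a, b), n in sorted(table.pairwise_shared.items())},
        "exclusive_counts": dict(table.exclusive),
        "exclusive_proportions": {g: perm.observed[g] for g in perm.groups},
        "permutation_p": {g: perm.p_values[g] for g in perm.groups},
        "permutation_p_pooled": perm.p_pooled,
        "significant_terms": sig_counts,
        "topology_stable_across_caps": bool(stable),
        "profile_distance_max": float(dist.to_numpy().max()),
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
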