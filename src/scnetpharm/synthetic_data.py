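"""Synthetic input bundles with planted, recoverable structure.

The real study consumed three web resources: a compound-target prediction
database (scored herb ingredient -> gene interactions), a GO-Slim
annotation service, and a curated gene-disease association table. None can
be bundled, so this module fabricates statistically controllable stand-ins
for every pipeline input:

* herb catalog, herb-compound and scored compound-target edge tables with
  per-group target-gene pools whose pairwise overlaps are configured
  (e.g. a high SE-SY overlap and a nearly isolated TY pool);
* a two-tier annotation library in GMT format: a handful of first-level
  categories covering the gene universe (with a configurable per-group
  category skew) and a set of specific terms, one of which per group is
  planted to be enriched in that group's exclusive genes;
* a gene-disease score table plus an ICD-10 chapter map, with a per-group
  chapter skew strong enough that top-3 extraction recovers it.

A ground-truth manifest (JSON) records everything planted so tests can use
generator bookkeeping as the oracle. A fixed seed yields a byte-identical
bundle.

Planted-pool recovery contract: with ``score_threshold=700`` and a cap of
at least ``max_targets_per_compound`` (or ``unlimited``), ``collect_targets``
on the generated bundle returns exactly the planted pools — every pool
gene is guaranteed a surviving supra-threshold edge, and sub-threshold
noise edges never survive.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

FIRST_LEVEL_CATEGORIES = [
    ("FL01", "cellular process"),
    ("FL02", "metabolic process"),
    ("FL03", "biological regulation"),
    ("FL04", "response to stimulus"),
    ("FL05", "signaling"),
    ("FL06", "developmental process"),
    ("FL07", "localization"),
    ("FL08", "immune system process"),
]

ICD_CHAPTERS = [
    "Certain infectious and parasitic diseases",
    "Neoplasms",
    "Endocrine, nutritional and metabolic diseases",
    "Mental, behavioural and neurodevelopmental disorders",
    "Diseases of the nervous system",
    "Diseases of the circulatory system",
    "Diseases of the respiratory system",
    "Diseases of the digestive system",
    "Diseases of the genitourinary system",
    "Congenital malformations, deformations and chromosomal abnormalities",
]


class InfeasibleConfig(ValueError):
    """Raised when requested overlaps exceed the configured pool sizes."""


@dataclass
class SyntheticConfig:
    """Defaults emulate the study's scale and qualitative structure.

    28 herbs split 8/8/8/4 over SE/SY/TE/TY; per-group target pools sized
    in the same order as the study's real target counts (SE largest, TY
    smallest, scaled to desk size); SE-SY strongly overlapping and TY
    nearly disjoint from everything, mirroring the reported overlap
    pattern; per-group annotation and disease-chapter skews matching the
    study's qualitative findings (e.g. TY genes concentrated in metabolic
    process; TE diseases in the endocrine/metabolic chapter).
    """

    seed: int = 0
    herb_counts: dict = field(
        default_factory=lambda: {"SE": 8, "SY": 8, "TE": 8, "TY": 4}
    )
    lambda_compounds: float = 10.0      # mean compounds per herb
    shared_compound_prob: float = 0.15  # within-group compound reuse
    lambda_targets: float = 5.0         # mean pool targets per compound
    max_targets_per_compound: int = 10  # hard limit before any capping
    frac_high_score: float = 0.6        # mass of scores above 700
    noise_edge_rate: float = 1.0        # mean sub-threshold edges/compound
    pool_sizes: dict = field(
        default_factory=lambda: {"SE": 120, "SY": 90, "TE": 70, "TY": 40}
    )
    #: pairwise overlap fractions of min(pool sizes); keys "A-B"
    overlap: dict = field(
        default_factory=lambda: {
            "SE-SY": 0.30, "SE-TE": 0.10, "SY-TE": 0.10,
            "SE-TY": 0.05, "SY-TY": 0.0, "TE-TY": 0.02,
        }
    )
    null_model: bool = False  # iid targets from a common pool; nothing planted
    universe_size: int = 1500
    multi_category_prob: float = 0.2
    #: group -> first-level category id given preferentially to exclusive genes
    category_skew: dict = field(
        default_factory=lambda: {"SE": "FL02", "SY": "FL01", "TE": "FL03", "TY": "FL02"}
    )
    category_skew_strength: float = 0.6
    n_terms: int = 60
    term_size_range: tuple = (10, 60)
    planted_term_size: int = 15
    planted_term_overlap: float = 0.8  # fraction of term genes from the group pool
    diseases_per_gene: float = 4.0
    n_diseases: int = 120
    chapter_skew: dict = field(
        default_factory=lambda: {
            "SE": "Diseases of the digestive system",
            "SY": "Diseases of the nervous system",
            "TE": "Endocrine, nutritional and metabolic diseases",
            "TY": "Congenital malformations, deformations and chromosomal abnormalities",
        }
    )
    chapter_skew_strength: float = 0.6

    @property
    def groups(self) -> list[str]:
        return list(self.herb_counts)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key, val in self.overlap.items():
            if not 0 <= val <= 1:
                raise InfeasibleConfig(f"overlap[{key}] = {val} outside [0,1]")
        for p in (self.shared_compound_prob, self.frac_high_score,
                  self.multi_category_prob, self.category_skew_strength,
                  self.chapter_skew_strength, self.planted_term_overlap):
            if not 0 <= p <= 1:
                raise InfeasibleConfig(f"probability {p} outside [0,1]")
        self._plan_pools()  # raises on infeasible overlap demands

    def _overlap_frac(self, a: str, b: str) -> float:
        return float(self.overlap.get(f"{a}-{b}", self.overlap.get(f"{b}-{a}", 0.0)))

    def _plan_pools(self) -> dict:
        """Shared-block and exclusive-block sizes per group; checks feasibility."""
        groups = self.groups
        shared: dict[tuple[str, str], int] = {}
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                n = round(self._overlap_frac(a, b)
                          * min(self.pool_sizes[a], self.pool_sizes[b]))
                shared[(a, b)] = int(n)
        exclusive: dict[str, int] = {}
        for g in groups:
            taken = sum(n for pair, n in shared.items() if g in pair)
            excl = self.pool_sizes[g] - taken
            if excl < 0:
                raise InfeasibleConfig(
                    f"group {g}: overlap demands ({taken}) exceed pool size "
                    f"({self.pool_sizes[g]})"
                )
            exclusive[g] = excl
        return {"shared": shared, "exclusive": exclusive}


def _shifted_poisson(rng: np.random.Generator, lam: float, size: int = 1) -> np.ndarray:
    """1 + Poisson(lam - 1): guaranteed >= 1 with mean exactly lam."""
    if lam < 1:
        raise ValueError("mean must be >= 1")
    return 1 + rng.poisson(lam - 1.0, size=size)


def _score_high(rng: np.random.Generator) -> float:
    return 700.0 + 300.0 * rng.beta(2, 2)


def _score_low(rng: np.random.Generator) -> float:
    return 700.0 * rng.beta(2, 2)


def generate(config: SyntheticConfig, out_dir: str | Path, seed: int | None = None) -> dict:
    """Write the full input bundle and return the ground-truth manifest.

    ``seed`` overrides ``config.seed`` when given. Files written:
    herb_catalog.tsv, herb_compound.tsv, compound_target.tsv, go_slim.gmt,
    first_level.gmt, gda.tsv, icd_map.tsv, manifest.json.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = config.groups

    universe = [f"G{i:05d}" for i in range(1, config.universe_size + 1)]

    # ---- per-group target pools with planted pairwise overlaps ----------
    pools: dict[str, set[str]] = {g: set() for g in groups}
    cursor = 0
    if config.null_model:
        common_size = max(config.pool_sizes.values())
        common = universe[:common_size]
        cursor = common_size
        for g in groups:
            pools[g] = set(common)
        plan = {"shared": {}, "exclusive": {}}
    else:
        plan = config._plan_pools()
        for (a, b), n in sorted(plan["shared"].items()):
            block = universe[cursor:cursor + n]
            cursor += n
            pools[a].update(block)
            pools[b].update(block)
        for g in groups:
            n = plan["exclusive"][g]
            block = universe[cursor:cursor + n]
            cursor += n
            pools[g].update(block)
    if cursor > config.universe_size:
        raise InfeasibleConfig("universe too small for the configured pools")

    exclusive_genes = {
        g: pools[g] - set().union(*(pools[h] for h in groups if h != g))
        if len(groups) > 1 else set(pools[g])
        for g in groups
    }

    # ---- herbs and compounds -------------------------------------------
    herb_rows: list[tuple[str, str, str, str]] = []
    herb_group: dict[str, str] = {}
    for g in groups:
        for i in range(1, config.herb_counts[g] + 1):
            hid = f"{g}-H{i:02d}"
            herb_rows.append((hid, g, f"Herb {g}-{i}", f"Radix synthetica {g.lower()}-{i}"))
            herb_group[hid] = g

    hc_edges: list[tuple[str, str]] = []
    compound_group: dict[str, str] = {}
    group_compounds: dict[str, list[str]] = {g: [] for g in groups}
    counter = 0
    for hid, g, _, _ in herb_rows:
        n_c = int(_shifted_poisson(rng, config.lambda_compounds)[0])
        for _ in range(n_c):
            if group_compounds[g] and rng.random() < config.shared_compound_prob:
                cid = group_compounds[g][int(rng.integers(len(group_compounds[g])))]
            else:
                counter += 1
                cid = f"C{counter:05d}"
                compound_group[cid] = g
                group_compounds[g].append(cid)
            hc_edges.append((hid, cid))
    hc_edges = sorted(set(hc_edges))

    # ---- scored compound-target edges ----------------------------------
    edges: dict[tuple[str, str], float] = {}
    for cid in sorted(compound_group):
        g = compound_group[cid]
        pool = sorted(pools[g])
        n_t = min(int(_shifted_poisson(rng, config.lambda_targets)[0]),
                  config.max_targets_per_compound)
        if config.null_model:
            picks = {pool[int(i)] for i in rng.integers(len(pool), size=n_t)}
        else:
            n_t = min(n_t, len(pool))
            picks = {pool[int(i)] for i in rng.choice(len(pool), size=n_t, replace=False)}
        for gene in sorted(picks):
            score = _score_high(rng) if rng.random() < config.frac_high_score \
                else _score_low(rng)
            edges[(cid, gene)] = score
        n_noise = int(rng.poisson(config.noise_edge_rate))
        for _ in range(n_noise):
            gene = universe[int(rng.integers(config.universe_size))]
            if (cid, gene) not in edges:
                edges[(cid, gene)] = _score_low(rng)

    if not config.null_model:
        # coverage guarantee: every pool gene gets >= 1 supra-threshold edge
        high_count = {cid: 0 for cid in compound_group}
        covered: dict[str, set[str]] = {g: set() for g in groups}
        for (cid, gene), s in edges.items():
            if s > 700:
                high_count[cid] += 1
                covered[compound_group[cid]].add(gene)
        for g in groups:
            for gene in sorted(pools[g] - covered[g]):
                slots = [c for c in sorted(group_compounds[g])
                         if high_count[c] < config.max_targets_per_compound]
                if not slots:
                    counter += 1
                    cid = f"C{counter:05d}"
                    compound_group[cid] = g
                    group_compounds[g].append(cid)
                    herb = sorted(h for h, gg in herb_group.items() if gg == g)[0]
                    hc_edges.append((herb, cid))
                    high_count[cid] = 0
                    slots = [cid]
                cid = min(slots, key=lambda c: (high_count[c], c))
                edges[(cid, gene)] = _score_high(rng)
                high_count[cid] += 1
        hc_edges = sorted(set(hc_edges))

    # ---- annotation libraries ------------------------------------------
    cat_ids = [c for c, _ in FIRST_LEVEL_CATEGORIES]
    cat_assign: dict[str, list[str]] = {}
    excl_lookup = {gene: g for g in groups for gene in exclusive_genes[g]}
    for gene in universe:
        g = excl_lookup.get(gene)
        skew_cat = None if config.null_model or g is None else config.category_skew.get(g)
        if skew_cat is not None and rng.random() < config.category_skew_strength:
            primary = skew_cat
        else:
            primary = cat_ids[int(rng.integers(len(cat_ids)))]
        cats = [primary]
        if rng.random() < config.multi_category_prob:
            other = cat_ids[int(rng.integers(len(cat_ids)))]
            if other != primary:
                cats.append(other)
        cat_assign[gene] = cats

    lo, hi = config.term_size_range
    term_rows: list[tuple[str, str, list[str]]] = []
    for i in range(1, config.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.universe_size, size=size, replace=False)
        term_rows.append((f"T{i:04d}", f"specific process {i}",
                          sorted(universe[int(j)] for j in idx)))
    planted_terms: dict[str, str] = {}
    if not config.null_model:
        for g in groups:
            src = sorted(exclusive_genes[g]) or sorted(pools[g])
            n_in = min(round(config.planted_term_size * config.planted_term_overlap),
                       len(src))
            n_out = config.planted_term_size - n_in
            inside = [src[int(i)] for i in rng.choice(len(src), size=n_in, replace=False)]
            outside = [universe[int(i)]
                       for i in rng.choice(config.universe_size, size=n_out, replace=False)]
            tid = f"TP_{g}"
            term_rows.append((tid, f"planted process {g}", sorted(set(inside + outside))))
            planted_terms[g] = tid

    # ---- gene-disease table and ICD map --------------------------------
    diseases = [f"D{i:04d}" for i in range(1, config.n_diseases + 1)]
    disease_chapter = {
        d: ICD_CHAPTERS[int(rng.integers(len(ICD_CHAPTERS)))] for d in diseases
    }
    by_chapter: dict[str, list[str]] = {}
    for d, ch in disease_chapter.items():
        by_chapter.setdefault(ch, []).append(d)

    gda_rows: list[tuple[str, str, str, float]] = []
    for gene in universe:
        g = excl_lookup.get(gene)
        skew_ch = None if config.null_model or g is None else config.chapter_skew.get(g)
        n_d = min(int(_shifted_poisson(rng, config.diseases_per_gene)[0]),
                  config.n_diseases)
        chosen: dict[str, float] = {}
        if skew_ch is not None and by_chapter.get(skew_ch):
            cands = sorted(by_chapter[skew_ch])
            n_skew = int(rng.binomial(n_d, config.chapter_skew_strength))
            n_skew = min(n_skew, len(cands))
            for i in rng.choice(len(cands), size=n_skew, replace=False):
                chosen[cands[int(i)]] = 0.7 + 0.3 * rng.random()
        while len(chosen) < n_d:
            d = diseases[int(rng.integers(config.n_diseases))]
            if d not in chosen:
                chosen[d] = (0.7 * rng.random()) if skew_ch is not None else rng.random()
        for d in sorted(chosen):
            gda_rows.append((gene, d, f"synthetic disease {d[1:]}", chosen[d]))

    # ---- write files (deterministic order and formatting) ---------------
    def _write(name: str, header: str, lines: list[str]) -> None:
        (out / name).write_text(header + "".join(lines))

    _write("herb_catalog.tsv", "herb_id\tgroup\tlocal_name\tlatin_name\n",
           [f"{a}\t{b}\t{c}\t{d}\n" for a, b, c, d in herb_rows])
    _write("herb_compound.tsv", "herb_id\tcompound_id\n",
           [f"{h}\t{c}\n" for h, c in hc_edges])
    _write("compound_target.tsv", "compound_id\ttarget_gene\tscore\n",
           [f"{c}\t{g}\t{s:.3f}\n" for (c, g), s in sorted(edges.items())])
    _write("first_level.gmt", "",
           [f"{cid}\t{name}\t" + "\t".join(
               sorted(g for g in universe if cid in cat_assign[g])) + "\n"
            for cid, name in FIRST_LEVEL_CATEGORIES])
    _write("go_slim.gmt", "",
           [f"{tid}\t{name}\t" + "\t".join(genes) + "\n"
            for tid, name, genes in term_rows])
    _write("gda.tsv", "gene\tdisease_id\tdisease_name\tscore\n",
           [f"{g}\t{d}\t{n}\t{s:.4f}\n" for g, d, n, s in gda_rows])
    _write("icd_map.tsv", "disease_id\tchapter\n",
           [f"{d}\t{disease_chapter[d]}\n" for d in diseases])

    manifest = {
        "seed": seed,
        "groups": groups,
        "pools": {g: sorted(pools[g]) for g in groups},
        "exclusive_genes": {g: sorted(exclusive_genes[g]) for g in groups},
        "planned_shared": {f"{a}-{b}": n for (a, b), n in sorted(plan["shared"].items())},
        "herb_group": herb_group,
        "compound_group": compound_group,
        "planted_terms": planted_terms,
        "category_skew": {} if config.null_model else dict(config.category_skew),
        "chapter_skew": {} if config.null_model else dict(config.chapter_skew),
        "null_model": config.null_model,
        "n_compounds": len(compound_group),
        "n_edges": len(edges),
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
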