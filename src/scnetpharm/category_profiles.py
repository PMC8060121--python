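"""First-level annotation-category proportion profiles per group.

Every target gene of a group is assigned to the first-level biological-
process categories it belongs to (a gene in several categories contributes
one assignment to each). A group's profile is the vector of assignment
counts normalised by the total number of assignments; genes in no category
are tallied in an "unclassified" bucket and excluded from the proportions
by default. Profiles are compared by plain Euclidean distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import GeneSetLibrary


@dataclass
class CategoryProfile:
    group: str
    categories: list[str]
    proportions: np.ndarray
    unclassified: int
    total_assignments: int


def category_profile(
    library: GeneSetLibrary,
    genes: set[str],
    group: str,
    per_gene: bool = False,
) -> CategoryProfile:
    """Proportion vector of a group's genes over first-level categories.

    With ``per_gene=True`` the denominator is the number of classified
    genes instead of the number of assignments (so multi-category genes
    make the vector sum exceed 1).
    """
    cats = library.term_ids()
    genes = {g.upper() for g in genes}
    counts = np.zeros(len(cats), dtype=float)
    classified_genes = 0
    for g in sorted(genes):
        hits = [i for i, c in enumerate(cats) if g in library.terms[c][1]]
        if hits:
            classified_genes += 1
            for i in hits:
                counts[i] += 1
    total = int(counts.sum())
    unclassified = len(genes) - classified_genes
    denom = classified_genes if per_gene else total
    props = counts / denom if denom > 0 else counts
    return CategoryProfile(
        group=group,
        categories=cats,
        proportions=props,
        unclassified=unclassified,
        total_assignments=total,
    )


def profile_distances(profiles: list[CategoryProfile]) -> pd.DataFrame:
    """Pairwise Euclidean distances between group proportion vectors."""
    if not profiles:
        raise ValueError("no profiles given")
    cats = profiles[0].categories
    for p in profiles:
        if p.categories != cats:
            raise ValueError(
                f"profile {p.group!r} uses a different category list"
            )
    labels = [p.group for p in profiles]
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(profiles):
        for b in profiles[i + 1:]:
            d = float(np.linalg.norm(a.proportions - b.proportions))
            mat.at[a.group, b.group] = mat.at[b.group, a.group] = d
    return mat
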