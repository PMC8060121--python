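"""Category-proportion distances and ICD-10 disease-chapter profiles.

Assigns each type's target genes to first-level biological-process
categories, compares the proportion vectors by Euclidean distance, then
pools each gene's top-3 scored diseases and bins them into ICD-10 chapters.
Writes category_profiles.tsv, profile_dist.tsv and disease_profiles.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

import scnetpharm as snp
from scnetpharm import category_profiles as catprof

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "synthetic_bundle")
    ap.add_argument("--targets", type=Path, default=ROOT / "results" / "targets.tsv")
    args = ap.parse_args()
    out = ROOT / "results"

    targets = pd.read_csv(args.targets, sep="\t", dtype=str)
    groups = list(dict.fromkeys(targets["group"]))
    sets = {g: set(targets.loc[targets["group"] == g, "gene"]) for g in groups}

    first_level = snp.read_gmt(args.bundle / "first_level.gmt")
    profiles = [catprof.category_profile(first_level, sets[g], g) for g in groups]
    pd.DataFrame(
        {p.group: p.proportions for p in profiles}, index=profiles[0].categories
    ).to_csv(out / "category_profiles.tsv", sep="\t")
    dist = catprof.profile_distances(profiles)
    dist.to_csv(out / "profile_dist.tsv", sep="\t")
    for p in profiles:
        top = p.categories[int(p.proportions.argmax())]
        name = first_level.terms[top][0]
        print(f"{p.group}: dominant category {top} ({name}), "
              f"{p.proportions.max():.0%} of assignments")
    import numpy as np
    tri = dist.where(np.triu(np.ones(dist.shape, dtype=bool), 1))
    closest = tri.stack().idxmin()
    farthest = tri.stack().idxmax()
    print(f"closest pair: {closest} (d={tri.stack().min():.3f}); "
          f"farthest: {farthest} (d={tri.stack().max():.3f})")

    coll = snp.TargetSetCollection(groups, sets, {g: 0 for g in groups})
    gda = snp.read_gene_disease_table(args.bundle / "gda.tsv")
    icd = snp.read_icd_map(args.bundle / "icd_map.tsv")
    dprofiles = snp.disease_profile(coll, gda, icd, k=3)
    rows = [(g, ch, f) for g, prof in dprofiles.items()
            for ch, f in prof.chapter_frequencies.items()]
    pd.DataFrame(rows, columns=["group", "chapter", "frequency"]).to_csv(
        out / "disease_profiles.tsv", sep="\t", index=False
    )
    for g, prof in dprofiles.items():
        ch = max(prof.chapter_frequencies, key=prof.chapter_frequencies.get)
        print(f"{g}: modal disease chapter '{ch}' "
              f"({prof.chapter_frequencies[ch]:.1%} of instances)")


if __name__ == "__main__":
    main()
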