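import json
from pathlib import Path

import pytest

import scnetpharm as snp


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory) -> Path:
    """Default synthetic input bundle (planted overlap structure), seed 11."""
    out = tmp_path_factory.mktemp("bundle")
    snp.generate(snp.SyntheticConfig(), out, seed=11)
    return out


@pytest.fixture(scope="session")
def manifest(bundle_dir) -> dict:
    return json.loads((bundle_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def network(bundle_dir) -> snp.HCTNetwork:
    herbs = snp.load_herb_catalog(bundle_dir / "herb_catalog.tsv")
    return snp.build_network(
        herbs,
        bundle_dir / "herb_compound.tsv",
        bundle_dir / "compound_target.tsv",
        score_threshold=700,
        cap=10,
    )


@pytest.fixture(scope="session")
def collection(network) -> snp.TargetSetCollection:
    return snp.collect_targets(network)


def write_edge_tables(tmp_path, hc_rows, ct_rows):
    """Small helper: write herb-compound and compound-target TSVs."""
    hc = tmp_path / "hc.tsv"
    ct = tmp_path / "ct.tsv"
    hc.write_text("herb_id\tcompound_id\n" + "".join(f"{h}\t{c}\n" for h, c in hc_rows))
    ct.write_text(
        "compound_id\ttarget_gene\tscore\n"
        + "".join(f"{c}\t{g}\t{s}\n" for c, g, s in ct_rows)
    )
    return hc, ct


def tiny_catalog():
    return [
        snp.HerbRecord("H1", "SE", "a", "A"),
        snp.HerbRecord("H2", "SY", "b", "B"),
        snp.HerbRecord("H3", "TE", "c", "C"),
        snp.HerbRecord("H4", "TY", "d", "D"),
    ]
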