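"""Network loading, score filtering and per-compound capping."""

import pytest

import scnetpharm as snp
from scnetpharm.hct_network import ValidationError, apply_cap, CompoundTargetEdge

from conftest import tiny_catalog, write_edge_tables


class TestHerbCatalog:
    def test_packaged_catalog_reproduces_study_counts(self):
        records = snp.load_herb_catalog(snp.packaged_herb_catalog())
        assert len(records) == 28
        by_group = {}
        for r in records:
            by_group[r.group] = by_group.get(r.group, 0) + 1
        assert by_group == {"SE": 8, "SY": 8, "TE": 8, "TY": 4}

    def test_header_only_file_gives_empty_catalog(self, tmp_path):
        f = tmp_path / "herbs.tsv"
        f.write_text("herb_id\tgroup\tlocal_name\tlatin_name\n")
        assert snp.load_herb_catalog(f) == []

    def test_duplicate_herb_id_rejected(self, tmp_path):
        f = tmp_path / "herbs.tsv"
        f.write_text(
            "herb_id\tgroup\tlocal_name\tlatin_name\n"
            "H1\tSE\ta\tA\nH1\tSY\tb\tB\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            snp.load_herb_catalog(f)

    def test_unknown_group_label_rejected(self, tmp_path):
        f = tmp_path / "herbs.tsv"
        f.write_text("herb_id\tgroup\tlocal_name\tlatin_name\nH1\tXX\ta\tA\n")
        with pytest.raises(ValidationError, match="unknown group"):
            snp.load_herb_catalog(f)


class TestBuildNetwork:
    def test_threshold_is_strict_and_cap_spares_small_compounds(self, tmp_path):
        hc, ct = write_edge_tables(
            tmp_path,
            [("H1", "C1"), ("H2", "C2")],
            [("C1", "g1", 800), ("C1", "g2", 701), ("C1", "g3", 750),
             ("C2", "g1", 700)],  # exactly at threshold: removed
        )
        net = snp.build_network(tiny_catalog(), hc, ct, score_threshold=700, cap=10)
        assert {(e.compound_id, e.target_gene) for e in net.compound_target_edges} == {
            ("C1", "G1"), ("C1", "G2"), ("C1", "G3")
        }
        assert net.orphan_compounds == {"C2"}

    def test_cap_tie_break_keeps_lexicographically_smallest_genes(self, tmp_path):
        genes = ["g12", "g03", "g07", "g01", "g10", "g05", "g11", "g02",
                 "g08", "g04", "g09", "g06"]
        hc, ct = write_edge_tables(
            tmp_path, [("H1", "C1")], [("C1", g, 900) for g in genes]
        )
        net = snp.build_network(tiny_catalog(), hc, ct, cap=10)
        kept = sorted(e.target_gene for e in net.compound_target_edges)
        # all scores tie, so the 10 smallest symbols survive
        assert kept == sorted(g.upper() for g in genes)[:10]

    def test_unknown_herb_in_edges_rejected(self, tmp_path):
        hc, ct = write_edge_tables(tmp_path, [("H9", "C1")], [("C1", "g1", 800)])
        with pytest.raises(ValidationError, match="unknown herb"):
            snp.build_network(tiny_catalog(), hc, ct)

    def test_malformed_score_rejected(self, tmp_path):
        hc, ct = write_edge_tables(tmp_path, [("H1", "C1")], [("C1", "g1", "high")])
        with pytest.raises(ValidationError, match="malformed score"):
            snp.build_network(tiny_catalog(), hc, ct)


class TestCappingProperties:
    def _edges(self, rng, n_compounds=8, n_genes=30):
        edges = []
        for c in range(n_compounds):
            genes = rng.choice(n_genes, size=rng.integers(1, 15), replace=False)
            for g in genes:
                edges.append(
                    CompoundTargetEdge(f"C{c}", f"G{g:02d}", float(rng.integers(701, 1000)))
                )
        return edges

    def test_capping_is_idempotent_and_monotone(self):
        import numpy as np

        rng = np.random.default_rng(5)
        for _ in range(20):
            edges = self._edges(rng)
            for cap in (1, 3, 10, "unlimited"):
                once = apply_cap(edges, cap)
                assert apply_cap(once, cap) == once
            # per-compound target sets grow with the cap
            prev: dict = {}
            for cap in (1, 2, 5, 10, "unlimited"):
                by_c: dict = {}
                for e in apply_cap(edges, cap):
                    by_c.setdefault(e.compound_id, set()).add(e.target_gene)
                for c, s in prev.items():
                    assert s <= by_c.get(c, set())
                prev = by_c

    def test_raising_threshold_never_adds_edges(self, bundle_dir):
        herbs = snp.load_herb_catalog(bundle_dir / "herb_catalog.tsv")
        nets = [
            snp.build_network(
                herbs, bundle_dir / "herb_compound.tsv",
                bundle_dir / "compound_target.tsv",
                score_threshold=t, cap="unlimited",
            )
            for t in (600, 700, 800)
        ]
        sets = [set(n.compound_target_edges) for n in nets]
        assert sets[2] <= sets[1] <= sets[0]

    def test_network_json_round_trip(self, network, tmp_path):
        path = tmp_path / "net.json"
        network.to_json(path)
        back = snp.HCTNetwork.from_json(path)
        assert back.compound_target_edges == network.compound_target_edges
        assert back.herbs == network.herbs
        assert back.orphan_compounds == network.orphan_compounds
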