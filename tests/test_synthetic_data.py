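"""Generator contracts: determinism, feasibility checks, planted structure."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

import scnetpharm as snp
from scnetpharm.synthetic_data import InfeasibleConfig, _shifted_poisson


def _hashes(d: Path) -> dict:
    return {f.name: hashlib.sha256(f.read_bytes()).hexdigest()
            for f in sorted(d.iterdir())}


class TestDeterminism:
    def test_fixed_seed_gives_byte_identical_bundle(self, tmp_path):
        cfg = snp.SyntheticConfig(universe_size=600,
                                  pool_sizes={"SE": 50, "SY": 40, "TE": 30, "TY": 20})
        snp.generate(cfg, tmp_path / "a", seed=3)
        snp.generate(cfg, tmp_path / "b", seed=3)
        assert _hashes(tmp_path / "a") == _hashes(tmp_path / "b")

    def test_different_seeds_differ(self, tmp_path):
        cfg = snp.SyntheticConfig()
        snp.generate(cfg, tmp_path / "a", seed=3)
        snp.generate(cfg, tmp_path / "b", seed=4)
        assert (_hashes(tmp_path / "a")["compound_target.tsv"]
                != _hashes(tmp_path / "b")["compound_target.tsv"])


class TestFeasibility:
    def test_overlap_demands_exceeding_pool_rejected_before_writing(self, tmp_path):
        cfg = snp.SyntheticConfig(
            pool_sizes={"SE": 20, "SY": 20, "TE": 20, "TY": 20},
            overlap={"SE-SY": 0.9, "SE-TE": 0.9, "SE-TY": 0.9,
                     "SY-TE": 0.0, "SY-TY": 0.0, "TE-TY": 0.0},
        )
        with pytest.raises(InfeasibleConfig):
            snp.generate(cfg, tmp_path / "x", seed=0)
        assert not (tmp_path / "x").exists() or not any((tmp_path / "x").iterdir())

    def test_bad_probability_rejected(self):
        with pytest.raises(InfeasibleConfig):
            snp.SyntheticConfig(frac_high_score=1.4).validate()


class TestPlantedStructure:
    def test_bundle_parses_through_every_reader(self, bundle_dir):
        herbs = snp.load_herb_catalog(bundle_dir / "herb_catalog.tsv")
        assert len(herbs) == 28
        snp.read_gmt(bundle_dir / "go_slim.gmt")
        snp.read_gmt(bundle_dir / "first_level.gmt")
        snp.read_gene_disease_table(bundle_dir / "gda.tsv")
        snp.read_icd_map(bundle_dir / "icd_map.tsv")

    def test_pool_recovery_at_unlimited_cap(self, bundle_dir, manifest):
        herbs = snp.load_herb_catalog(bundle_dir / "herb_catalog.tsv")
        net = snp.build_network(
            herbs, bundle_dir / "herb_compound.tsv",
            bundle_dir / "compound_target.tsv", cap="unlimited",
        )
        coll = snp.collect_targets(net)
        for g in coll.groups:
            assert coll.sets[g] == set(manifest["pools"][g])

    def test_planned_pairwise_shared_counts_realised(self, manifest, collection):
        for pair, planned in manifest["planned_shared"].items():
            a, b = pair.split("-")
            assert len(collection.sets[a] & collection.sets[b]) == planned

    def test_fully_disjoint_config_gives_unit_exclusivity(self, tmp_path):
        cfg = snp.SyntheticConfig(
            overlap={k: 0.0 for k in
                     ("SE-SY", "SE-TE", "SY-TE", "SE-TY", "SY-TY", "TE-TY")},
        )
        snp.generate(cfg, tmp_path, seed=6)
        herbs = snp.load_herb_catalog(tmp_path / "herb_catalog.tsv")
        net = snp.build_network(
            herbs, tmp_path / "herb_compound.tsv", tmp_path / "compound_target.tsv"
        )
        coll = snp.collect_targets(net)
        for g in coll.groups:
            assert snp.exclusive_proportion(coll, g) == 1.0

    def test_planted_term_is_enriched_in_its_group(self, bundle_dir, manifest, collection):
        lib = snp.read_gmt(bundle_dir / "go_slim.gmt")
        for g, tid in manifest["planted_terms"].items():
            rows = snp.overrepresentation(lib, collection.sets[g], R_cal=60, seed=1)
            byid = {r.term_id: r for r in rows}
            assert byid[tid].p_adj < 0.05


class TestMarginalStatistics:
    def test_shifted_poisson_mean_and_floor(self):
        rng = np.random.default_rng(0)
        draws = _shifted_poisson(rng, 5.0, size=20000)
        assert draws.min() >= 1
        assert draws.mean() == pytest.approx(5.0, abs=3 * draws.std() / np.sqrt(draws.size))

    def test_configured_marginals_within_three_standard_errors(self, tmp_path):
        cfg = snp.SyntheticConfig()
        m = snp.generate(cfg, tmp_path, seed=13)
        hc = (tmp_path / "herb_compound.tsv").read_text().strip().splitlines()[1:]
        n_herbs = sum(cfg.herb_counts.values())
        mean_cpd = len(hc) / n_herbs
        se_cpd = np.sqrt(cfg.lambda_compounds / n_herbs)
        assert abs(mean_cpd - cfg.lambda_compounds) <= 3 * se_cpd

        ct = (tmp_path / "compound_target.tsv").read_text().strip().splitlines()[1:]
        scores = np.array([float(l.split("\t")[2]) for l in ct])
        frac = (scores > 700).mean()
        # coverage-repair edges push the supra-threshold mass slightly above
        # the configured fraction; noise edges push it below
        se_frac = np.sqrt(frac * (1 - frac) / scores.size)
        assert abs(frac - cfg.frac_high_score) <= max(3 * se_frac, 0.1)
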