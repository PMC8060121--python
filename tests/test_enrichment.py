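"""Overrepresentation statistics: expected counts, Fisher, BH, combined score."""

import math
from math import comb

import numpy as np
import pytest

import scnetpharm as snp
from scnetpharm.enrichment import GeneSetLibrary


def hypergeom_tail_by_enumeration(k, K, n, N):
    """Independent oracle: P(X >= k) summed term by term with binomials."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


@pytest.fixture(scope="module")
def small_library():
    rng = np.random.default_rng(21)
    universe = [f"G{i:04d}" for i in range(400)]
    terms = {}
    for i in range(15):
        size = int(rng.integers(8, 40))
        idx = rng.choice(400, size=size, replace=False)
        terms[f"T{i:02d}"] = (f"term {i}", frozenset(universe[j] for j in idx))
    return GeneSetLibrary(terms=terms, universe=frozenset(universe))


class TestExpectedCount:
    def test_published_table_arithmetic(self):
        # ratio n/N calibrated from one printed row reproduces another row
        assert snp.expected_count(3273, 127, 174400) == pytest.approx(2.38, abs=0.005)
        assert snp.expected_count(1745, 185, 407200) == pytest.approx(0.79, abs=0.005)

    def test_zero_reference_count(self):
        assert snp.expected_count(100, 0, 1000) == 0.0

    def test_linearity_and_additivity_over_a_partition(self):
        rng = np.random.default_rng(1)
        N, n = 500, 60
        # disjoint exhaustive K's sum to N, so expectations sum to n
        cuts = np.sort(rng.choice(np.arange(1, N), size=4, replace=False))
        Ks = np.diff(np.concatenate([[0], cuts, [N]]))
        assert sum(snp.expected_count(n, int(K), N) for K in Ks) == pytest.approx(n)


class TestFisherOverrep:
    def test_worked_example(self):
        # (C(5,4)C(15,4) + C(5,5)C(15,3)) / C(20,8) = 7280/125970
        assert snp.fisher_overrep(4, 5, 8, 20) == pytest.approx(7280 / 125970)

    def test_k_zero_gives_one(self):
        assert snp.fisher_overrep(0, 5, 8, 20) == 1.0

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            N = int(rng.integers(5, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert snp.fisher_overrep(k, K, n, N) == pytest.approx(
                hypergeom_tail_by_enumeration(k, K, n, N), rel=1e-12, abs=1e-15
            )

    def test_non_increasing_in_k(self):
        ps = [snp.fisher_overrep(k, 10, 15, 50) for k in range(0, 11)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            snp.fisher_overrep(6, 5, 8, 20)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        adj = snp.bh_adjust([0.002, 0.01, 0.03, 0.04])
        assert adj == pytest.approx([0.008, 0.02, 0.04, 0.04])

    @pytest.mark.parametrize("p", [[0.2, 0.2, 0.2], [0.77]])
    def test_equal_or_single_p_unchanged(self, p):
        assert snp.bh_adjust(p) == pytest.approx(p)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            p = rng.random(15)
            adj = snp.bh_adjust(p)
            assert (adj >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()
            assert (adj <= 1.0).all()


class TestRankZAndCombined:
    def test_planted_term_attains_top_combined_score(self, small_library):
        rng = np.random.default_rng(33)
        # target list = most of one term plus random background
        planted = "T03"
        term_genes = sorted(small_library.terms[planted][1])
        extra = rng.choice(sorted(small_library.universe), size=30, replace=False)
        targets = set(term_genes[: int(0.8 * len(term_genes))]) | set(extra)
        rows = snp.overrepresentation(
            small_library, targets, R_cal=200, seed=42
        )
        assert rows[0].term_id == planted
        assert rows[0].combined > 0

    def test_combined_zero_when_p_is_one(self, small_library):
        term_ids = small_library.term_ids()
        p_obs = {t: 1.0 for t in term_ids}
        z, combined = snp.rank_z_and_combined(
            small_library, set(list(small_library.universe)[:20]), p_obs,
            R_cal=50, seed=0,
        )
        assert all(c == 0.0 for c in combined.values())

    def test_rcal_floor_enforced(self, small_library):
        with pytest.raises(ValueError):
            snp.rank_z_and_combined(
                small_library, {"G0001"}, {t: 0.5 for t in small_library.terms},
                R_cal=10, seed=0,
            )


class TestOverrepresentation:
    def test_pure_term_list_ranks_that_term_first(self):
        universe = [f"G{i}" for i in range(100)]
        terms = {
            "TA": ("a", frozenset(universe[:10])),
            "TB": ("b", frozenset(universe[40:70])),
            "TC": ("c", frozenset(universe[80:95])),
        }
        lib = GeneSetLibrary(terms=terms, universe=frozenset(universe))
        rows = snp.overrepresentation(lib, set(universe[:10]), R_cal=50, seed=1)
        assert rows[0].term_id == "TA"
        assert rows[0].k == rows[0].K == 10

    def test_expected_uses_mapped_gene_count(self, small_library):
        universe_genes = sorted(small_library.universe)[:50]
        targets = set(universe_genes) | {"NOT_A_GENE_1", "NOT_A_GENE_2"}
        rows = snp.overrepresentation(small_library, targets, R_cal=50, seed=2)
        N = small_library.reference_size
        for r in rows:
            assert r.expected == pytest.approx(50 * r.K / N)

    def test_fully_unmapped_list_is_an_error(self, small_library):
        with pytest.raises(ValueError, match="no target genes map"):
            snp.overrepresentation(small_library, {"XX1", "XX2"}, R_cal=50, seed=0)

    def test_adjusted_never_below_raw_and_sorted_by_combined(self, small_library):
        rng = np.random.default_rng(8)
        targets = set(rng.choice(sorted(small_library.universe), 40, replace=False))
        rows = snp.overrepresentation(small_library, targets, R_cal=60, seed=3)
        assert all(r.p_adj >= r.p - 1e-15 for r in rows)
        assert all(a.combined >= b.combined for a, b in zip(rows, rows[1:]))

    def test_binomial_method_close_to_fisher_for_small_n(self, small_library):
        rng = np.random.default_rng(9)
        targets = set(rng.choice(sorted(small_library.universe), 25, replace=False))
        f = {r.term_id: r.p for r in snp.overrepresentation(
            small_library, targets, R_cal=50, seed=4, method="fisher")}
        b = {r.term_id: r.p for r in snp.overrepresentation(
            small_library, targets, R_cal=50, seed=4, method="binomial")}
        for t in f:
            assert b[t] == pytest.approx(f[t], abs=0.12)


class TestGMTParsing:
    def test_round_trip_through_generator_output(self, bundle_dir):
        lib = snp.read_gmt(bundle_dir / "go_slim.gmt")
        assert len(lib.terms) >= 60
        assert all(genes <= lib.universe for _, genes in lib.terms.values())

    def test_malformed_line_rejected(self, tmp_path):
        f = tmp_path / "bad.gmt"
        f.write_text("T1\tonly-a-name\n")
        with pytest.raises(ValueError, match="malformed"):
            snp.read_gmt(f)
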