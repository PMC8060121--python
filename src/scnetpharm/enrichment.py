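"""Gene-set overrepresentation with PANTHER-style combined scores.

For each annotation term with K genes in a reference universe of N genes,
and a target list with n_mapped genes in the universe of which k fall in
the term:

* expected count = n_mapped * K / N;
* one-sided Fisher p = P(X >= k), X ~ Hypergeometric(N, K, n_mapped)
  (a one-sided binomial with success probability K/N is available for
  fidelity to tools that report "binomial statistics");
* Benjamini-Hochberg step-up adjustment across the library's terms;
* a rank-deviation z-score: terms are ranked by Fisher p on each of
  R_cal random gene sets of the target list's size, giving a per-term
  mean rank mu and sd sigma; z = (r_obs - mu) / sigma, negative when the
  term ranks better than chance;
* combined score = z * ln(p): positive when both factors are negative,
  i.e. for genuinely overrepresented terms.

The z-score construction is a reconstruction of the behaviour of rank-
calibrated enrichment tools (the exact upstream algorithm is unpublished);
it is documented as such in the methods note.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetLibrary:
    #: term_id -> (term_name, frozenset of gene symbols)
    terms: dict[str, tuple[str, frozenset]]
    universe: frozenset

    @property
    def reference_size(self) -> int:
        return len(self.universe)

    def term_ids(self) -> list[str]:
        return sorted(self.terms)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    K: int
    k: int
    expected: float
    p: float
    p_adj: float
    z: float
    combined: float
    significant: bool


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetLibrary:
    """Parse a GMT file (term_id <TAB> description <TAB> gene ...).

    The universe defaults to the union of all term genes; pass an explicit
    universe to widen it (terms are intersected with it).
    """
    terms: dict[str, tuple[str, frozenset]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (needs id, name, >=1 gene): {line[:80]!r}")
        term_id, name, genes = parts[0], parts[1], frozenset(g.upper() for g in parts[2:] if g)
        if term_id in terms:
            raise ValueError(f"duplicate term id in GMT: {term_id}")
        terms[term_id] = (name, genes)
    if not terms:
        raise ValueError(f"empty GMT file: {path}")
    univ = frozenset().union(*(g for _, g in terms.values()))
    if universe is not None:
        universe = frozenset(g.upper() for g in universe)
        if not univ <= universe:
            raise ValueError("GMT contains genes outside the supplied universe")
        univ = universe
    else:
        univ = frozenset(univ)
    return GeneSetLibrary(terms=terms, universe=univ)


def expected_count(n_mapped: int, K: int, N: int) -> float:
    """Genes expected in the list for a term under proportional sampling."""
    if N <= 0 or not 0 <= K <= N or n_mapped < 0:
        raise ValueError("require N > 0, 0 <= K <= N, n_mapped >= 0")
    return n_mapped * K / N


def fisher_overrep(k: int, K: int, n: int, N: int) -> float:
    """One-sided overrepresentation p-value P(X >= k), hypergeometric."""
    if k > K or k > n or K > N or n > N or min(k, K, n) < 0:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def binomial_overrep(k: int, K: int, n: int, N: int) -> float:
    """One-sided binomial tail with success probability K/N."""
    if k > n or K > N or min(k, K, n) < 0:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    return float(stats.binom.sf(k - 1, n, K / N))


def bh_adjust(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_terms(p_by_term: np.ndarray) -> np.ndarray:
    """Ranks (1 = smallest p); ties share their average rank."""
    return stats.rankdata(p_by_term, method="average")


def rank_z_and_combined(
    library: GeneSetLibrary,
    target_genes: set[str],
    p_obs: dict[str, float],
    R_cal: int = 200,
    seed: int = 0,
    method: str = "fisher",
) -> tuple[dict[str, float], dict[str, float]]:
    """Rank-deviation z-scores and combined scores for every term.

    Draws R_cal random gene sets of the mapped target list's size from the
    universe, ranks all terms by p each time, and standardises the observed
    rank against that null. sigma = 0 yields z = 0 with a warning.
    """
    if R_cal < 30:
        raise ValueError("R_cal must be >= 30 for a usable rank null")
    if not library.terms:
        raise ValueError("empty gene-set library")
    term_ids = library.term_ids()
    universe = np.array(sorted(library.universe))
    mapped = sorted({g.upper() for g in target_genes} & library.universe)
    n = len(mapped)
    N = library.reference_size
    rng = np.random.default_rng(seed)

    term_genes = [library.terms[t][1] for t in term_ids]
    tail = fisher_overrep if method == "fisher" else binomial_overrep
    ranks = np.empty((R_cal, len(term_ids)))
    for r in range(R_cal):
        draw = set(universe[rng.choice(N, size=n, replace=False)])
        ps = np.array([tail(len(draw & tg), len(tg), n, N) for tg in term_genes])
        ranks[r] = _rank_terms(ps)
    mu = ranks.mean(axis=0)
    sigma = ranks.std(axis=0, ddof=0)

    obs_ranks = _rank_terms(np.array([p_obs[t] for t in term_ids]))
    z: dict[str, float] = {}
    combined: dict[str, float] = {}
    for i, t in enumerate(term_ids):
        if sigma[i] == 0:
            logger.warning("term %s has zero rank variance in the null; z set to 0", t)
            zi = 0.0
        else:
            zi = float((obs_ranks[i] - mu[i]) / sigma[i])
        z[t] = zi
        combined[t] = zi * math.log(p_obs[t])
    return z, combined


def overrepresentation(
    library: GeneSetLibrary,
    target_genes: set[str],
    alpha: float = 0.05,
    R_cal: int = 200,
    seed: int = 0,
    method: str = "fisher",
) -> list[EnrichmentRow]:
    """Full per-term overrepresentation table, sorted by combined score.

    Only genes present in the annotation universe enter the statistics
    (n = n_mapped); an entirely unmapped target list is an error.
    """
    targets = {g.upper() for g in target_genes}
    mapped = targets & library.universe
    if not mapped:
        raise ValueError(
            f"no target genes map to the annotation universe; unmapped: {sorted(targets)[:10]}..."
        )
    unmapped = targets - mapped
    if unmapped:
        logger.info("%d target genes outside the universe were dropped", len(unmapped))

    n, N = len(mapped), library.reference_size
    term_ids = library.term_ids()
    tail = fisher_overrep if method == "fisher" else binomial_overrep
    raw_p = {}
    counts = {}
    for t in term_ids:
        genes = library.terms[t][1]
        K, k = len(genes), len(mapped & genes)
        counts[t] = (K, k)
        raw_p[t] = tail(k, K, n, N)
    adj = bh_adjust([raw_p[t] for t in term_ids])
    p_adj = dict(zip(term_ids, adj))
    z, combined = rank_z_and_combined(
        library, mapped, raw_p, R_cal=R_cal, seed=seed, method=method
    )
    rows = [
        EnrichmentRow(
            term_id=t,
            term_name=library.terms[t][0],
            K=counts[t][0],
            k=counts[t][1],
            expected=expected_count(n, counts[t][0], N),
            p=raw_p[t],
            p_adj=float(p_adj[t]),
            z=z[t],
            combined=combined[t],
            significant=bool(p_adj[t] < alpha),
        )
        for t in term_ids
    ]
    rows.sort(key=lambda r: (-r.combined, r.p, r.term_id))
    return rows
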