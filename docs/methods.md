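# Methods

## Network construction

The tripartite network links herbs (each carrying one of four constitution
labels: SE, SY, TE, TY) to compounds, and compounds to target genes.
Compound-target edges carry a confidence score in [0, 1000] produced
upstream; the package consumes these scores and never computes them.

Two filters define the working network:

* **Score threshold** (default 700): an edge survives only when
  `score > threshold`, strictly. An edge at exactly 700 is removed.
* **Per-compound cap** (default n = 10): if more than n edges survive the
  threshold for one compound, the n highest-scoring are kept. Score ties at
  the cutoff break by lexicographically ascending gene symbol — the source
  databases do not document a tie rule, so we fixed a deterministic,
  auditable one. Capping is idempotent and monotone in n; the uncapped
  network is a superset of every capped one.

Gene symbols are upper-cased at load. Compounds whose edges are all removed
stay in the network as flagged orphan nodes, so compound counts remain
comparable across filter settings. A compound listed under several herbs is
a single shared node.

## Target sets, overlap, exclusivity

A type's target set is the union of surviving target genes over all
compounds of all its herbs. Overlap structure is computed exactly by
tallying each gene's membership pattern (the Venn regions); pairwise shared
counts and per-type exclusive counts are marginals of that tally.

The **exclusive proportion** of a type is |genes in its set and no
other's| / |its set|, defined as 0 for an empty set so the permutation
statistic is always finite.

## Clustering

Each type's profile is the vector, over the union of target genes, of the
number of distinct surviving compound-target edges (from that type's
compounds) supporting each gene; a binary presence/absence variant is
available (`binary=True`). Weighted profiles are the default because edge
multiplicity carries the support information the binary view discards.

Distances are cosine: d(u, v) = 1 − u·v/(‖u‖‖v‖), which is scale-invariant
and lies in [0, 1] for the nonnegative profiles used here; a zero profile
is an error naming the offending group rather than a silent NaN.

UPGMA merges the closest pair, with inter-cluster distance the
size-weighted average of original member distances and the new node placed
at height = pair distance / 2 (so cophenetic distance between two leaves is
the merge distance and the tree is ultrametric). Ties between candidate
merges break toward the lexicographically smallest label pair. Topology
equality between trees compares the unordered set of clades, ignoring
heights. Cap robustness reclusters the score-filtered network at each cap
in {10, 50, 100, 500, unlimited} and flags whether all trees share one
topology.

## Exclusivity permutation test

The null shuffles the compound-target interactions of the *filtered*
network: target endpoints (with their scores) are permuted uniformly across
edges, conserving each compound's degree and the global target multiset;
duplicate (compound, target) pairs created by the shuffle are collapsed,
keeping the highest score. An alternative `full-rewire` scheme draws each
edge's target uniformly from the observed target universe. Endpoint
permutation is the default because it is the least-structured null
consistent with shuffling the observed interactions.

Per type (and for the pooled mean across types), the empirical one-sided
p-value is (#{null ≥ observed} + 1)/(R + 1), R = 999 by default. The +1
correction keeps p in (0, 1]. Because the statistic is a ratio of small
integers, exact ties between observed and null values are common on small
networks and make the test conservative (p stochastically above uniform);
calibration checks therefore use networks large enough that the statistic
is fine-grained (target sets of a few hundred genes), where simulated null
p-values are uniform to within KS sampling error.

## Overrepresentation

With a universe of N annotated genes, a term covering K of them, and a
target list with n genes in the universe (unmapped identifiers are dropped
before any statistic; n is the mapped count):

* expected count = nK/N;
* p = P(X ≥ k), X ~ Hypergeom(N, K, n), via the exact survival function
  (`fisher` method, default), or a one-sided binomial tail with success
  probability K/N (`binomial`), provided because upstream tools describe
  their test both ways;
* Benjamini–Hochberg step-up adjustment across the library's terms
  (significance threshold: adjusted p < 0.05);
* a rank-deviation z-score: for R_cal random gene sets of size n drawn from
  the universe (R_cal ≥ 30, default 200), all terms are ranked by p
  (average ranks on ties); the observed rank is standardised against the
  per-term null mean and sd, so z < 0 means the term ranks better than
  chance. A term with zero null rank variance gets z = 0 with a warning;
* combined score = z · ln(p) (natural log), positive when both factors are
  negative, zero whenever p = 1 or z = 0. Output is sorted by combined
  score descending.

The z-score construction is our reconstruction of rank-calibrated
enrichment scoring as popularised by tools in the Enrichr family; the exact
upstream algorithm is not published, so the package documents its own
convention rather than claiming equivalence.

## Category and disease profiles

First-level category profiles count gene-to-category assignments (a gene in
m categories contributes m assignments) and normalise by total assignments;
`per_gene=True` normalises by classified genes instead. Genes in no
category are tallied separately and excluded from the proportions, matching
how upstream annotation services report an "unclassified" bucket.
Profiles over a common category list are compared by Euclidean distance.

Disease profiles take, per gene, the k = 3 highest-scored diseases (0–1
curation-confidence scores; ties at the cutoff break by ascending disease
id; genes with fewer than k diseases contribute them all), pool them over a
type's gene set *with multiplicity* — a disease reached through several
genes counts once per gene, since the profiles are frequency distributions
over disease instances (`unique_diseases=True` gives the set-based
variant) — map them to ICD-10 chapters via a supplied table, and normalise
over classified instances. Unmapped diseases are tallied and excluded.

## Synthetic data generator

The generator fabricates every pipeline input with planted, recoverable
structure, recorded in a JSON manifest. What it emulates, and how:

* **Target pools.** Each type has a gene pool; pairwise overlaps are built
  from shared blocks sized `round(f · min(|A|, |B|))` for a configured
  fraction f per pair. Defaults: pools of 120/90/70/40 genes for
  SE/SY/TE/TY (the same ordering as the real study's 371/185/146/89 target
  counts, scaled to desk size), SE–SY overlap 0.30, TY nearly isolated
  (0.05/0.0/0.02) — the qualitative overlap structure the real analysis
  reported. An infeasible demand (overlaps exceeding a pool) fails before
  any file is written.
* **Herbs and compounds.** 28 herbs split 8/8/8/4. Counts per herb are
  1 + Poisson(λ − 1) — guaranteed ≥ 1 with mean exactly λ (λ_c = 10
  compounds/herb, λ_t = 5 targets/compound, at most 10 targets before
  capping). Within a group, a new compound is replaced by a reuse of an
  existing one with probability 0.15, giving shared compound nodes.
* **Scores.** A two-component scaled-Beta mixture: with probability 0.6 a
  "true" score 700 + 300·Beta(2,2), otherwise 700·Beta(2,2). Each compound
  also gets ~Poisson(1) sub-threshold noise edges to random universe genes;
  these never survive the default filter, exercising the threshold.
* **Recovery contract.** Every pool gene is guaranteed at least one
  supra-threshold edge on a compound with spare capacity (extra compounds
  are created if needed), so at threshold 700 and cap ≥ the generator's
  per-compound maximum, `collect_targets` returns exactly the planted
  pools. The coverage repair slightly raises the realised supra-threshold
  score fraction above the configured 0.6.
* **Annotations.** Eight first-level categories cover the 1500-gene
  universe (each gene gets one category, a second with probability 0.2);
  a per-type skew assigns a chosen category to that type's exclusive genes
  with probability 0.6 — the default gives TY a metabolic-process majority,
  echoing the real study's observation. Sixty specific terms of 10–60
  genes are drawn at random, plus one planted term per type built mostly
  (80%) from that type's exclusive genes.
* **Diseases.** 120 diseases are assigned uniformly to ten ICD-10
  chapters. Genes exclusive to a type draw a Binomial(n, 0.6) share of
  their diseases from the type's skewed chapter with scores in [0.7, 1],
  the rest uniformly with scores in [0, 0.7), so top-3 extraction recovers
  the planted chapter. Defaults mirror the real study's modal chapters
  (SE digestive, SY nervous, TE endocrine/metabolic, TY congenital).
* **Null model.** `null_model=True` gives all types one common pool and
  draws each compound's targets iid (with replacement, then collapsed) from
  it, with no planted structure of any kind — the configuration under which
  the permutation test's p-values should be uniform.

A fixed seed yields a byte-identical bundle (deterministic iteration order
and fixed-precision score formatting).

What the generator does **not** emulate: real gene symbols or chemistry,
the correlation structure of real annotation libraries (terms are sampled
independently), database-specific biases in confidence scores, and the
long-tailed compound promiscuity of real databases. Passing tests therefore
demonstrate correctness of the statistical machinery and recoverability of
planted structure, not agreement with any real database's content.

## Problem sizes and numerical conventions

Default desk-scale sizes — 28 herbs, ≈ 240 compounds, ≈ 1400 scored edges,
1500-gene universe — run the full pipeline in seconds. Calibration studies
use 200 simulated datasets at R = 199 permutations (exclusivity null) and
100 random target lists over a 40-term library with term sizes 50–150
(type-I error of the Fisher test), sizes at which the discrete statistics
are fine-grained enough for their asymptotic behaviour to show.

Degenerate inputs fail loudly rather than silently: zero vectors in cosine
distance, all-zero group profiles, asymmetric distance matrices, fully
unmapped target lists, inconsistent contingency counts and infeasible
generator configurations all raise errors naming the offender. Empirical
p-values are never 0 by construction; BH adjustment is capped at 1.

## Known limitations

* The real study's absolute numbers (target counts, shared counts,
  printed category distances and chapter frequencies) depend on databases
  that cannot be bundled; this package reproduces the analysis logic and
  its qualitative structure on synthetic data, plus the published tables'
  internal expected-count arithmetic.
* The rank-deviation z-score is a documented reconstruction, not a
  certified reimplementation of any service's internals.
* The permutation test's empirical p is conservative under heavy ties
  (small networks); reported p-values remain valid.
* UPGMA tie-breaking is deterministic but arbitrary; trees from tied
  distance matrices are reproducible yet not canonical.
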