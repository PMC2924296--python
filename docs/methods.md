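# Methods

## Model

`medianet` treats a protein–protein interaction (PPI) network as a simple,
undirected, unweighted graph. Self-loops are dropped at ingestion (a protein
does not mediate an effect to itself in this model) and duplicate or
reversed edge records collapse to one undirected edge. Node identifiers are
opaque case-sensitive strings; nothing is validated against any protein
database, which keeps the tool source-agnostic.

The effect model assumes effects spread along edges in either direction with
equal probability, and that a node receiving effects splits them equally
among its D neighbors. Hence the one-step effect of j on an adjacent i is
a¹_ij = 1/D_i — the magnitude is set by the **receiver's** degree. This
direction convention is easy to get backwards; the effect matrix is
receiver-row indexed throughout and every API takes explicit
`source=`/`receiver=` roles.

Effects multiply along a walk and add across walks, so the n-step effect
matrix is the matrix power a^n = (a¹)^n. Consequences worth knowing:

* **Conservation.** a¹ is row-stochastic on non-isolated nodes, and powers
  of row-stochastic matrices stay row-stochastic, so every receiver row of
  a^n sums to exactly 1 (asserted to 1e-12 in the tests). Isolated nodes
  have all-zero rows.
* **Walks, not paths.** A two-step walk may return to its origin, so the
  diagonal of a² is nonzero. Diagonal entries are retained in the matrix but
  excluded from every "effect on other nodes" aggregate (TI^n, A^n, mutual
  dependence, set effects).
* The mediator decomposition Σ_k M²_k(i,j) = a²_ij + a²_ji over common
  neighbors k of i ≠ j is an identity, because every two-step walk between
  distinct endpoints passes through exactly one intermediate node. The
  implementation computes the two sides by different code paths (pairwise
  pathway products vs. matrix power) and the tests assert their equality.

## Parameters and defaults

* **n (walk length), default 2.** Two-step effects are the headline
  quantity: one-step effects are just weighted adjacency, and beyond two
  steps effects are increasingly diffuse and of less practical relevance for
  disease–disease association. The API supports any n ≥ 1.
* **TI mode, default `exact_n`.** TI^n_j sums j's effects through walks of
  exactly n steps. The alternative `cumulative_mean` averages the sums over
  step lengths 1..n, the convention of the ecological topological-importance
  literature; both are exposed because published definitions differ.
* **Analysis network for M².** Degrees are always taken in whatever network
  is passed to `mediator_table`/`mediator_contribution`. The toy worked
  example only comes out right with full-network degrees (yellow's degree 5
  counts its three non-IP neighbors), so the CLI defaults to the full input
  graph rather than the DPIP subnetwork; callers wanting DPIP-basis values
  pass `--network dpip`.
* **Set effects are directional** (influence of sources on receivers);
  `symmetric=True` adds the reverse direction.
* **Top-k mediators, default 11** in the CLI ranking output.
* **Normalizations.** nD = D/(N−1); nB = B/((N−1)(N−2)/2); betweenness
  counts each unordered pair once and disconnected pairs contribute zero.
  Ranks use competition ranking (ties share the best rank), and mediator
  rankings break ties lexicographically on the protein id so output is
  deterministic.

## Subnetwork construction

A protein with at least one disease label is a DP — always, even when it
also neighbors other DPs. An IP is an unlabeled protein adjacent to at least
one DP; everything else is "other". The DPIP network keeps DPs and IPs with
only DP-incident edges (no IP–IP edges); the IP network keeps IPs and the
IP–IP edges, and is therefore not a subgraph of the DPIP network. Edge-level
invariant (tested): DPIP edges, IP edges and other-incident edges partition
the PPI edge set. Disease-pair linkage is classified direct (an edge joins
the two DP sets), indirect (a two-step path does), or unlinked; proteins
annotated to both diseases are reported separately and excluded from the
path tests, since self-influence is meaningless.

No attempt is made to emulate upstream data cleaning of any particular
interaction database beyond deduplication and self-loop removal; input
quality is the caller's concern.

## Synthetic data

`toy_fixture()` is the canonical 13-node fixture: two disease proteins (red,
degree 3; black, degree 7), mediators green (degree 2) and yellow (degree
5), six degree-1 "blue" partners that mediate nothing, and three "white"
leaves on yellow that are not interacting partners of any disease protein.
Its topology is the minimal one consistent with those degrees and the
mediation structure, and every index value on it is known in closed form
(stored as exact fractions in the fixture and recomputed by the tests).

`random_disease_network(n, p, labels, dp_per_label, seed)` draws an
Erdős–Rényi graph and plants disjoint disease-protein sets uniformly at
random; a single integer seed drives one numpy Generator stream, so networks
are bit-reproducible. The property and acceptance tests use batches of such
graphs at N ≤ 10 (where brute-force enumeration is feasible) and a 60-node /
p = 0.12 five-disease network for format-level checks — sizes chosen so the
full suite enumerates hundreds of graphs in seconds while still exercising
disconnected nodes, multi-mediator pairs and label overlap.

What the generator does **not** emulate: the heavy-tailed degree
distribution, clustering and dense cores of a real interactome, biased
ascertainment of interactions, or correlated disease annotations. Passing
tests therefore certify the algebra and the construction contracts, not any
biological claim about real disease modules.

## Oracles and numerics

Two brute-force oracles cross-check the fast implementations and share no
code with them: `brute_force_effect` enumerates every n-step walk explicitly
(exact rational arithmetic via `fractions.Fraction`, guarded to N ≤ 13,
n ≤ 5), and `brute_force_betweenness` enumerates every geodesic per node
pair with its own BFS plus DFS over distance-decreasing edges. The effect
matrix uses dense numpy matrix powers up to 3000 nodes and scipy.sparse CSR
above, with a test pinning the two paths to identical results. Comparisons
in tests are absolute (1e-12 for exact identities, 1e-9 where floating-point
summation order may differ). Degenerate inputs fail loudly: normalized
degree needs N ≥ 2, normalized betweenness N ≥ 3, correlations need ≥ 3
observations and non-constant vectors, empty protein sets are rejected, and
an all-zero influence decomposition yields an explicitly undefined
percentage breakdown rather than NaNs.

## Functional-importance helper

`average_term_pvalue` averages a protein's enrichment P-values over all its
term rows regardless of ontology category, and
`mediator_function_correlation` joins the top-k mediators (default 11) with
their avP and reports Pearson and Spearman coefficients (scipy.stats;
Spearman with average ranks on ties). The package consumes a flat
term/P-value TSV and does not compute enrichment itself — that belongs to
dedicated enrichment tools whose exports this format mirrors.

## Known limitations

* Unweighted, undirected networks only; the multiplicative-additive walk
  model generalizes to weighted graphs but that is not implemented.
* The effect model's equal-split assumption ignores interaction confidence,
  stoichiometry and cellular context.
* Results are only as good as the input interactome: the indices are
  sensitive to degree, so ascertainment bias in interaction databases
  propagates directly into mediator rankings.
* Published full-interactome analyses of this kind depend on specific
  database snapshots; with different inputs the specific rankings will
  differ even though the indices are deterministic.
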