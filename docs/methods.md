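# Methods

## Model

`heatlink` treats tumor→gene association prediction as heat diffusion on
a two-layer graph. Layer 1 is the directed bipartite graph of observed
`hasGene` edges; layer 2 is an undirected gene–gene interaction network.
For each tumor the binary indicator of its (training) genes is the initial
heat vector `f(0)`, and the diffused vector

    f(1) = exp(α R) f(0)

scores every gene, candidate associations being all (tumor, gene) pairs
outside the training edges. The approach assumes that genes associated
with the same tumor lie close together in the interaction network, so heat
leaking from a tumor's known genes accumulates on its unobserved ones.
Diffusion is linear, so per-tumor normalization of `f(1)` (to sum 1) is a
reporting convenience that cannot change within-tumor ranking — a property
the test suite asserts.

### Heat matrices

Two operators over the `n` genes are implemented:

* **Unnormalized** `H**`: off-diagonal 1 on edges, diagonal `−d(g_j)`
  (edge weights ignored). Columns sum to zero, so total heat is conserved.
* **Degree-normalized** `H*`: off-diagonal `w_ji / d_j` and diagonal
  `−(τ_i / d_i) Σ_k w_ik`, where `d` is the **unweighted** incident-edge
  count, `w ∈ (0, 1]` are edge weights (implicitly 1 for unweighted
  networks), and `τ_i = 0` exactly when gene `i` has no incident edge.
  Columns again sum to zero. Dividing by the weighted degree instead is
  available behind a flag (`weighted_degree=True`) but off by default.

Isolated genes (τ = 0) have an all-zero row and column: they retain their
heat apart from teleport leakage. This choice matters because the gene
universe is the union of both layers' genes, so bipartite-only genes are
legitimate isolated interaction-layer nodes.

The normalized operator is the package default (`variant="auto"`). On
degree-skewed networks the unnormalized exponential `e^{αH**}` relaxes
toward the uniform distribution within components at moderate α (the
spectral gap grows with degree), collapsing the ranking toward chance;
normalization keeps the dynamics local and preserves discrimination. The
evaluation suite demonstrates this directly: on a planted-signal
preferential-attachment graph, cross-validated AUC-ROC is ≈ 0.83–0.95 with
`H*` and ≈ 0.41–0.5 with `H**`. (Note the direction of the hub bias is
subtle: the *equilibrium* of `H*` is degree-proportional while that of
`H**` is uniform, so "normalization removes degree bias" refers to the
transient flow per edge — each sender distributes unit influence — not to
hub heat shares, which can be larger under `H*`.)

### Teleport

Random, structure-independent gene interactions are modeled by a uniform
rank-1 jump term, `R = γ H + (1 − γ) g 1ᵀ` with `g = (1/n) 1` and
γ = 0.85 (the conventional PageRank damping). The term is applied
identically on top of either heat matrix and is never materialized: the
`HeatMatrix` stores only non-zero entries of `H` and applies
`R x = γ (H x) + ((1 − γ)/n) (Σx) 1` implicitly. Useful identities that
the tests exploit: without teleport `1ᵀ f(1) = 1ᵀ f(0)` exactly; with
teleport the total grows by exactly `e^{α(1−γ)}` (continuous) or
`(1 + α(1−γ)/M)^M` (discrete), because `1ᵀH = 0` and `1ᵀg = 1`.

### Discrete approximation

`diffuse_exact` computes the dense matrix exponential and is capped at
n ≤ 2000 (configurable); it exists as the small-graph oracle. Production
scoring uses

    f(1) = (I + (α/M) R)^M f(0)

as `M` sparse matrix–vector products per tumor, never forming the matrix
power: cost `O(M |E|)` per tumor and `O(M |E| T)` overall. The error
against the exponential decreases monotonically in `M` (asserted for
M ∈ {1, 10, 100, 1000}; below 1e-3 per entry at M = 1000 on graphs with
n ≤ 50). For M ≥ α the discrete operator built on `H*` is entrywise
non-negative (diagonal of `H*` is ≥ −1), so non-negative seeds yield
non-negative scores.

### Parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | thermal conductivity (dimensionless) | 1.0 | past ~1 the ranking stops changing; 0 disables diffusion |
| M | discrete iterations / diffusion horizon | 6 | convergence point of the ranking on the reference weighted network |
| γ | non-jump probability | 0.85 | PageRank convention |
| teleport | apply the random-jump term | on | models spurious interactions; keeps zero-seed tumors scoreable |
| normalize_output | per-tumor sum-to-1 | on | reporting only; rank-invariant |

Zero-seed tumors (every edge held out by a fold) are still scored: with
teleport on, the uniform jump distribution `g` is diffused in place of the
empty seed. The zero vector is a fixed point of the linear operator, so
without this fallback such tumors would receive all-tied zero scores;
either way they carry essentially no signal, but scoring them keeps fold
metrics defined over the full candidate set.

## Input handling

Edge lists are tab-, comma-, or whitespace-delimited (sniffed), optionally
gzipped, with an auto-detected optional header. Gene symbols are
uppercased before indexing; tumor identifiers are kept verbatim.
STRING-style integer scores are divided by 1000 (configurable) to land in
(0, 1]; because `H*` divides each column by its degree and the exponential
acts on the whole operator, a global rescaling of weights only rescales α,
so ranking is insensitive to this choice at fixed α up to that
reparameterization. Duplicate edges keep the maximum weight — the same
rule used when collapsing protein–protein edges onto gene pairs (many
proteins per gene: each gene pair gets the maximum weight over
contributing protein pairs; pairs collapsing to one gene are dropped as
self-loops; unmapped proteins are dropped with a logged count). The gene
universe of an assembled `TwoLayerGraph` is the union of both layers'
genes, in layer-1-first order.

## Baselines

Neighborhood scores are adapted to the directed bipartite layer: with
`N_out(x)` the tumor's genes and `N′(y)` the union of gene sets of the
tumors linked to gene `y`, the common-neighbor set is
`z = N_out(x) ∩ N′(y)`. Because genes have no out-edges, the "degree" of
a common-neighbor gene is its bipartite degree (tumors linked to it);
genes of degree ≤ 1 contribute 0 to Adamic/Adar (natural log), avoiding
1/log 1. Katz is the pure truncated sum `Σ_{l≤L} β^l · #walks(l)` on the
combined graph (directed tumor→gene plus symmetrized gene–gene), default
β = 1e-4, L = 5; an `α = 0.15` sometimes quoted alongside Katz results in
the comparison literature has no defined role in this score and is
recorded on `BaselineSpec` but unused. Personalized PageRank walks on the
interaction layer with restart 0.15 at the tumor's training genes
(uniform over all genes, with a warning, when there are none); the
transition matrix is the column-normalized (weighted) adjacency and
dangling genes redistribute to the restart vector, so the stationary
vector sums to 1. All of these are pinned against brute-force oracles
(set enumeration, DFS walk counting, dense linear solve) in the tests.

## Evaluation

Observed edges are globally permuted under a seed and split into k
near-equal folds (a tumor may lose all its edges to a test fold; it is
scored anyway). Per fold, positives are the test edges and negatives are
all pairs outside the *full* observed edge set — exhaustive by default,
with an optional seeded sampling budget for very large graphs. AUC-ROC is
`(n′ + 0.5 n″)/n` computed by the rank-statistic equivalence (verified
against exhaustive pairwise comparison for small lists); AUC-PR is
average precision over the pooled ranking. A 60/20/20
train/validation/test split (proportions honored to within one edge) and
an (α, M) grid sweep — run on the training split only when one is
configured — support parameter selection.

## Significance

The null model rewires a layer by double-edge swaps: 10·|E| attempted
swaps, rejecting (and counting) any attempt creating a self-loop or
duplicate; degree sequences (both marginals for the bipartite layer) are
preserved exactly and weights travel with the swapped stubs. For each
candidate pair, `p = Ω/N` where Ω counts randomizations whose score for
that pair is *strictly* greater than the observed one — ties do not count,
no +1 smoothing is applied, and p = 0 is therefore attainable; each pair
is compared to its own randomized scores, not to a pooled null. N = 1000
by default (desk-scale tests use N ≤ 200). The Bonferroni threshold is
`α*/m` with m defaulting to N. Under an exchangeable null the p-values
are uniform on {0, 1/N, …, 1} (KS statistic < 0.1 at N = 200 in the
suite).

## Synthetic data

The generator emulates the two structural features the method relies on:
a sparse bipartite layer (default density 0.0133, the observed full-scale
`hasGene` prevalence) and a skewed-degree interaction layer (preferential
attachment, m = 2, by default; Erdős–Rényi available). Per tumor, the
gene count is binomial(n_genes, density); the first gene is uniform and
each further gene is, with probability `planted_fraction`, drawn from the
interaction-layer neighbors of the tumor's current genes — the pattern
diffusion can recover — falling back to uniform (with a logged count)
when no neighbor is available. The trailing `holdout_fraction` of each
tumor's genes is returned as a designated held-out set disjoint from the
graph's bipartite edges. Weighted layers draw w ~ U(0.1, 1.0);
`boost_planted_weights` moves planting edges into the top band
U(0.8, 1.0). Identical seeds give byte-identical edge lists.

What the generator does *not* emulate: methylation beta-values, anatomical
location structure, gene-set biology, or the correlated noise of real
interaction databases. Passing tests therefore demonstrate that the
implementation is correct and that the method recovers
network-neighborhood-structured associations — not that it will reach any
particular accuracy on real COSMIC/STRING/BioGRID data.

Default experiment scale is 200 tumors × 150 genes (≈ 400 bipartite
edges), chosen so a full 10-fold CV of every method runs in seconds on one
CPU while keeping per-fold positives (~40) large enough for stable AUC;
full-scale inputs (thousands of nodes per layer) load and score in
seconds via the sparse discrete path.

## Numerical choices and edge cases

* Per-tumor candidate ranking uses dense ranks, ties broken by gene label
  for determinism.
* `normalize_heat` of a zero vector returns it unchanged with a warning
  (zero seed, no teleport).
* Fold seeds, generator seeds, swap seeds, and the random baseline are all
  explicit `numpy` Generator seeds; every CLI command writes a manifest
  (inputs, parameters, seeds, package version) sufficient to reproduce its
  outputs bit-identically on the same platform.
* The toy fixture also exposes the literal printed 4×4 heat matrix of the
  worked example as a regression constant; its A–B block is asymmetric
  (unlike the normative symmetric construction for an undirected graph)
  and only the unseeded-gene entry of its diffusion output (0.43) is
  treated as ground truth.

## Known limitations

* Exact diffusion is deliberately capped (dense `expm` is cubic); large
  graphs must use the discrete path.
* Bonferroni is the only multiplicity correction offered.
* The permutation test rescores candidate pairs against their own null
  distribution; a pooled-null variant is not implemented.
* Baseline Katz truncates at L = 5 by default; very long-range structure
  is invisible to it.
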