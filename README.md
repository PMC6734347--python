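# heatlink

Heat-diffusion link prediction between tumor samples and genes on a
two-layer network.

## The problem

Cancer genomics produces bipartite association data — which genes were
observed (e.g. methylated) in which tumor samples — that is inevitably
incomplete. `heatlink` predicts the missing tumor→gene links by combining
two layers of evidence over a shared gene index:

* **layer 1**: the directed bipartite graph of observed `hasGene` edges
  from tumor samples to genes (COSMIC-style exports);
* **layer 2**: an undirected, optionally weighted gene–gene interaction
  network (STRING scored channels, BioGRID physical pairs, or any edge
  list in those dialects; protein-level networks are collapsed to gene
  level by maximum weight).

The package is aimed at computational biologists who want a fast,
network-topology-only prioritization of candidate tumor–gene associations,
together with the baselines, cross-validated evaluation, and permutation
significance machinery needed to judge it.

## The model

Each tumor's known genes seed a heat vector `f(0)` (1 on its training
genes, 0 elsewhere) which diffuses over the interaction layer:

    f(1) = exp(α R) f(0),     R = γ H + (1 − γ) g 1ᵀ,   g = (1/n) 1

where `H` is a heat matrix over genes, `α` is the thermal conductivity
(α = 0 means no diffusion), and the rank-1 teleport term models spurious
random gene interactions with jump probability `1 − γ` (γ = 0.85,
PageRank-style). The degree-normalized heat matrix

    H*_ij = w_ji / d_j   (edges),    H*_ii = −(τ_i / d_i) Σ_k w_ik

gives every gene unit influence and removes high-degree bias; an
unnormalized variant `H**` (off-diagonal 1, diagonal −d) is provided for
contrast. At scale the exponential is replaced by the discrete
approximation `f(1) = (I + (α/M) R)^M f(0)`, applied as `M` sparse
matrix–vector products per tumor — `O(M |E| T)` overall. Diffused heat,
optionally normalized to sum 1 per tumor, ranks every candidate (tumor,
gene) pair.

Also included: bipartite-adapted neighborhood baselines (common
neighbors, Jaccard, Adamic/Adar, preferential attachment, resource
allocation), truncated Katz, personalized PageRank and a random baseline;
k-fold edge-holdout evaluation with the link-prediction AUC
`(n′ + 0.5 n″)/n` and AUC-PR; and degree-preserving permutation tests with
p = Ω/N and Bonferroni correction.

## Worked example

The hand-checkable toy network has one tumor linked to genes A, B, C
(not D) over interaction edges A–B and C–D:

```python
from heatlink import DiffusionParams, score_tumors
from heatlink.synthetic import toy_fixture

graph = toy_fixture()
table = score_tumors(graph, ["Tumor X"], graph.layer1.edges, DiffusionParams())
print(table.table.to_string(index=False))
```

```
  tumor gene   score  rank
Tumor X    D 0.15867     1
```

Gene D — never linked to Tumor X — receives positive heat through its
interaction with gene C, making it the predicted novel association (with
exact dense-exponential diffusion and no teleport its raw heat is 0.43,
i.e. 0.15 of the normalized total).

On synthetic data with a planted diffusion signal (each tumor's genes
cluster in interaction-layer neighborhoods; 200 tumors × 150 genes):

```python
from heatlink import evaluate_method
from heatlink.synthetic import GeneratorConfig, generate

graph, _ = generate(GeneratorConfig(n_tumors=200, n_genes=150,
                                    planted_fraction=1.0, seed=1))
for method in ("heat", "adamic_adar", "ppr", "random"):
    r = evaluate_method(graph, method, k=10, seed=0, params=DiffusionParams())
    print(f"{method:13s} AUC-ROC {r.mean_auc_roc:.4f} ± {r.sd_auc_roc:.4f}"
          f"   AUC-PR {r.mean_auc_pr:.4f}")
```

```
heat          AUC-ROC 0.9472 ± 0.0125   AUC-PR 0.0465
adamic_adar   AUC-ROC 0.7299 ± 0.0548   AUC-PR 0.0207
ppr           AUC-ROC 0.9102 ± 0.0222   AUC-PR 0.0360
random        AUC-ROC 0.5093 ± 0.0471   AUC-PR 0.0017
```

Diffusion recovers the planted held-out links far above chance, with the
neighborhood and walk baselines in between — the qualitative ordering
expected when associations respect interaction-network structure.

The same workflows are available from a shell:

```sh
heatlink simulate --tumors 200 --genes 150 --planted-fraction 1.0 --seed 1 --out sim/
heatlink predict  --graph sim/graph.json --out pred/
heatlink evaluate --graph sim/graph.json --method heat --folds 10 --out eval/
heatlink permtest --graph sim/graph.json --n-perm 100 --top-k 50 --out perm/
```

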