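"""Baseline link-prediction scores for the tumor→gene bipartite task.

Neighborhood scores (common neighbors, Jaccard, Adamic/Adar, preferential
attachment, resource allocation) are adapted to the directed bipartite
setting: for a tumor ``x`` and gene ``y``,

* ``N_out(x)`` is the set of genes linked from ``x``;
* ``N'_out,in(y)`` is the union of out-neighbor gene sets of the tumors
  that link to ``y`` (the "genes co-observed with y").

The score operates on ``z = N_out(x) ∩ N'_out,in(y)``.  Because genes have
no out-edges in the bipartite layer, the degree of a common-neighbor gene
``z`` is taken as its bipartite degree (number of tumors linked to it);
genes with degree <= 1 contribute 0 to Adamic/Adar (avoiding 1/log 1).

Path-based baselines run on the combined two-layer graph (directed
tumor→gene edges plus the undirected gene–gene edges): truncated Katz sums
``beta^l`` over paths of length ``l <= L``; personalized PageRank walks on
the interaction layer with restart at the tumor's training genes.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .graph_model import BipartiteLayer, TwoLayerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "BaselineSpec",
    "NeighborhoodScorer",
    "neighborhood_score",
    "katz_score",
    "katz_scores",
    "ppr_score",
    "random_score",
]

NEIGHBORHOOD_METHODS = (
    "common_neighbors",
    "jaccard",
    "adamic_adar",
    "preferential_attachment",
    "resource_allocation",
)

ALL_METHODS = NEIGHBORHOOD_METHODS + ("katz", "ppr", "random")


@dataclass
class BaselineSpec:
    """Configuration of a baseline method.

    ``katz_alpha`` is recorded for provenance alongside Katz results in
    the comparison literature but plays no role in the truncated Katz sum,
    which depends on ``katz_beta`` and ``katz_max_length`` only.
    """

    method: str
    katz_beta: float = 1e-4
    katz_max_length: int = 5
    katz_alpha: float = 0.15
    ppr_restart: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.method not in ALL_METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; valid: {', '.join(ALL_METHODS)}"
            )
        if self.method == "katz" and self.katz_beta <= 0:
            raise ValueError("katz_beta must be > 0")
        if self.method == "katz" and self.katz_max_length < 1:
            raise ValueError("katz_max_length must be >= 1")
        if self.method == "ppr" and not (0.0 < self.ppr_restart <= 1.0):
            raise ValueError("ppr_restart must lie in (0, 1]")


class NeighborhoodScorer:
    """Neighborhood scores over a fixed set of training edges.

    Precomputes tumor→genes and gene→tumors adjacency once so repeated
    pair queries are cheap.
    """

    def __init__(self, layer1: BipartiteLayer, train_edges: frozenset | None = None):
        edges = layer1.edges if train_edges is None else train_edges
        self.layer1 = layer1
        self.t2g: dict[int, set] = defaultdict(set)
        self.g2t: dict[int, set] = defaultdict(set)
        for t, g in edges:
            self.t2g[t].add(g)
            self.g2t[g].add(t)
        # cache of N'_out,in per gene
        self._nprime: dict[int, frozenset] = {}

    def _nprime_of(self, g: int) -> frozenset:
        if g not in self._nprime:
            acc: set = set()
            for t in self.g2t.get(g, ()):
                acc |= self.t2g[t]
            self._nprime[g] = frozenset(acc)
        return self._nprime[g]

    def score(self, t: int, g: int, method: str) -> float:
        out_x = self.t2g.get(t, set())
        nprime = self._nprime_of(g)
        if method == "preferential_attachment":
            return float(len(out_x) * len(nprime))
        z = out_x & nprime
        if method == "common_neighbors":
            return float(len(z))
        if method == "jaccard":
            union = out_x | nprime
            return len(z) / len(union) if union else 0.0
        if method == "adamic_adar":
            return float(
                sum(
                    1.0 / math.log(len(self.g2t[zz]))
                    for zz in z
                    if len(self.g2t[zz]) > 1
                )
            )
        if method == "resource_allocation":
            return float(sum(1.0 / len(self.g2t[zz]) for zz in z))
        raise ValueError(f"unknown neighborhood method {method!r}")


def neighborhood_score(
    layer1: BipartiteLayer,
    tumor: str,
    gene: str,
    method: str,
    train_edges: frozenset | None = None,
) -> float:
    """Single-pair neighborhood score (see module docstring for the
    bipartite adaptation).  Raises for unknown labels or methods."""
    if method not in NEIGHBORHOOD_METHODS:
        raise ValueError(
            f"unknown neighborhood method {method!r}; valid: "
            f"{', '.join(NEIGHBORHOOD_METHODS)}"
        )
    t = layer1.tumors.position(tumor)
    g = layer1.genes.position(gene)
    return NeighborhoodScorer(layer1, train_edges).score(t, g, method)


# -- Katz -----------------------------------------------------------------


def _combined_adjacency(
    graph: TwoLayerGraph, train_edges: frozenset
) -> sp.csr_array:
    """Directed adjacency of the combined graph: tumors occupy rows/cols
    [0, T), genes [T, T+n).  Tumor→gene edges are one-way; gene–gene edges
    appear in both directions."""
    T = len(graph.tumors)
    n = len(graph.genes)
    ii, jj = [], []
    for t, g in train_edges:
        ii.append(t)
        jj.append(T + g)
    for i, j in graph.layer2.weights:
        ii += [T + i, T + j]
        jj += [T + j, T + i]
    data = np.ones(len(ii))
    return sp.csr_array((data, (ii, jj)), shape=(T + n, T + n))


def katz_scores(
    graph: TwoLayerGraph,
    tumor: str,
    spec: BaselineSpec,
    train_edges: frozenset | None = None,
) -> np.ndarray:
    """Truncated Katz scores from *tumor* to every gene:
    ``sum_{l=1..L} beta^l * #paths of length l`` on the combined graph."""
    if spec.katz_beta <= 0:
        raise ValueError("katz_beta must be > 0")
    edges = graph.layer1.edges if train_edges is None else train_edges
    T = len(graph.tumors)
    A = _combined_adjacency(graph, edges).T.tocsr()  # for row propagation
    r = np.zeros(T + len(graph.genes))
    r[graph.tumors.position(tumor)] = 1.0
    total = np.zeros(len(graph.genes))
    b = 1.0
    for _ in range(spec.katz_max_length):
        r = A @ r
        b *= spec.katz_beta
        total += b * r[T:]
    return total


def katz_score(
    graph: TwoLayerGraph,
    tumor: str,
    gene: str,
    spec: BaselineSpec,
    train_edges: frozenset | None = None,
) -> float:
    return float(
        katz_scores(graph, tumor, spec, train_edges)[graph.genes.position(gene)]
    )


# -- personalized PageRank ------------------------------------------------


def ppr_score(
    graph: TwoLayerGraph,
    tumor: str,
    spec: BaselineSpec,
    train_edges: frozenset | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> np.ndarray:
    """Stationary vector of a restart walk on the interaction layer.

    The restart distribution is uniform over the tumor's training genes (a
    uniform distribution over all genes, with a warning, if the tumor has
    none).  The transition matrix is the degree-normalized (weighted, when
    weights exist) layer-2 adjacency; dangling genes redistribute their
    mass to the restart vector, so the result sums to 1.
    """
    r = spec.ppr_restart
    n = len(graph.genes)
    t = graph.tumors.position(tumor)
    edges = graph.layer1.edges if train_edges is None else train_edges
    seeds = sorted(g for tt, g in edges if tt == t)
    s = np.zeros(n)
    if seeds:
        s[seeds] = 1.0 / len(seeds)
    else:
        warnings.warn("tumor has no training genes; using uniform restart")
        s[:] = 1.0 / n
    W = graph.layer2.adjacency()
    colsum = np.asarray(W.sum(axis=0)).ravel()
    inv = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    P = (W @ sp.diags_array(inv)).tocsr()  # column-stochastic on non-dangling
    dangling = colsum == 0
    v = s.copy()
    for _ in range(max_iter):
        walk = P @ v + s * v[dangling].sum()
        v_new = (1.0 - r) * walk + r * s
        if np.abs(v_new - v).max() < tol:
            v = v_new
            break
        v = v_new
    return v


# -- random baseline ------------------------------------------------------


def random_score(candidates: list[tuple[str, str]], seed: int):
    """Uniform(0, 1) i.i.d. scores per candidate pair, reproducible under
    *seed*; the benchmark every informative method must beat."""
    from .diffusion import ScoreTable, _rank_scores

    rng = np.random.default_rng(seed)
    rows = [(t, g, float(x)) for (t, g), x in zip(candidates, rng.random(len(candidates)))]
    return ScoreTable(table=_rank_scores(rows), method="random")
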