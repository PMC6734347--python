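"""Permutation significance testing against degree-preserving null graphs.

The null model rewires one layer by repeated double-edge swaps, keeping
every node's degree exactly while destroying the specific wiring.  For a
candidate (tumor, gene) pair with observed diffusion score ``s``, the
permutation p-value is

    p = Omega / N

where ``Omega`` counts the ``N`` randomized graphs whose score for the
pair strictly exceeds ``s`` (ties do not count; no +1 smoothing, so p = 0
is attainable).  Family-wise error over ``m`` tests is controlled by the
Bonferroni threshold ``alpha* / m``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffusion import DiffusionParams
from .evaluation import score_pairs
from .graph_model import BipartiteLayer, InteractionLayer, TwoLayerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationResult",
    "randomize_interactions",
    "randomize_bipartite",
    "pvalues_from_null",
    "permutation_pvalues",
    "bonferroni_threshold",
]

#: Attempted swaps per randomization, as a multiple of the edge count.
SWAP_FACTOR = 10


def randomize_interactions(
    layer2: InteractionLayer, seed: int, swap_factor: int = SWAP_FACTOR
) -> InteractionLayer:
    """Degree-preserving rewiring of the gene–gene layer.

    Attempts ``swap_factor * |E|`` double-edge swaps; swaps that would
    create self-loops or duplicate edges are rejected (and still count
    toward the attempt budget).  Weights travel with the swapped stubs.
    Graphs with fewer than 2 edges are returned unchanged with a warning.
    """
    edges = [(i, j, w) for (i, j), w in sorted(layer2.weights.items())]
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; returning the layer unchanged")
        return layer2
    rng = np.random.default_rng(seed)
    edge_set = {(i, j) for i, j, _ in edges}
    n_attempts = swap_factor * len(edges)
    for _ in range(n_attempts):
        a, b = rng.integers(len(edges)), rng.integers(len(edges))
        if a == b:
            continue
        u, v, w1 = edges[a]
        x, y, w2 = edges[b]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed: (u, x) carrying w1 and (v, y) carrying w2
        if u == x or v == y:
            continue
        new1 = (min(u, x), max(u, x))
        new2 = (min(v, y), max(v, y))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((min(u, v), max(u, v)))
        edge_set.discard((min(x, y), max(x, y)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a] = (*new1, w1)
        edges[b] = (*new2, w2)
    weights = {(i, j): w for i, j, w in edges}
    return InteractionLayer(
        genes=layer2.genes, weights=weights, weighted=layer2.weighted
    )


def randomize_bipartite(
    layer1: BipartiteLayer, seed: int, swap_factor: int = SWAP_FACTOR
) -> BipartiteLayer:
    """Degree-preserving rewiring of the tumor→gene layer.

    Swaps (t1, g1), (t2, g2) → (t1, g2), (t2, g1); both marginal degree
    sequences are preserved and duplicates are rejected.
    """
    edges = sorted(layer1.edges)
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; returning the layer unchanged")
        return layer1
    rng = np.random.default_rng(seed)
    edge_set = set(edges)
    for _ in range(swap_factor * len(edges)):
        a, b = rng.integers(len(edges)), rng.integers(len(edges))
        if a == b:
            continue
        t1, g1 = edges[a]
        t2, g2 = edges[b]
        if t1 == t2 or g1 == g2:
            continue
        new1, new2 = (t1, g2), (t2, g1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard((t1, g1))
        edge_set.discard((t2, g2))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[a], edges[b] = new1, new2
    return BipartiteLayer(
        tumors=layer1.tumors, genes=layer1.genes, edges=frozenset(edge_set)
    )


def bonferroni_threshold(alpha_star: float, m: int) -> float:
    """Per-test significance level ``alpha* / m`` for m tests."""
    if not (0.0 < alpha_star <= 1.0):
        raise ValueError("alpha_star must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha_star / m


def pvalues_from_null(
    observed: np.ndarray, null_scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Omega counts and p-values from an (N, n_pairs) null-score matrix.

    Omega counts null scores *strictly* greater than the observed one
    (ties do not increment it); p = Omega / N exactly.
    """
    observed = np.asarray(observed, dtype=float)
    null_scores = np.atleast_2d(np.asarray(null_scores, dtype=float))
    omega = (null_scores > observed[None, :]).sum(axis=0)
    return omega, omega / null_scores.shape[0]


@dataclass
class PermutationResult:
    """Per-pair permutation p-values with a Bonferroni summary."""

    table: pd.DataFrame  # tumor, gene, score, omega, p_value, significant
    N: int
    corrected_alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# N: {self.N}\n# corrected_alpha: {self.corrected_alpha:g}\n"
                f"# n_significant: {self.n_significant}\n"
            )
            out = self.table.copy()
            out["significant"] = out["significant"].astype(int)
            out.to_csv(fh, sep="\t", index=False)


def permutation_pvalues(
    graph: TwoLayerGraph,
    pairs: list[tuple[str, str]],
    params: DiffusionParams,
    N: int,
    seed: int,
    target: str = "layer2",
    alpha_star: float = 0.05,
    n_tests: int | None = None,
) -> PermutationResult:
    """Permutation p-values for candidate (tumor, gene) label pairs.

    Observed scores come from diffusion on the real graph (all observed
    edges as training information); each of the *N* randomizations rewires
    *target* ("layer1" or "layer2") degree-preservingly and rescores the
    same pairs.  The Bonferroni threshold uses ``n_tests`` tests
    (default N, following the convention of correcting for the number of
    randomization rounds).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if target not in ("layer1", "layer2"):
        raise ValueError("target must be 'layer1' or 'layer2'")
    pos_pairs = [
        (graph.tumors.position(t), graph.genes.position(g)) for t, g in pairs
    ]
    train = graph.layer1.edges
    observed = score_pairs(graph, train, pos_pairs, "heat", params=params)
    rng = np.random.default_rng(seed)
    null = np.empty((N, len(pairs)))
    for i in range(N):
        child = int(rng.integers(2**31))
        if target == "layer2":
            rand_graph = TwoLayerGraph(
                layer1=graph.layer1,
                layer2=randomize_interactions(graph.layer2, child),
            )
            rand_train = train
        else:
            rand_layer1 = randomize_bipartite(graph.layer1, child)
            rand_graph = TwoLayerGraph(layer1=rand_layer1, layer2=graph.layer2)
            rand_train = rand_layer1.edges
        null[i] = score_pairs(rand_graph, rand_train, pos_pairs, "heat", params=params)
    omega, pvals = pvalues_from_null(observed, null)
    corrected = bonferroni_threshold(alpha_star, n_tests if n_tests is not None else N)
    table = pd.DataFrame(
        {
            "tumor": [t for t, _ in pairs],
            "gene": [g for _, g in pairs],
            "score": observed,
            "omega": omega,
            "p_value": pvals,
            "significant": pvals < corrected,
        }
    )
    logger.info(
        "permutation test: N=%d, %d/%d pairs significant at %g",
        N, int((pvals < corrected).sum()), len(pairs), corrected,
    )
    return PermutationResult(table=table, N=N, corrected_alpha=corrected)
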