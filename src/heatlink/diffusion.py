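"""Heat-kernel diffusion over the gene interaction layer.

The model treats each tumor's known genes as heat sources and lets heat
flow along gene–gene interaction edges.  With heat matrix ``H`` and a
binary seed vector ``f(0)`` over genes, the exact diffusion output is

    f(1) = exp(alpha * H) @ f(0)

where ``alpha`` (thermal conductivity) controls how fast heat spreads;
``alpha = 0`` means no diffusion.  Two heat-matrix variants are supported:

* ``unweighted`` — off-diagonal 1 on edges, diagonal ``-d(g_j)``; heat flow
  is biased towards high-degree genes;
* ``weighted`` (degree-normalized) — off-diagonal ``w_ji / d_j`` and
  diagonal ``-(tau_i / d_i) * sum_k w_ik``, where ``d`` is the unweighted
  incident-edge count and ``tau_i`` flags genes with at least one edge.
  Each gene then has unit total influence, removing the degree bias.  An
  unweighted network uses implicit weight 1, which yields the normalized
  operator with diagonal ``-tau``.

A teleport (random-jump) term models spurious random gene interactions,
PageRank-style:  ``R = gamma * H + (1 - gamma) * g 1^T`` with uniform
``g = (1/n) 1`` and non-jump probability ``gamma`` (default 0.85).  The
rank-1 term is never materialized: matrix–vector products apply it
implicitly so only non-zero entries of ``H`` are stored.

For large graphs the exponential is replaced by the discrete approximation

    f(1) = (I + (alpha / M) R)^M @ f(0)

computed as ``M`` sparse matrix–vector products per tumor, giving overall
cost ``O(M |E| T)`` for ``T`` tumors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .graph_model import InteractionLayer, TwoLayerGraph

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionParams",
    "HeatMatrix",
    "ScoreTable",
    "build_heat_matrix_unweighted",
    "build_heat_matrix_weighted",
    "add_teleport",
    "seed_vector",
    "diffuse_exact",
    "diffuse_discrete",
    "normalize_heat",
    "score_tumors",
]

#: Default cap on the matrix size accepted by the dense-exponential path.
DENSE_CAP = 2000


@dataclass
class DiffusionParams:
    """Tunable diffusion parameters.

    alpha
        Thermal conductivity, >= 0.  0 disables diffusion entirely.
    iterations
        Number of discrete steps M (>= 1); controls how far heat travels.
    gamma
        Non-jump probability in [0, 1]; ``1 - gamma`` is the probability of
        a uniform random jump (teleport).
    teleport
        Whether to augment the heat matrix with the teleport term.
    normalize_output
        Divide each tumor's diffused vector by its sum (reporting only;
        cannot change within-tumor ranking).
    """

    alpha: float = 1.0
    iterations: int = 6
    gamma: float = 0.85
    teleport: bool = True
    normalize_output: bool = True

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations (M) must be >= 1")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class HeatMatrix:
    """Sparse n×n heat operator.

    ``variant`` is one of ``unweighted``, ``weighted``, or ``teleport``.
    ``matrix`` always holds the sparse Laplacian-style part; for the
    teleport variant the dense rank-1 jump term is applied implicitly in
    :meth:`matvec` so that only non-zero entries are ever stored.
    """

    matrix: sp.csr_array
    variant: str
    n: int
    gamma: float | None = None
    base_variant: str | None = None

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """Apply the full operator (including any teleport term) to *x*."""
        if self.variant == "teleport":
            jump = (1.0 - self.gamma) / self.n * x.sum()
            return self.gamma * (self.matrix @ x) + jump
        return self.matrix @ x

    def to_dense(self) -> np.ndarray:
        dense = self.matrix.toarray()
        if self.variant == "teleport":
            dense = self.gamma * dense + (1.0 - self.gamma) / self.n
        return dense

    def validate(self, atol: float = 1e-10) -> None:
        """Check the column-sum invariant (0, or 1-gamma with teleport)."""
        target = 0.0 if self.variant != "teleport" else 1.0 - self.gamma
        colsums = np.asarray(self.to_dense().sum(axis=0)).ravel()
        if self.n and not np.allclose(colsums, target, atol=atol):
            raise ValueError(
                f"column sums deviate from {target}: max |err| = "
                f"{np.abs(colsums - target).max():.3e}"
            )


def build_heat_matrix_unweighted(layer2: InteractionLayer) -> HeatMatrix:
    """Heat matrix for the unweighted undirected graph: ``A - diag(deg)``.

    Edge weights, if present, are ignored.
    """
    A = layer2.adjacency(use_weights=False)
    deg = layer2.degrees().astype(float)
    H = (A - sp.diags_array(deg)).tocsr()
    return HeatMatrix(matrix=H, variant="unweighted", n=len(layer2.genes))


def build_heat_matrix_weighted(
    layer2: InteractionLayer, weighted_degree: bool = False
) -> HeatMatrix:
    """Degree-normalized heat matrix for the (optionally weighted) graph.

    Entry ``(i, j) = w_ji / d_j`` for edges and diagonal
    ``-(tau_i / d_i) * sum_k w_ik`` with ``tau_i = 1`` iff gene *i* has at
    least one incident edge; columns sum to zero.  ``d`` is the unweighted
    incident-edge count by default (``weighted_degree=True`` divides by the
    weighted degree instead).  Isolated genes get an all-zero row and
    column and simply retain their heat.
    """
    n = len(layer2.genes)
    W = layer2.adjacency(use_weights=True)
    if weighted_degree:
        d = np.asarray(W.sum(axis=0)).ravel()
    else:
        d = layer2.degrees().astype(float)
    inv_d = np.divide(1.0, d, out=np.zeros_like(d, dtype=float), where=d > 0)
    # off-diagonal: scale column j by 1/d_j
    S = (W @ sp.diags_array(inv_d)).tocsr()
    wdeg = np.asarray(W.sum(axis=1)).ravel()  # sum_k w_ik (symmetric W)
    diag = -wdeg * inv_d  # tau folded in: zero where d == 0
    H = (S + sp.diags_array(diag)).tocsr()
    return HeatMatrix(matrix=H, variant="weighted", n=n)


def add_teleport(H: HeatMatrix, gamma: float) -> HeatMatrix:
    """Augment *H* with the uniform random-jump term:
    ``R = gamma * H + (1 - gamma) * (1/n) 1 1^T``.

    The rank-1 term is represented implicitly (see :class:`HeatMatrix`).
    """
    if H.variant == "teleport":
        raise ValueError("heat matrix already has a teleport term")
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if H.n < 1:
        raise ValueError("teleport requires at least one node")
    return HeatMatrix(
        matrix=H.matrix, variant="teleport", n=H.n,
        gamma=float(gamma), base_variant=H.variant,
    )


def heat_matrix_for(
    layer2: InteractionLayer,
    params: DiffusionParams,
    variant: str = "auto",
) -> HeatMatrix:
    """Build the operator a scoring run uses.

    ``variant='auto'`` selects the degree-normalized (weighted) form, the
    model's default; ``'unweighted'`` forces the raw form for contrast
    experiments.  Teleport is added per *params*.
    """
    if variant == "auto":
        variant = "weighted"
    if variant == "weighted":
        H = build_heat_matrix_weighted(layer2)
    elif variant == "unweighted":
        H = build_heat_matrix_unweighted(layer2)
    else:
        raise ValueError(f"unknown heat-matrix variant {variant!r}")
    if params.teleport:
        H = add_teleport(H, params.gamma)
    return H


def seed_vector(
    graph: TwoLayerGraph, tumor: str, train_edges: frozenset
) -> np.ndarray:
    """Binary seed f(0): 1 for genes linked to *tumor* in *train_edges*.

    1 means the gene has a (training) association with the tumor sample,
    0 means none.
    """
    t = graph.tumors.position(tumor)
    f0 = np.zeros(len(graph.genes))
    for tt, g in train_edges:
        if tt == t:
            f0[g] = 1.0
    return f0


def diffuse_exact(
    H: HeatMatrix,
    f0: np.ndarray,
    alpha: float,
    dense_cap: int = DENSE_CAP,
) -> np.ndarray:
    """Exact diffusion ``f(1) = exp(alpha * H) @ f(0)`` via a dense matrix
    exponential.  Intended as the small-graph oracle; refuses matrices
    larger than *dense_cap*."""
    if H.n > dense_cap:
        raise ValueError(
            f"n = {H.n} exceeds the dense-computation cap ({dense_cap}); "
            "use diffuse_discrete for large graphs"
        )
    f0 = np.asarray(f0, dtype=float)
    return scipy.linalg.expm(alpha * H.to_dense()) @ f0


def diffuse_discrete(
    R: HeatMatrix, f0: np.ndarray, params: DiffusionParams
) -> np.ndarray:
    """Discrete diffusion ``f(1) = (I + (alpha/M) R)^M @ f(0)``.

    Applied as M sparse matrix–vector products; the matrix power is never
    materialized, so each tumor costs ``O(M |E|)``.
    """
    y = np.asarray(f0, dtype=float).copy()
    c = params.alpha / params.iterations
    for _ in range(params.iterations):
        y = y + c * R.matvec(y)
    return y


def normalize_heat(f: np.ndarray) -> np.ndarray:
    """Divide by the vector sum so the output sums to 1.

    A zero-sum vector (zero seed with no teleport) is returned unchanged
    with a warning.  Normalization never changes within-tumor ranking.
    """
    f = np.asarray(f, dtype=float)
    s = f.sum()
    if s <= 0:
        warnings.warn("heat vector sums to <= 0; returning it unnormalized")
        return f.copy()
    return f / s


def diffused_scores(
    H: HeatMatrix, f0: np.ndarray, params: DiffusionParams
) -> np.ndarray:
    """Diffuse one seed vector and (optionally) normalize the result.

    A zero seed (every edge of the tumor held out) diffuses the uniform
    teleport distribution ``g = (1/n) 1`` instead when teleport is on —
    the linear operator maps the zero vector to itself, so without this
    fallback such tumors would receive all-tied zero scores.
    """
    f0 = np.asarray(f0, dtype=float)
    if f0.sum() == 0 and params.teleport:
        f0 = np.full(H.n, 1.0 / H.n)
    f1 = diffuse_discrete(H, f0, params)
    if params.normalize_output and f1.sum() > 0:
        f1 = normalize_heat(f1)
    return f1


@dataclass
class ScoreTable:
    """Per-(tumor, gene) candidate scores with per-tumor dense ranks."""

    table: pd.DataFrame  # columns: tumor, gene, score, rank
    method: str = "heat"

    def write(self, path, top_k: int | None = None) -> None:
        df = self.table
        if top_k is not None:
            df = df[df["rank"] <= top_k]
        with open(path, "w") as fh:
            fh.write(f"# method: {self.method}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "ScoreTable":
        method = "unknown"
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("# method:"):
                method = first.split(":", 1)[1].strip()
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        return cls(table=df, method=method)


def _rank_scores(rows: list[tuple[str, str, float]]) -> pd.DataFrame:
    """Sort candidates per tumor (score desc, gene label asc) and attach
    dense ranks; tied scores share a rank."""
    df = pd.DataFrame(rows, columns=["tumor", "gene", "score"])
    df = df.sort_values(
        ["tumor", "score", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = (
        df.groupby("tumor")["score"]
        .rank(method="dense", ascending=False)
        .astype(int)
    )
    return df


def score_tumors(
    graph: TwoLayerGraph,
    tumors: list[str],
    train_edges: frozenset,
    params: DiffusionParams,
    variant: str = "auto",
) -> ScoreTable:
    """Diffusion scores for every candidate (tumor, gene) pair.

    The heat matrix is built once and reused across tumors.  Candidates are
    all pairs not in *train_edges*; tumors whose every edge is held out get
    a zero seed and are scored by teleport-only diffusion rather than
    skipped.
    """
    if not tumors:
        return ScoreTable(table=pd.DataFrame(columns=["tumor", "gene", "score", "rank"]))
    H = heat_matrix_for(graph.layer2, params, variant=variant)
    gene_labels = graph.genes.labels
    rows: list[tuple[str, str, float]] = []
    for tumor in tumors:
        t = graph.tumors.position(tumor)
        f0 = seed_vector(graph, tumor, train_edges)
        f1 = diffused_scores(H, f0, params)
        seeded = {g for tt, g in train_edges if tt == t}
        for g, label in enumerate(gene_labels):
            if g not in seeded:
                rows.append((tumor, label, float(f1[g])))
    return ScoreTable(table=_rank_scores(rows), method="heat")
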