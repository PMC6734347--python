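"""Domain types and edge-list I/O for the two-layer tumor–gene graph.

The predictor consumes two information sources that share a gene index:

* **layer 1** — a directed bipartite graph of ``hasGene`` edges from tumor
  samples to the genes observed in them (e.g. methylated genes in a
  COSMIC-style export);
* **layer 2** — an undirected, optionally weighted gene–gene interaction
  network, in the dialect of STRING protein-links files (integer scores
  0–1000) or BioGRID-style unweighted pairs.

Protein-level networks are collapsed to gene level by keeping, for every
gene pair, the maximum-weight edge over all protein pairs encoded by those
genes.  The gene universe of a :class:`TwoLayerGraph` is the union of genes
seen in either layer; genes absent from the interaction layer remain as
isolated layer-2 nodes.
"""

from __future__ import annotations

import csv
import gzip
import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "NodeIndex",
    "BipartiteLayer",
    "InteractionLayer",
    "TwoLayerGraph",
    "load_bipartite_edges",
    "load_interaction_edges",
    "map_proteins_to_genes",
    "build_two_layer_graph",
]

# Tokens that mark a first row as a header rather than data.
_HEADER_TOKENS = {
    "tumor", "tumour", "tumor_id", "tumour_id", "sample", "sample_id",
    "sample_name", "gene", "gene1", "gene2", "gene_symbol", "protein",
    "protein1", "protein2", "score", "combined_score", "weight", "source",
    "target",
}


class NodeIndex:
    """Bijective mapping between node labels and dense 0-based positions.

    Gene indexes are built with ``normalize=True`` so that lookups are
    case-insensitive (gene symbols are uppercased); tumor identifiers are
    kept verbatim.
    """

    __slots__ = ("labels", "positions", "_normalize")

    def __init__(self, labels: Iterable[str], normalize: bool = False):
        if normalize:
            labels = (str(x).upper() for x in labels)
        seen: dict[str, int] = {}
        ordered: list[str] = []
        for lab in labels:
            if lab not in seen:
                seen[lab] = len(ordered)
                ordered.append(lab)
        self.labels: tuple[str, ...] = tuple(ordered)
        self.positions: dict[str, int] = seen
        self._normalize = normalize

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label: str) -> bool:
        if self._normalize:
            label = str(label).upper()
        return label in self.positions

    def __eq__(self, other) -> bool:
        return isinstance(other, NodeIndex) and self.labels == other.labels

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"NodeIndex(n={len(self)})"

    def position(self, label: str) -> int:
        """0-based position of *label* (case-normalized for gene indexes)."""
        if self._normalize:
            label = str(label).upper()
        try:
            return self.positions[label]
        except KeyError:
            raise KeyError(f"unknown node label: {label!r}") from None

    def label(self, position: int) -> str:
        return self.labels[position]


@dataclass(frozen=True)
class BipartiteLayer:
    """Directed tumor→gene ``hasGene`` layer.

    ``edges`` holds deduplicated ``(tumor_position, gene_position)`` pairs.
    """

    tumors: NodeIndex
    genes: NodeIndex
    edges: frozenset

    def __post_init__(self):
        nt, ng = len(self.tumors), len(self.genes)
        for t, g in self.edges:
            if not (0 <= t < nt and 0 <= g < ng):
                raise ValueError(f"edge ({t}, {g}) outside index ranges")

    @classmethod
    def from_label_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "BipartiteLayer":
        pairs = [(str(t), str(g).upper()) for t, g in pairs]
        tumors = NodeIndex((t for t, _ in pairs))
        genes = NodeIndex((g for _, g in pairs), normalize=True)
        edges = frozenset(
            (tumors.position(t), genes.position(g)) for t, g in pairs
        )
        return cls(tumors=tumors, genes=genes, edges=edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        """Edge prevalence |E| / (n_tumors * n_genes)."""
        denom = len(self.tumors) * len(self.genes)
        return len(self.edges) / denom if denom else 0.0

    def genes_of(self, tumor_position: int) -> set:
        return {g for t, g in self.edges if t == tumor_position}

    def edge_labels(self) -> list[tuple[str, str]]:
        return sorted(
            (self.tumors.label(t), self.genes.label(g)) for t, g in self.edges
        )

    def tumor_degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.tumors), dtype=int)
        for t, _ in self.edges:
            deg[t] += 1
        return deg

    def gene_degrees(self) -> np.ndarray:
        deg = np.zeros(len(self.genes), dtype=int)
        for _, g in self.edges:
            deg[g] += 1
        return deg


@dataclass(frozen=True)
class InteractionLayer:
    """Undirected gene–gene interaction layer.

    ``weights`` maps unordered position pairs ``(i, j)`` with ``i < j`` to
    edge weights in ``(0, 1]``.  Unweighted networks carry implicit weight 1
    and ``weighted=False``.
    """

    genes: NodeIndex
    weights: dict
    weighted: bool = False

    def __post_init__(self):
        n = len(self.genes)
        for (i, j), w in self.weights.items():
            if i == j:
                raise ValueError(f"self-loop on position {i}")
            if not (0 <= i < j < n):
                raise ValueError(f"bad edge key ({i}, {j})")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"weight {w} for edge ({i}, {j}) outside (0, 1]")

    @classmethod
    def from_label_pairs(
        cls,
        pairs: Iterable[tuple],
        weighted: bool = False,
    ) -> "InteractionLayer":
        """Build from ``(gene1, gene2[, weight])`` label tuples.

        Self-loops are dropped; duplicate pairs keep the maximum weight.
        """
        rows = []
        for row in pairs:
            g1, g2 = str(row[0]).upper(), str(row[1]).upper()
            w = float(row[2]) if weighted and len(row) > 2 else 1.0
            rows.append((g1, g2, w))
        genes = NodeIndex(
            (g for r in rows for g in r[:2]), normalize=True
        )
        weights: dict = {}
        dropped = 0
        for g1, g2, w in rows:
            i, j = genes.position(g1), genes.position(g2)
            if i == j:
                dropped += 1
                continue
            key = (min(i, j), max(i, j))
            weights[key] = max(weights.get(key, 0.0), w)
        if dropped:
            logger.warning("dropped %d self-loop interaction edge(s)", dropped)
        return cls(genes=genes, weights=weights, weighted=weighted)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    @property
    def edges(self) -> frozenset:
        return frozenset(self.weights)

    def degrees(self) -> np.ndarray:
        """Unweighted incident-edge counts."""
        deg = np.zeros(len(self.genes), dtype=int)
        for i, j in self.weights:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self, use_weights: bool | None = None) -> sp.csr_array:
        """Symmetric sparse adjacency with zero diagonal."""
        if use_weights is None:
            use_weights = self.weighted
        n = len(self.genes)
        if not self.weights:
            return sp.csr_array((n, n))
        ii, jj, ww = [], [], []
        for (i, j), w in self.weights.items():
            v = w if use_weights else 1.0
            ii += [i, j]
            jj += [j, i]
            ww += [v, v]
        return sp.csr_array((ww, (ii, jj)), shape=(n, n))

    def reindex(self, new_genes: NodeIndex) -> "InteractionLayer":
        """Remap edge positions onto *new_genes* (must contain all labels)."""
        remap = [new_genes.position(lab) for lab in self.genes.labels]
        weights = {}
        for (i, j), w in self.weights.items():
            a, b = remap[i], remap[j]
            weights[(min(a, b), max(a, b))] = w
        return InteractionLayer(genes=new_genes, weights=weights, weighted=self.weighted)

    def edge_labels(self) -> list[tuple]:
        out = []
        for (i, j), w in self.weights.items():
            a, b = sorted((self.genes.label(i), self.genes.label(j)))
            out.append((a, b, w))
        return sorted(out)


@dataclass(frozen=True)
class TwoLayerGraph:
    """Bipartite tumor→gene layer over a shared gene index with a gene–gene
    interaction layer; ``layer1.genes`` and ``layer2.genes`` are identical."""

    layer1: BipartiteLayer
    layer2: InteractionLayer

    def __post_init__(self):
        if self.layer1.genes != self.layer2.genes:
            raise ValueError("layer1 and layer2 must share the same gene index")

    @property
    def genes(self) -> NodeIndex:
        return self.layer1.genes

    @property
    def tumors(self) -> NodeIndex:
        return self.layer1.tumors

    def summary(self) -> str:
        """Structured text summary of node/edge counts."""
        lines = [
            f"Number of tumor samples\t{len(self.tumors)}",
            f"Number of genes\t{len(self.genes)}",
            f"Number of relations between tumor samples and genes (hasGene)\t{self.layer1.n_edges}",
            f"Gene-gene interaction edges\t{self.layer2.n_edges}",
            f"Interaction layer weighted\t{self.layer2.weighted}",
            f"Bipartite density\t{self.layer1.density:.6f}",
        ]
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "tumors": list(self.tumors.labels),
            "genes": list(self.genes.labels),
            "layer1_edges": sorted(self.layer1.edges),
            "layer2_edges": sorted(
                [i, j, w] for (i, j), w in self.layer2.weights.items()
            ),
            "weighted": self.layer2.weighted,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TwoLayerGraph":
        payload = json.loads(text)
        tumors = NodeIndex(payload["tumors"])
        genes = NodeIndex(payload["genes"], normalize=True)
        layer1 = BipartiteLayer(
            tumors=tumors,
            genes=genes,
            edges=frozenset((t, g) for t, g in payload["layer1_edges"]),
        )
        layer2 = InteractionLayer(
            genes=genes,
            weights={(i, j): w for i, j, w in payload["layer2_edges"]},
            weighted=payload["weighted"],
        )
        return cls(layer1=layer1, layer2=layer2)

    def write_edge_lists(self, layer1_path, layer2_path) -> None:
        """Write both layers as tab-delimited edge lists (round-trip safe)."""
        with open(layer1_path, "w") as fh:
            for t, g in self.layer1.edge_labels():
                fh.write(f"{t}\t{g}\n")
        with open(layer2_path, "w") as fh:
            for a, b, w in self.layer2.edge_labels():
                if self.layer2.weighted:
                    fh.write(f"{a}\t{b}\t{w!r}\n")
                else:
                    fh.write(f"{a}\t{b}\n")


# -- readers --------------------------------------------------------------


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _sniff_delimiter(line: str) -> str:
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return " "


def _read_rows(path) -> list[tuple[int, list[str]]]:
    """Parse a delimited text file into (line_number, fields) tuples."""
    rows = []
    with _open_text(path) as fh:
        delim = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line)
            if delim == " ":
                fields = line.split()
            else:
                fields = next(csv.reader([line], delimiter=delim))
            rows.append((lineno, [f.strip() for f in fields]))
    return rows


def _is_header(fields: Sequence[str], score_expected: bool) -> bool:
    if any(f.lower() in _HEADER_TOKENS for f in fields):
        return True
    if score_expected and len(fields) >= 3:
        try:
            float(fields[2])
        except ValueError:
            return True
    return False


def load_bipartite_edges(path) -> BipartiteLayer:
    """Read a 2+-column ``tumor_id<sep>gene_symbol`` edge list.

    The delimiter (tab/comma/whitespace) is sniffed; an optional header row
    is auto-detected; duplicate rows are collapsed; gene symbols are
    uppercased.  Raises :class:`ValueError` for empty files or malformed
    rows (naming the line number).
    """
    rows = _read_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty bipartite edge list")
    if _is_header(rows[0][1], score_expected=False):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows after header")
    pairs = []
    for lineno, fields in rows:
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{lineno}: malformed row {fields!r}")
        pairs.append((fields[0], fields[1]))
    layer = BipartiteLayer.from_label_pairs(pairs)
    logger.info(
        "loaded layer 1 from %s: %d tumors, %d genes, %d hasGene edges (%d rows)",
        path, len(layer.tumors), len(layer.genes), layer.n_edges, len(pairs),
    )
    return layer


def load_interaction_edges(
    path,
    weighted: bool = False,
    score_scale: float | None = None,
) -> InteractionLayer:
    """Read a ``gene1<sep>gene2[<sep>score]`` interaction edge list.

    Scores are divided by *score_scale* (default 1000 for STRING-style
    integer scores when ``weighted=True``, else 1).  Self-loops are dropped
    with a warning; duplicate pairs keep the maximum weight; scaled scores
    must land in ``(0, 1]``.
    """
    if score_scale is None:
        score_scale = 1000.0 if weighted else 1.0
    if score_scale <= 0:
        raise ValueError("score_scale must be positive")
    rows = _read_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty interaction edge list")
    if _is_header(rows[0][1], score_expected=weighted):
        rows = rows[1:]
    triples = []
    for lineno, fields in rows:
        if len(fields) < 2 or not fields[0] or not fields[1]:
            raise ValueError(f"{path}:{lineno}: malformed row {fields!r}")
        if weighted:
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: weighted=True but no score column"
                )
            try:
                score = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unparsable score {fields[2]!r}"
                ) from None
            w = score / score_scale
            if not (0.0 < w <= 1.0):
                raise ValueError(
                    f"{path}:{lineno}: score {score} outside (0, {score_scale}]"
                )
            triples.append((fields[0], fields[1], w))
        else:
            triples.append((fields[0], fields[1]))
    layer = InteractionLayer.from_label_pairs(triples, weighted=weighted)
    logger.info(
        "loaded layer 2 from %s: %d genes, %d edges (weighted=%s)",
        path, len(layer.genes), layer.n_edges, weighted,
    )
    return layer


def map_proteins_to_genes(
    protein_edges: Iterable[tuple],
    mapping: Mapping[str, str],
) -> InteractionLayer:
    """Collapse a weighted protein–protein network to gene level.

    *mapping* is a (possibly many-to-one) protein→gene table.  For every
    resulting gene pair the weight is the maximum over all contributing
    protein pairs; pairs collapsing onto a single gene are dropped as
    self-loops; edges with unmapped proteins are dropped with a logged
    count.
    """
    if not mapping:
        raise ValueError("empty protein-to-gene mapping")
    norm_map = {str(p): str(g).upper() for p, g in mapping.items()}
    triples = []
    unmapped = 0
    for row in protein_edges:
        p1, p2 = str(row[0]), str(row[1])
        w = float(row[2]) if len(row) > 2 else 1.0
        g1, g2 = norm_map.get(p1), norm_map.get(p2)
        if g1 is None or g2 is None:
            unmapped += 1
            continue
        triples.append((g1, g2, w))
    if unmapped:
        logger.info("dropped %d protein edge(s) with unmapped endpoints", unmapped)
    # from_label_pairs handles self-loop drop and max-weight collapse
    return InteractionLayer.from_label_pairs(triples, weighted=True)


def build_two_layer_graph(
    layer1: BipartiteLayer, layer2: InteractionLayer
) -> TwoLayerGraph:
    """Unify the gene indexes of both layers (union; layer-1 order first).

    Genes present only in layer 1 become isolated interaction-layer nodes;
    genes present only in layer 2 become bipartite genes with no incident
    ``hasGene`` edge.
    """
    union = NodeIndex(
        list(layer1.genes.labels) + list(layer2.genes.labels), normalize=True
    )
    remap1 = [union.position(lab) for lab in layer1.genes.labels]
    new_layer1 = BipartiteLayer(
        tumors=layer1.tumors,
        genes=union,
        edges=frozenset((t, remap1[g]) for t, g in layer1.edges),
    )
    new_layer2 = layer2.reindex(union)
    graph = TwoLayerGraph(layer1=new_layer1, layer2=new_layer2)
    logger.info("built two-layer graph:\n%s", graph.summary())
    return graph
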