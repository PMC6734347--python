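import numpy as np
import pytest
from hypothesis import settings

from heatlink.diffusion import DiffusionParams
from heatlink.graph_model import (
    BipartiteLayer,
    InteractionLayer,
    build_two_layer_graph,
)
from heatlink.synthetic import GeneratorConfig, generate, toy_fixture

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=30)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy_graph():
    """Tumor X -> {A, B, C} over gene edges A-B and C-D."""
    return toy_fixture()


@pytest.fixture(scope="session")
def planted_graph():
    """200x150 synthetic graph with fully planted diffusion signal."""
    graph, _ = generate(
        GeneratorConfig(n_tumors=200, n_genes=150, planted_fraction=1.0, seed=1)
    )
    return graph


@pytest.fixture(scope="session")
def noise_graph():
    """200x150 synthetic graph with no planted signal."""
    graph, _ = generate(
        GeneratorConfig(n_tumors=200, n_genes=150, planted_fraction=0.0, seed=2)
    )
    return graph


def random_interaction_layer(rng, n_genes, p=0.25, weighted=True):
    """Small random gene-gene layer (keeping isolated genes) for property tests."""
    from heatlink.graph_model import NodeIndex

    genes = NodeIndex([f"G{i}" for i in range(n_genes)], normalize=True)
    weights = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                weights[(i, j)] = float(rng.uniform(0.05, 1.0)) if weighted else 1.0
    if not weights:
        weights[(0, 1)] = 1.0
    return InteractionLayer(genes=genes, weights=weights, weighted=weighted)


def random_two_layer(rng, n_tumors=5, n_genes=8, p1=0.4, p2=0.3, weighted=False):
    pairs = [
        (f"T{t}", f"G{g}")
        for t in range(n_tumors)
        for g in range(n_genes)
        if rng.random() < p1
    ]
    if not pairs:
        pairs = [("T0", "G0")]
    layer1 = BipartiteLayer.from_label_pairs(pairs)
    layer2 = random_interaction_layer(rng, n_genes, p=p2, weighted=weighted)
    return build_two_layer_graph(layer1, layer2)
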