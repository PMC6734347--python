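"""Heat-matrix construction, exact/discrete diffusion, and scoring."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from conftest import random_interaction_layer
from heatlink.diffusion import (
    DiffusionParams,
    HeatMatrix,
    add_teleport,
    build_heat_matrix_unweighted,
    build_heat_matrix_weighted,
    diffuse_discrete,
    diffuse_exact,
    normalize_heat,
    score_tumors,
    seed_vector,
)
from heatlink.graph_model import InteractionLayer, NodeIndex
from heatlink.synthetic import TOY_PRINTED_HEAT_MATRIX, TOY_TUMOR


def layer_from(pairs, weighted=False):
    return InteractionLayer.from_label_pairs(pairs, weighted=weighted)


class TestHeatMatrixConstruction:
    def test_single_edge_unweighted(self):
        H = build_heat_matrix_unweighted(layer_from([("G1", "G2")]))
        assert np.allclose(H.to_dense(), [[-1, 1], [1, -1]])

    def test_triangle_unweighted(self):
        H = build_heat_matrix_unweighted(
            layer_from([("A", "B"), ("B", "C"), ("A", "C")])
        )
        dense = H.to_dense()
        assert np.allclose(np.diag(dense), -2)
        assert np.allclose(dense - np.diag(np.diag(dense)), 1 - np.eye(3))

    def test_edgeless_graph_zero_matrix(self):
        layer = InteractionLayer(genes=NodeIndex(["A", "B"], normalize=True), weights={})
        H = build_heat_matrix_unweighted(layer)
        assert H.matrix.nnz == 0

    def test_single_weighted_edge(self):
        H = build_heat_matrix_weighted(layer_from([("G1", "G2", 0.5)], weighted=True))
        assert np.allclose(H.to_dense(), [[-0.5, 0.5], [0.5, -0.5]])

    def test_isolated_node_row_and_column_zero(self):
        # C is isolated: tau_C = 0, so it neither sends nor receives
        layer = InteractionLayer.from_label_pairs([("A", "B", 0.8)], weighted=True)
        genes = NodeIndex(["A", "B", "C"], normalize=True)
        layer = InteractionLayer(genes=genes, weights=dict(layer.weights), weighted=True)
        dense = build_heat_matrix_weighted(layer).to_dense()
        assert np.all(dense[2, :] == 0)
        assert np.all(dense[:, 2] == 0)

    @given(st.integers(0, 10**6))
    def test_weighted_columns_sum_to_zero(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_interaction_layer(rng, 6, p=0.4, weighted=True)
        H = build_heat_matrix_weighted(layer)
        colsums = H.to_dense().sum(axis=0)
        assert np.abs(colsums).max() < 1e-12
        H.validate()

    def test_unweighted_matrix_symmetric(self):
        rng = np.random.default_rng(3)
        layer = random_interaction_layer(rng, 7, p=0.4, weighted=False)
        dense = build_heat_matrix_unweighted(layer).to_dense()
        assert np.allclose(dense, dense.T)


class TestTeleport:
    def test_gamma_one_is_identity_on_h(self):
        H = build_heat_matrix_unweighted(layer_from([("A", "B")]))
        R = add_teleport(H, 1.0)
        x = np.array([0.3, 0.7])
        assert np.allclose(R.matvec(x), H.matvec(x))

    def test_gamma_zero_pure_teleport(self):
        layer = layer_from([("A", "B"), ("C", "D")])
        R = add_teleport(build_heat_matrix_unweighted(layer), 0.0)
        dense = R.to_dense()
        assert np.allclose(dense, 0.25)

    def test_entries_are_affine_combination(self):
        layer = layer_from([("A", "B"), ("C", "D")])
        H = build_heat_matrix_unweighted(layer)
        R = add_teleport(H, 0.85)
        assert np.allclose(R.to_dense(), 0.85 * H.to_dense() + 0.15 / 4)

    def test_column_sums_one_minus_gamma(self):
        layer = layer_from([("A", "B"), ("B", "C")])
        R = add_teleport(build_heat_matrix_weighted(layer), 0.85)
        R.validate()

    def test_invalid_gamma_rejected(self):
        H = build_heat_matrix_unweighted(layer_from([("A", "B")]))
        with pytest.raises(ValueError):
            add_teleport(H, 1.2)

    def test_matvec_matches_dense(self):
        rng = np.random.default_rng(0)
        layer = random_interaction_layer(rng, 6, p=0.5, weighted=True)
        R = add_teleport(build_heat_matrix_weighted(layer), 0.85)
        x = rng.random(6)
        assert np.allclose(R.matvec(x), R.to_dense() @ x)


class TestSeedVector:
    def test_toy_seed(self, toy_graph):
        f0 = seed_vector(toy_graph, TOY_TUMOR, toy_graph.layer1.edges)
        assert f0.tolist() == [1, 1, 1, 0]

    def test_zero_seed_when_all_edges_held_out(self, toy_graph):
        f0 = seed_vector(toy_graph, TOY_TUMOR, frozenset())
        assert f0.sum() == 0

    def test_all_genes_linked(self, toy_graph):
        edges = frozenset((0, g) for g in range(4))
        assert seed_vector(toy_graph, TOY_TUMOR, edges).tolist() == [1, 1, 1, 1]

    def test_unknown_tumor_rejected(self, toy_graph):
        with pytest.raises(KeyError):
            seed_vector(toy_graph, "nope", toy_graph.layer1.edges)


class TestExactDiffusion:
    def test_alpha_zero_is_identity(self, toy_graph):
        H = build_heat_matrix_unweighted(toy_graph.layer2)
        f0 = np.array([1.0, 1.0, 1.0, 0.0])
        assert np.allclose(diffuse_exact(H, f0, 0.0), f0)

    def test_printed_toy_gene_d_entry(self):
        """The unseeded gene's diffused heat: (1 - e^-2) / 2 ~ 0.43."""
        H = HeatMatrix(matrix=sp.csr_array(TOY_PRINTED_HEAT_MATRIX), variant="unweighted", n=4)
        f1 = diffuse_exact(H, np.array([1.0, 1.0, 1.0, 0.0]), 1.0)
        assert round(float(f1[3]), 2) == 0.43
        assert f1[3] == pytest.approx((1 - np.exp(-2)) / 2)

    def test_two_node_equilibrium_at_large_alpha(self):
        H = build_heat_matrix_unweighted(layer_from([("A", "B")]))
        f1 = diffuse_exact(H, np.array([1.0, 0.0]), 50.0)
        assert np.allclose(f1, [0.5, 0.5], atol=1e-9)

    def test_dense_cap_enforced(self):
        H = HeatMatrix(matrix=sp.csr_array((3000, 3000)), variant="unweighted", n=3000)
        with pytest.raises(ValueError, match="diffuse_discrete"):
            diffuse_exact(H, np.zeros(3000), 1.0)


class TestDiscreteDiffusion:
    def test_single_step_on_path(self):
        # path A-B-C: f1 = f0 + H f0 by hand
        H = build_heat_matrix_unweighted(layer_from([("A", "B"), ("B", "C")]))
        f0 = np.array([1.0, 0.0, 0.0])
        got = diffuse_discrete(
            H, f0, DiffusionParams(alpha=1.0, iterations=1, teleport=False)
        )
        assert np.allclose(got, f0 + H.to_dense() @ f0)
        assert np.allclose(got, [0.0, 1.0, 0.0])

    @given(st.integers(0, 10**6))
    def test_conservation_without_teleport(self, seed):
        rng = np.random.default_rng(seed)
        layer = random_interaction_layer(rng, 8, p=0.3, weighted=True)
        H = build_heat_matrix_weighted(layer)
        f0 = rng.random(8)
        exact = diffuse_exact(H, f0, 1.0)
        assert exact.sum() == pytest.approx(f0.sum(), abs=1e-9)
        disc = diffuse_discrete(H, f0, DiffusionParams(iterations=6, teleport=False))
        assert disc.sum() == pytest.approx(f0.sum(), abs=1e-9)

    def test_teleport_growth_factors(self):
        rng = np.random.default_rng(7)
        layer = random_interaction_layer(rng, 10, p=0.3, weighted=True)
        R = add_teleport(build_heat_matrix_weighted(layer), 0.85)
        f0 = rng.random(10)
        alpha = 0.9
        exact = diffuse_exact(R, f0, alpha)
        assert exact.sum() == pytest.approx(
            np.exp(alpha * 0.15) * f0.sum(), abs=1e-9
        )
        M = 17
        disc = diffuse_discrete(R, f0, DiffusionParams(alpha=alpha, iterations=M))
        assert disc.sum() == pytest.approx(
            (1 + alpha * 0.15 / M) ** M * f0.sum(), abs=1e-9
        )

    def test_converges_to_exact_monotonically(self):
        rng = np.random.default_rng(11)
        layer = random_interaction_layer(rng, 12, p=0.3, weighted=True)
        R = add_teleport(build_heat_matrix_weighted(layer), 0.85)
        f0 = rng.random(12)
        exact = diffuse_exact(R, f0, 1.0)
        errors = []
        for M in (1, 10, 100, 1000):
            disc = diffuse_discrete(R, f0, DiffusionParams(iterations=M))
            errors.append(np.abs(disc - exact).max())
        assert errors[-1] < 1e-3
        assert all(a > b for a, b in zip(errors, errors[1:]))

    @given(st.integers(0, 10**6))
    def test_non_negative_seeds_yield_non_negative_scores(self, seed):
        # requires M >= alpha so the discrete operator is non-negative
        rng = np.random.default_rng(seed)
        layer = random_interaction_layer(rng, 8, p=0.4, weighted=True)
        R = add_teleport(build_heat_matrix_weighted(layer), 0.85)
        f0 = (rng.random(8) < 0.4).astype(float)
        out = diffuse_discrete(R, f0, DiffusionParams(alpha=1.0, iterations=6))
        assert (out >= -1e-15).all()


class TestNormalizeHeat:
    def test_printed_vector_normalization(self):
        f = normalize_heat(np.array([1.0, 1.0, 0.5, 0.43]))
        assert np.round(f[:3], 2).tolist() == [0.34, 0.34, 0.17]
        assert f[3] == pytest.approx(0.1468, abs=5e-4)
        assert f.sum() == pytest.approx(1.0, abs=1e-12)

    def test_single_entry(self):
        assert normalize_heat(np.array([5.0])).tolist() == [1.0]

    def test_zero_vector_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = normalize_heat(np.zeros(3))
        assert out.tolist() == [0, 0, 0]

    @given(st.integers(0, 10**6))
    def test_never_changes_ranking(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random(10) + 0.01
        assert np.array_equal(np.argsort(normalize_heat(f)), np.argsort(f))


class TestScoreTumors:
    def test_toy_candidate_is_gene_d(self, toy_graph):
        table = score_tumors(
            toy_graph, [TOY_TUMOR], toy_graph.layer1.edges, DiffusionParams()
        ).table
        assert table["gene"].tolist() == ["D"]
        assert table["score"].iloc[0] > 0
        assert table["rank"].iloc[0] == 1

    def test_alpha_zero_no_teleport_all_tied_at_zero(self, toy_graph):
        params = DiffusionParams(alpha=0.0, teleport=False, normalize_output=False)
        table = score_tumors(
            toy_graph, [TOY_TUMOR], toy_graph.layer1.edges, params
        ).table
        assert (table["score"] == 0).all()
        assert (table["rank"] == 1).all()

    def test_zero_seed_tumor_scored_by_teleport_only(self, toy_graph):
        table = score_tumors(
            toy_graph, [TOY_TUMOR], frozenset(), DiffusionParams()
        ).table
        assert len(table) == 4  # all genes are candidates
        assert (table["score"] > 0).all()

    def test_empty_tumor_list_gives_empty_table(self, toy_graph):
        table = score_tumors(
            toy_graph, [], toy_graph.layer1.edges, DiffusionParams()
        ).table
        assert table.empty

    def test_planted_holdouts_outscore_random_nonedges(self):
        from heatlink.synthetic import GeneratorConfig, generate

        graph, held = generate(
            GeneratorConfig(
                n_tumors=60, n_genes=80, planted_fraction=1.0,
                bipartite_density=0.04, holdout_fraction=0.3, seed=5,
            )
        )
        tumors = sorted({t for t, _ in held})
        table = score_tumors(
            graph, tumors, graph.layer1.edges, DiffusionParams()
        ).table
        scores = {(r.tumor, r.gene): r.score for r in table.itertuples()}
        held_set = set(held)
        held_scores = [scores[p] for p in held_set if p in scores]
        other = [s for p, s in scores.items() if p not in held_set]
        assert np.mean(held_scores) > np.mean(other)
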