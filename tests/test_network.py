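import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from coexsurv.io import ExpressionMatrix, InteractionSet, ValidationError
from coexsurv.network import (
    AdjacencyMatrix,
    ModulePartition,
    average_linkage_tree,
    detect_modules,
    dynamic_tree_cut,
    filter_modules_by_ppi,
    soft_adjacency,
    topological_overlap,
)
from coexsurv.synthetic import DevelopmentSimSpec, simulate_development
from oracles import brute_force_soft_adjacency, brute_force_tom, upgma_heights


def _random_adjacency(rng, n):
    a = rng.uniform(0, 1, (n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestSoftAdjacency:
    def test_perfect_correlation_is_fixed_point(self):
        df = pd.DataFrame([[1.0, 2, 3, 4], [2.0, 4, 6, 8]], index=["a", "b"],
                          columns=list("wxyz"))
        adj = soft_adjacency(ExpressionMatrix(df), power=10)
        assert adj.values[0, 1] == pytest.approx(1.0)

    def test_negative_half_correlation_power_ten(self):
        # profiles engineered to have PCC exactly -0.5
        x = np.array([1.0, -1.0, 0.0, 0.0])
        y = np.array([0.0, 0.0, 1.0, -1.0])
        b = -0.5 * x + np.sqrt(0.75) * y  # corr(x, b) = -0.5 by construction
        df = pd.DataFrame([x, b], index=["a", "b"], columns=list("wxyz"))
        adj = soft_adjacency(ExpressionMatrix(df), power=10)
        assert adj.values[0, 1] == pytest.approx(0.5**10, rel=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        x = rng.standard_normal((10, 6))
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(10)],
                          columns=[f"s{j}" for j in range(6)])
        adj = soft_adjacency(ExpressionMatrix(df), power=10)
        np.testing.assert_allclose(adj.values, brute_force_soft_adjacency(x, 10), atol=1e-12)

    def test_zero_variance_gene_reported(self):
        df = pd.DataFrame([[1.0, 2, 3], [5.0, 5, 5]], index=["ok", "flat"],
                          columns=list("xyz"))
        with pytest.raises(ValidationError, match="flat"):
            soft_adjacency(ExpressionMatrix(df))


class TestTopologicalOverlap:
    def test_two_node_unit_edge(self):
        adj = AdjacencyMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 1.0]]))
        tom = topological_overlap(adj)
        assert tom.values[0, 1] == pytest.approx(1.0)

    def test_empty_network_gives_zero_overlap(self):
        adj = AdjacencyMatrix(["a", "b", "c"], np.eye(3))
        tom = topological_overlap(adj)
        off = tom.values[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_triple_loop_oracle(self, rng):
        a = _random_adjacency(rng, 15)
        tom = topological_overlap(AdjacencyMatrix([str(i) for i in range(15)], a))
        np.testing.assert_allclose(tom.values, brute_force_tom(a), atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=2, max_value=20), st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_on_random_adjacencies(self, n, seed):
        a = _random_adjacency(np.random.default_rng(seed), n)
        tom = topological_overlap(AdjacencyMatrix([str(i) for i in range(n)], a))
        assert tom.values.min() >= 0.0 and tom.values.max() <= 1.0
        np.testing.assert_allclose(tom.values, tom.values.T)


class TestAverageLinkage:
    def test_separated_pairs_merge_in_order(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        tree = average_linkage_tree(d)
        heights = tree[:, 2]
        assert heights[0] == pytest.approx(0.1) and heights[1] == pytest.approx(0.1)
        assert heights[2] >= 0.9

    def test_equal_dissimilarities_merge_at_same_height(self):
        d = np.full((3, 3), 0.4)
        np.fill_diagonal(d, 0.0)
        tree = average_linkage_tree(d)
        np.testing.assert_allclose(tree[:, 2], 0.4)

    def test_matches_naive_upgma(self, rng):
        d = np.round(rng.uniform(0.05, 1, (12, 12)), 3)  # rounding avoids float ties
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = average_linkage_tree(d)
        np.testing.assert_allclose(sorted(tree[:, 2]), upgma_heights(d), atol=1e-10)

    def test_nan_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValidationError):
            average_linkage_tree(d)


class TestDynamicTreeCut:
    def _block_diss(self, sizes, within=0.05, between=0.95):
        n = sum(sizes)
        d = np.full((n, n), between)
        start = 0
        for s in sizes:
            d[start : start + s, start : start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_planted_blocks(self):
        d = self._block_diss([20, 20])
        part = dynamic_tree_cut(average_linkage_tree(d), d, min_module_size=5)
        assert sorted(part.module_sizes.values()) == [20, 20]

    def test_no_structure_gives_single_module(self):
        d = np.full((12, 12), 0.5)
        np.fill_diagonal(d, 0.0)
        part = dynamic_tree_cut(average_linkage_tree(d), d, min_module_size=5)
        assert part.module_sizes == {1: 12}

    def test_min_module_size_validated(self):
        d = self._block_diss([10])
        with pytest.raises(ValidationError):
            dynamic_tree_cut(average_linkage_tree(d), d, min_module_size=1)

    def test_labels_sorted_by_decreasing_size(self):
        d = self._block_diss([8, 25, 15])
        part = dynamic_tree_cut(average_linkage_tree(d), d, min_module_size=5)
        sizes = part.module_sizes
        assert [sizes[m] for m in sorted(sizes)] == [25, 15, 8]

    def test_recovers_planted_modules(self):
        spec = DevelopmentSimSpec(
            n_genes=250,
            module_defs=[(30, "early", 0.9), (40, "middle", 0.9), (50, "late", 0.9),
                         (60, "early", 0.9), (70, "late", 0.9)],
            seed=31,
        )
        protein, _, truth = simulate_development(spec)
        part = detect_modules(protein)
        genes = truth.assigned_genes()
        ari = adjusted_rand_score(truth.labels_for(genes), part.labels_for(genes))
        assert ari >= 0.9

    def test_pipeline_is_deterministic(self, planted_development):
        protein, _, truth = planted_development
        expr = protein.subset_genes(truth.assigned_genes())
        a = detect_modules(expr)
        b = detect_modules(expr)
        assert a.assignment == b.assignment

    def test_noise_never_helps_recovery(self):
        """Mean ARI is non-increasing in added measurement noise."""
        spec = DevelopmentSimSpec(
            n_genes=75,
            module_defs=[(25, "early", 0.95), (25, "middle", 0.95), (25, "late", 0.95)],
            seed=0,
        )
        mean_ari = []
        for extra_sd in (0.0, 1.5, 4.0):
            aris = []
            for seed in range(5):
                protein, _, truth = simulate_development(
                    DevelopmentSimSpec(**{**spec.__dict__, "seed": seed,
                                          "module_defs": spec.module_defs})
                )
                noisy = protein.data + np.random.default_rng(100 + seed).normal(
                    0, extra_sd, protein.data.shape
                )
                part = detect_modules(ExpressionMatrix(noisy))
                genes = truth.assigned_genes()
                aris.append(adjusted_rand_score(truth.labels_for(genes), part.labels_for(genes)))
            mean_ari.append(np.mean(aris))
        assert mean_ari[0] >= mean_ari[1] - 0.02 >= mean_ari[2] - 0.04


class TestPPIFilter:
    def _interactions(self, *pairs):
        return InteractionSet(
            pd.DataFrame(
                [(a, b, 300, 500) for a, b in pairs],
                columns=["gene_a", "gene_b", "experimental", "combined"],
            )
        )

    def test_member_without_internal_edge_removed(self):
        part = ModulePartition({"A": 1, "B": 1, "C": 1, "D": 2, "E": 2})
        filtered = filter_modules_by_ppi(part, self._interactions(("A", "B"), ("D", "E")))
        assert filtered.assignment["C"] == 0
        assert filtered.assignment["A"] == filtered.assignment["B"] != 0

    def test_edgeless_module_dropped_entirely(self):
        part = ModulePartition({"A": 1, "B": 1, "C": 2, "D": 2, "E": 2})
        # module 1 has only an edge to the *other* module: internal degree 0
        filtered = filter_modules_by_ppi(part, self._interactions(("A", "C"), ("C", "D")))
        assert filtered.assignment["A"] == filtered.assignment["B"] == 0
        assert len(filtered.labels) == 1

    def test_clique_module_is_fixed_point(self):
        part = ModulePartition({"A": 1, "B": 1, "C": 1})
        filtered = filter_modules_by_ppi(
            part, self._interactions(("A", "B"), ("A", "C"), ("B", "C"))
        )
        assert filtered.assignment == part.assignment
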