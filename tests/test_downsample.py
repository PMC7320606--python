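import numpy as np
import pytest
from _oracles import dense_pagerank as dense_pagerank_oracle

from icgs2 import (
    CellGraph,
    DownsampleConfig,
    ExpressionMatrix,
    NormState,
    build_knn_graph,
    community_representatives,
    downsample_cells,
    gene_dispersion,
    louvain_partition,
    pagerank_scores,
    select_dispersion_genes,
)


def one_d_matrix(positions, norm=NormState.cptt_log2):
    vals = np.array([positions], dtype=float)
    cells = [f"c{i}" for i in range(len(positions))]
    return ExpressionMatrix(["G1"], cells, vals, norm)


class TestDispersion:
    def test_hand_computed_variance_over_mean(self):
        m = ExpressionMatrix(["G1"], ["a", "b", "c"], np.array([[2.0, 4.0, 6.0]]), NormState.raw_counts)
        assert gene_dispersion(m)["G1"] == pytest.approx(1.0)  # var 4 (n-1), mean 4

    def test_constant_gene_scores_zero(self):
        m = ExpressionMatrix(["G1"], ["a", "b", "c"], np.full((1, 3), 5.0), NormState.raw_counts)
        assert gene_dispersion(m)["G1"] == 0.0

    def test_scaling_scales_dispersion_linearly(self):
        base = np.array([[1.0, 3.0, 8.0, 2.0]])
        m1 = ExpressionMatrix(["G1"], list("abcd"), base, NormState.raw_counts)
        m3 = ExpressionMatrix(["G1"], list("abcd"), 3 * base, NormState.raw_counts)
        assert gene_dispersion(m3)["G1"] == pytest.approx(3 * gene_dispersion(m1)["G1"])

    def test_single_cell_errors(self):
        m = ExpressionMatrix(["G1"], ["a"], np.array([[1.0]]), NormState.raw_counts)
        with pytest.raises(ValueError):
            gene_dispersion(m)


class TestSelectDispersionGenes:
    def test_exact_top_n(self):
        scores = {f"G{i:04d}": float(i) for i in range(5000)}
        assert len(select_dispersion_genes(scores, 500)) == 500

    def test_truncates_to_available(self):
        scores = {f"G{i}": float(i) for i in range(300)}
        assert len(select_dispersion_genes(scores, 500)) == 300

    def test_tie_breaks_lexicographically(self):
        scores = {"B": 1.0, "A": 1.0, "C": 2.0}
        assert select_dispersion_genes(scores, 2) == ["C", "A"]

    def test_class_exclusions_applied(self):
        scores = {"MT-ND1": 99.0, "RPL3": 98.0, "GATA1": 1.0}
        assert select_dispersion_genes(scores, 2) == ["GATA1"]

    def test_nonpositive_n_errors(self):
        with pytest.raises(ValueError):
            select_dispersion_genes({"A": 1.0}, 0)


class TestKnnGraph:
    def test_one_dimensional_nearest_neighbours(self):
        m = one_d_matrix([0.0, 1.0, 10.0])
        g = build_knn_graph(m, ["G1"], k=1)
        assert set(g.edges) == {("c0", "c1"), ("c1", "c0"), ("c2", "c1")}

    def test_out_degree_equals_k(self, small_normalized):
        sub = small_normalized.subset_cells(small_normalized.cell_ids[:50])
        g = build_knn_graph(sub, sub.gene_ids[:30], k=10)
        from collections import Counter

        deg = Counter(e[0] for e in g.edges)
        assert all(v == 10 for v in deg.values())

    def test_k_capped_with_warning(self):
        m = one_d_matrix([0.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="capping"):
            g = build_knn_graph(m, ["G1"], k=10)
        from collections import Counter

        assert all(v == 4 for v in Counter(e[0] for e in g.edges).values())




class TestPageRank:
    def test_triangle_symmetry(self):
        cells = ["a", "b", "c"]
        edges = [(u, v) for u in cells for v in cells if u != v]
        g = pagerank_scores(CellGraph(cells, edges))
        for c in cells:
            assert g.pagerank[c] == pytest.approx(1 / 3)

    def test_scores_sum_to_one(self, small_normalized):
        sub = small_normalized.subset_cells(small_normalized.cell_ids[:100])
        g = pagerank_scores(build_knn_graph(sub, sub.gene_ids[:40], k=5))
        assert sum(g.pagerank.values()) == pytest.approx(1.0, abs=1e-9)

    def test_star_center_scores_highest(self):
        leaves = [f"l{i}" for i in range(5)]
        edges = [(l, "hub") for l in leaves] + [("hub", leaves[0])]
        g = pagerank_scores(CellGraph(leaves + ["hub"], edges))
        assert g.pagerank["hub"] == max(g.pagerank.values())

    def test_matches_dense_power_iteration_oracle(self, small_normalized):
        sub = small_normalized.subset_cells(small_normalized.cell_ids[:150])
        g = build_knn_graph(sub, sub.gene_ids[:40], k=5)
        g = pagerank_scores(g)
        oracle = dense_pagerank_oracle(g.cell_ids, g.edges)
        for c in g.cell_ids:
            assert g.pagerank[c] == pytest.approx(oracle[c], abs=1e-8)


class TestLouvain:
    def two_cliques(self):
        cells = [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)]
        edges = []
        for grp in ("a", "b"):
            nodes = [c for c in cells if c.startswith(grp)]
            edges += [(u, v) for u in nodes for v in nodes if u != v]
        return CellGraph(cells, edges)

    def test_disconnected_cliques_two_communities(self):
        g = louvain_partition(self.two_cliques(), resolution=0.0, seed=0)
        labels = set(g.communities.values())
        assert len(labels) == 2

    def test_same_seed_identical_partition(self):
        g1 = louvain_partition(self.two_cliques(), seed=5)
        g2 = louvain_partition(self.two_cliques(), seed=5)
        assert g1.communities == g2.communities


class TestRepresentatives:
    def test_most_central_member_chosen(self):
        m = one_d_matrix([0.0, 1.0, 5.0])
        g = CellGraph(list(m.cell_ids), [])
        g.communities = {c: 0 for c in m.cell_ids}
        assert community_representatives(m, g, s=1) == ["c1"]

    def test_quota_is_floor_s_over_n_capped_by_size(self):
        # two communities sizes 3 and 6, s=8 -> quota 4 -> picks 3 and 4
        m = one_d_matrix(list(range(9)))
        g = CellGraph(list(m.cell_ids), [])
        g.communities = {f"c{i}": (0 if i < 3 else 1) for i in range(9)}
        reps = community_representatives(m, g, s=8)
        by = {0: 0, 1: 0}
        for c in reps:
            by[g.communities[c]] += 1
        assert by == {0: 3, 1: 4}
        assert len(reps) <= 8

    def test_matches_exhaustive_search_small_communities(self, small_normalized):
        rng = np.random.default_rng(0)
        cells = small_normalized.cell_ids[:10]
        sub = small_normalized.subset_cells(cells).subset_genes(small_normalized.gene_ids[:20])
        g = CellGraph(list(cells), [])
        g.communities = {c: 0 for c in cells}
        X = sub.values.T
        sums = [(sum(np.linalg.norm(X[i] - X[j]) for j in range(len(cells))), i) for i in range(len(cells))]
        best = min(sums)[1]
        assert community_representatives(sub, g, s=1) == [cells[best]]


class TestDownsampleCells:
    def test_below_cutoff_returns_all(self, small_normalized):
        out = downsample_cells(small_normalized, DownsampleConfig())
        assert out == list(small_normalized.cell_ids)

    def test_pagerank_path_returns_cutoff(self, small_normalized):
        cfg = DownsampleConfig(downsample_cutoff=200, louvain_threshold=15000, n_dispersion_genes=100)
        out = downsample_cells(small_normalized, cfg)
        assert len(out) == 200
        assert set(out) <= set(small_normalized.cell_ids)

    def test_louvain_path_engaged_above_threshold(self, small_normalized):
        cfg = DownsampleConfig(
            downsample_cutoff=150, louvain_threshold=400, louvain_target=600,
            n_dispersion_genes=100, seed=1,
        )
        out = downsample_cells(small_normalized, cfg)
        assert len(out) == 150
        assert len(set(out)) == 150
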