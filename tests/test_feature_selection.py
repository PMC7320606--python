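import itertools

import numpy as np
import pytest

from icgs2 import (
    CorrelationConfig,
    ExpressionMatrix,
    NormState,
    correlated_gene_search,
    hybrid_cluster,
    run_feature_selection,
    select_guide_genes,
    variable_gene_filter,
)
from icgs2.feature_selection import GeneModule, _distance_matrix, _kmedoids, guide3_matrix


def log_matrix(rows, genes=None, cells=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    cells = cells or [f"c{j}" for j in range(rows.shape[1])]
    return ExpressionMatrix(genes, cells, rows, NormState.cptt_log2)


class TestVariableGeneFilter:
    def test_three_cells_at_fold_retained(self):
        row = [0.0] * 7 + [4.0, 4.0, 4.0]  # 2^4 / 1 = 16 >= 4
        m = log_matrix([row, [0.1] * 10])
        assert "g0" in variable_gene_filter(m)

    def test_constant_gene_excluded_even_at_fold_one(self):
        m = log_matrix([[2.0] * 10, [0.0] * 8 + [3.0, 3.0]])
        cfg = CorrelationConfig(fold_threshold=1.0)
        out = variable_gene_filter(m, cfg)
        assert "g0" not in out and "g1" in out

    def test_two_high_cells_insufficient(self):
        row = [0.0] * 8 + [6.0, 6.0]  # only 2 cells high; 3rd-highest is 0
        m = log_matrix([row, [0.0] * 7 + [4.0] * 3])
        assert variable_gene_filter(m) == ["g1"]

    def test_no_passing_gene_errors(self):
        m = log_matrix([[0.1, 0.2, 0.1, 0.2, 0.1, 0.2]])
        with pytest.raises(ValueError, match="fold"):
            variable_gene_filter(m)


class TestKmedoidsOracle:
    """Deterministic k-medoids must match exhaustive subset search when small."""

    def brute(self, D, k):
        best = (np.inf, None)
        for med in itertools.combinations(range(D.shape[0]), k):
            cost = D[list(med)].min(axis=0).sum()
            if cost < best[0] - 1e-12:
                best = (cost, med)
        return best[0]

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_objective_matches_exhaustive(self, k):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(12, 5))
        D = _distance_matrix(X, "euclidean")
        medoids, labels = _kmedoids(D, k)
        cost = D[medoids].min(axis=0).sum()
        assert cost == pytest.approx(self.brute(D, k), abs=1e-9)


class TestHybridCluster:
    def test_two_blobs_two_clusters(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (10, 4)), rng.normal(5, 0.1, (10, 4))])
        res = hybrid_cluster(X, axis="genes", metric="euclidean")
        assert res.n_clusters == 2
        assert len(set(res.labels[:10])) == 1 and len(set(res.labels[10:])) == 1

    def test_deterministic_on_identical_input(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6))
        r1 = hybrid_cluster(X, metric="cosine")
        r2 = hybrid_cluster(X, metric="cosine")
        assert r1.order == r2.order
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_identical_items_single_cluster(self):
        X = np.ones((6, 3))
        assert hybrid_cluster(X, metric="euclidean").n_clusters == 1

    def test_ordering_is_a_permutation(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 4))
        res = hybrid_cluster(X, metric="correlation")
        assert sorted(res.order) == list(range(25))


class TestCorrelatedGeneSearch:
    def co_expressed(self, n_genes, n_cells, seed, noise=0.05):
        rng = np.random.default_rng(seed)
        program = rng.normal(2, 1, n_cells).clip(0)
        return np.abs(program[None, :] + rng.normal(0, noise, (n_genes, n_cells)))

    def test_duplicated_genes_one_module(self):
        rng = np.random.default_rng(4)
        base = rng.normal(3, 1, 30).clip(0.1)
        m = log_matrix(np.vstack([base, base]), genes=["dupA", "dupB"])
        cfg = CorrelationConfig(min_partners=1)
        modules, rho = correlated_gene_search(m, ["dupA", "dupB"], cfg)
        assert rho == pytest.approx(0.2)
        assert sorted(g for mod in modules for g in mod.genes) == ["dupA", "dupB"]

    def test_rho_incremented_until_under_cap(self):
        # 30 tightly co-expressed genes, cap forced to 20 -> rho must rise
        X = self.co_expressed(30, 60, seed=5, noise=0.01)
        m = log_matrix(X)
        cfg = CorrelationConfig(max_correlated_genes=20, min_partners=4)
        with pytest.raises(ValueError, match="0.9"):
            correlated_gene_search(m, list(m.gene_ids), cfg)

    def test_rho_final_multiple_of_step(self):
        rng = np.random.default_rng(6)
        tight = self.co_expressed(40, 80, seed=6, noise=0.05)
        loose = np.abs(rng.normal(1, 0.5, (40, 80)))
        m = log_matrix(np.vstack([tight, loose]))
        cfg = CorrelationConfig(max_correlated_genes=50)
        _, rho = correlated_gene_search(m, list(m.gene_ids), cfg)
        steps = round((rho - cfg.rho_start) / cfg.rho_step)
        assert rho == pytest.approx(cfg.rho_start + steps * cfg.rho_step)

    def test_planted_modules_recovered_without_noise_genes(self, small_fixture, small_normalized):
        cfg = CorrelationConfig()
        variable = variable_gene_filter(small_normalized, cfg)
        modules, rho = correlated_gene_search(small_normalized, variable, cfg)
        found = {g for mod in modules for g in mod.genes}
        planted = set().union(*small_fixture.markers.values())
        recovered = len(found & planted) / len(planted)
        assert recovered >= 0.9
        assert len(found - planted) == 0  # no pure-noise genes


class TestGuideSelection:
    def modules_from(self, m, groups):
        return [GeneModule(id=i, genes=list(g)) for i, g in enumerate(groups)]

    def corr_genes(self, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(3, 1, 50).clip(0.1)
        a = base + rng.normal(0, 0.1, 50)  # best medoid
        b = base + rng.normal(0, 0.5, 50)
        c = base + rng.normal(0, 0.5, 50)
        return log_matrix(np.abs(np.vstack([a, b, c])), genes=["A", "B", "C"])

    def test_medoid_gene_is_guide(self):
        m = self.corr_genes()
        mods = self.modules_from(m, [["A", "B", "C"]])
        assert select_guide_genes(mods, m) == ["A"]

    def test_cell_cycle_medoid_drops_module_when_excluding(self):
        m = self.corr_genes()
        mods = self.modules_from(m, [["A", "B", "C"]])
        cfg = CorrelationConfig(exclude_cell_cycle=True, cell_cycle_list=frozenset({"A"}))
        with pytest.raises(ValueError, match="dropped"):
            select_guide_genes(mods, m, cfg)

    def test_single_gene_module_guides_itself(self):
        m = self.corr_genes()
        mods = self.modules_from(m, [["B"]])
        assert select_guide_genes(mods, m) == ["B"]


class TestGuide3:
    def test_guides_include_themselves_and_uncorrelated_excluded(self):
        rng = np.random.default_rng(8)
        base = rng.normal(3, 1, 40).clip(0.1)
        other = rng.normal(3, 1, 40).clip(0.1)
        noise = rng.random(40) * 0.01
        m = log_matrix(
            np.abs(np.vstack([base, base + rng.normal(0, 0.1, 40), other, noise])),
            genes=["guideA", "friendA", "guideB", "noiseG"],
        )
        g3 = guide3_matrix(m, ["guideA", "guideB"], list(m.gene_ids), rho_final=0.4)
        assert {"guideA", "guideB", "friendA"} <= set(g3.gene_ids)
        assert "noiseG" not in g3.gene_ids

    def test_cell_set_preserved(self, small_normalized):
        cfg = CorrelationConfig()
        g3, _ = run_feature_selection(small_normalized, cfg)
        assert sorted(g3.cell_ids) == sorted(small_normalized.cell_ids)

    def test_end_to_end_deterministic(self, small_normalized):
        g3a, rho_a = run_feature_selection(small_normalized)
        g3b, rho_b = run_feature_selection(small_normalized)
        assert rho_a == rho_b
        assert g3a.gene_ids == g3b.gene_ids
        assert g3a.cell_ids == g3b.cell_ids
        np.testing.assert_array_equal(g3a.values, g3b.values)
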