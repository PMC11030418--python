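"""Graph construction, residuals, spatial statistics, module detection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from spotmodules import simulate as sim
from spotmodules import spatial as sp


def _grid_positions(rows, cols):
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _single_tissue_graph(rows=20, cols=20, k=6):
    pos = _grid_positions(rows, cols)
    return sp.build_knn_graph(pos, np.array(["t"] * len(pos)), k)


class TestKnnGraph:
    def test_interior_spot_gets_grid_neighbors(self):
        g = _single_tissue_graph(9, 9, k=6)
        center = 4 * 9 + 4
        nb = set(g.neighbors[center])
        rook = {center - 9, center + 9, center - 1, center + 1}
        assert rook <= nb and len(nb) == 6
        # remaining two are diagonal (distance sqrt(2))
        pos = _grid_positions(9, 9)
        d = np.linalg.norm(pos[list(nb)] - pos[center], axis=1)
        assert sorted(d)[:4] == [1, 1, 1, 1] and max(d) == pytest.approx(np.sqrt(2))

    def test_no_cross_tissue_edges(self):
        pos = np.vstack([_grid_positions(5, 5), _grid_positions(5, 5)])
        tissues = np.array(["a"] * 25 + ["b"] * 25)
        g = sp.build_knn_graph(pos, tissues, k=4)
        for i in range(50):
            assert all(tissues[j] == tissues[i] for j in g.neighbors[i])

    def test_partitioning_equals_coordinate_shifting(self):
        """Per-tissue partitioning and the +1000 coordinate-shift trick give
        identical edge sets."""
        pos = np.vstack([_grid_positions(6, 6), _grid_positions(6, 6)])
        tissues = np.array(["a"] * 36 + ["b"] * 36)
        g1 = sp.build_knn_graph(pos, tissues, k=6)
        shifted = pos.copy()
        shifted[36:] += 1000.0
        g2 = sp.build_knn_graph(shifted, np.array(["all"] * 72), k=6)
        for i in range(72):
            assert set(g1.neighbors[i]) == set(g2.neighbors[i])

    def test_small_tissue_errors(self):
        pos = _grid_positions(2, 3)
        with pytest.raises(ValueError, match="need > k"):
            sp.build_knn_graph(pos, np.array(["t"] * 6), k=6)


class TestResiduals:
    def test_counts_proportional_to_depth_give_zero(self):
        d = np.array([100, 200, 400, 300])
        p = np.array([0.5, 0.3, 0.2])
        counts = np.outer(d, p)
        x = sp.standardized_residuals(counts, d)
        assert np.allclose(x, 0.0)

    def test_poisson_variance_close_to_one(self):
        rng = np.random.default_rng(0)
        d = rng.integers(500, 2000, size=1000).astype(float)
        p = rng.dirichlet(np.ones(40))
        counts = rng.poisson(np.outer(d, p))
        counts[:, counts.sum(axis=0) == 0] += 1
        x = sp.standardized_residuals(counts, d)
        v = x.var(axis=0)
        assert 0.8 < v.mean() < 1.2 and (np.abs(v - 1) < 0.35).mean() > 0.9

    def test_spot_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(30, 8)) + 1
        x = sp.standardized_residuals(counts)
        perm = rng.permutation(30)
        assert np.allclose(sp.standardized_residuals(counts[perm]), x[perm])

    def test_zero_gene_errors(self):
        counts = np.ones((5, 3))
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="zero-total genes"):
            sp.standardized_residuals(counts)


class TestAutocorrelation:
    def test_zero_residual_gene_is_null(self):
        g = _single_tissue_graph(10, 10)
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 3))
        X[:, 0] = 0.0
        ac = sp.autocorrelation(X, g, n_perm=200, seed=0)
        assert ac.iloc[0]["H"] == 0.0 and ac.iloc[0]["Z"] == 0.0

    def test_planted_gradient_is_detected(self):
        """A smooth gradient gene on a 20x20 grid reaches Z > 5 and
        FDR < 0.01 for every one of 20 seeds."""
        g = _single_tissue_graph(20, 20)
        grad = _grid_positions(20, 20)[:, 1] / 19.0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 20))
            X[:, 0] = 2.0 * (grad - grad.mean()) + 0.3 * rng.normal(size=400)
            ac = sp.autocorrelation(X, g, n_perm=200, seed=seed)
            assert ac.iloc[0]["Z"] > 5 and ac.iloc[0]["fdr"] < 0.01

    def test_permutation_p_matches_exhaustive_enumeration(self):
        """On a 5-spot toy graph the Monte-Carlo permutation p equals the
        exact p over all 120 within-tissue permutations, within binomial
        error."""
        pos = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0]], dtype=float)
        g = sp.build_knn_graph(pos, np.array(["t"] * 5), k=2)
        x = np.array([1.3, 0.9, -0.4, -1.1, 0.2])
        A = g.adjacency()
        kp1 = g.k + 1

        def stat(v):
            return float(v @ (A @ v)) / kp1

        h_obs = stat(x)
        exact_ge = sum(stat(x[list(perm)]) >= h_obs
                       for perm in itertools.permutations(range(5)))
        p_exact = exact_ge / 120.0
        n_perm = 4000
        ac = sp.autocorrelation(x[:, None], g, n_perm=n_perm, seed=3,
                                min_tissue_spots=5)
        p_mc = ac.iloc[0]["p_perm"]
        tol = 4 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 2 / n_perm
        assert abs(p_mc - p_exact) < tol

    def test_small_tissue_guard(self):
        pos = _grid_positions(3, 3)
        g = sp.build_knn_graph(pos, np.array(["t"] * 9), k=2)
        with pytest.raises(ValueError, match="fewer than"):
            sp.autocorrelation(np.ones((9, 2)), g, n_perm=100, seed=0)

    def test_null_calibration_fdr(self):
        """Exchangeable input: the share of FDR<0.05 discoveries stays at or
        below the nominal level (20 seeds pooled)."""
        g = _single_tissue_graph(15, 15)
        hits, total = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            d = rng.integers(800, 1200, size=225).astype(float)
            p = rng.dirichlet(np.ones(80))
            counts = rng.poisson(np.outer(d, p))
            keep = counts.sum(axis=0) > 0
            X = sp.standardized_residuals(counts[:, keep], d)
            ac = sp.autocorrelation(X, g, n_perm=100, seed=seed)
            hits += int((ac["fdr"] < 0.05).sum())
            total += len(ac)
        se = np.sqrt(0.05 * 0.95 / total)
        assert hits / total <= 0.05 + 2 * se


class TestGeneSelection:
    def _acorr(self, z, fdr, genes):
        return pd.DataFrame({"Z": z, "fdr": fdr},
                            index=pd.Index(genes, name="gene"))

    def test_fdr_boundary_is_strict(self):
        ac = self._acorr([9.0, 8.0], [0.01, 0.005], ["tf1", "tf2"])
        assert sp.select_module_genes(ac, ["tf1", "tf2"]) == ["tf2"]

    def test_non_tf_excluded(self):
        ac = self._acorr([9.0, 2.0], [0.001, 0.001], ["geneX", "tf1"])
        assert sp.select_module_genes(ac, ["tf1"]) == ["tf1"]

    def test_top_n_rule(self):
        genes = [f"tf{i:03d}" for i in range(600)]
        z = np.linspace(600, 1, 600)
        ac = self._acorr(z, np.zeros(600), genes)
        out = sp.select_module_genes(ac, genes, top_n=500)
        assert len(out) == 500 and out[0] == "tf000" and "tf599" not in out


class TestLocalCorrelation:
    def test_diagonal_equals_autocorrelation_exactly(self, scenario):
        ac_h = scenario.acorr.loc[scenario.lc.genes, "H"].to_numpy()
        assert np.array_equal(np.diag(scenario.lc.C), ac_h)

    def test_white_noise_pairs_are_null(self):
        g = _single_tissue_graph(15, 15)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(225, 30))
        lc = sp.local_correlation(X, g, np.arange(30), n_perm=200, seed=4)
        iu = np.triu_indices(30, k=1)
        assert (np.abs(lc.Z[iu]) < 3).mean() >= 0.95

    def test_duplicated_gene_matches_self_correlation(self):
        g = _single_tissue_graph(15, 15)
        rng = np.random.default_rng(5)
        grad = _grid_positions(15, 15)[:, 0] / 14.0
        sig = 2.0 * (grad - grad.mean()) + 0.2 * rng.normal(size=225)
        X = np.column_stack([sig, sig.copy(), rng.normal(size=225)])
        lc = sp.local_correlation(X, g, np.arange(3), n_perm=400, seed=5)
        assert lc.Z[0, 1] == pytest.approx(lc.Z[0, 0], rel=0.1)

    def test_fewer_than_two_genes_errors(self):
        g = _single_tissue_graph(5, 5, k=3)
        with pytest.raises(ValueError, match="at least 2"):
            sp.local_correlation(np.ones((25, 3)), g, [0], n_perm=10, seed=0)


def _block_localcorr(sizes, z_in=10.0, z_out=0.0, noise_genes=0):
    G = sum(sizes) + noise_genes
    Z = np.full((G, G), z_out)
    start = 0
    for s in sizes:
        Z[start:start + s, start:start + s] = z_in
        start += s
    np.fill_diagonal(Z, z_in)
    genes = [f"g{i:03d}" for i in range(G)]
    return sp.LocalCorr(genes=genes, C=Z.copy(), Z=Z, p=stats.norm.sf(Z))


class TestDetectModules:
    def test_three_planted_blocks_recovered(self):
        """Block-diagonal Z: detected modules coincide with the connected
        components of the thresholded Z matrix (separable case oracle)."""
        lc = _block_localcorr([20, 20, 20])
        mod = sp.detect_modules(lc)
        assert mod.n_modules == 3
        adj = sparse.csr_matrix(lc.Z > 5)
        _, comp = connected_components(adj, directed=False)
        for c in range(3):
            assigned = set(mod.assignments.iloc[np.flatnonzero(comp == c)])
            assert len(assigned) == 1 and assigned != {-1}

    def test_small_block_dissolved(self):
        lc = _block_localcorr([10], noise_genes=8)
        mod = sp.detect_modules(lc, min_gene_threshold=15, core_only=True)
        assert mod.n_modules == 0
        assert (mod.assignments == -1).all()

    def test_gene_without_significant_pair_unassigned(self):
        lc = _block_localcorr([20], noise_genes=5)
        mod = sp.detect_modules(lc)
        assert mod.n_modules == 1
        assert (mod.assignments.iloc[20:] == -1).all()

    def test_no_significant_pairs_returns_empty(self):
        lc = _block_localcorr([16], z_in=0.5, z_out=0.0)
        mod = sp.detect_modules(lc)
        assert mod.n_modules == 0


class TestModuleScores:
    def test_identical_genes_give_shared_profile(self):
        g = _single_tissue_graph(8, 8, k=4)
        rng = np.random.default_rng(6)
        base = rng.normal(size=64)
        expr = np.column_stack([base] * 3)
        mod = sp.ModuleResult(pd.Series([1, 1, 1], index=["a", "b", "c"]))
        scores = sp.module_scores(expr, ["a", "b", "c"], mod, g)
        zs = (base - base.mean()) / base.std()
        smoothed = (g.adjacency() @ zs) / (g.k + 1)
        assert np.allclose(scores[1].to_numpy(), smoothed)

    def test_constant_expression_scores_zero(self):
        g = _single_tissue_graph(8, 8, k=4)
        expr = np.ones((64, 2)) * 3.3
        mod = sp.ModuleResult(pd.Series([1, 1], index=["a", "b"]))
        scores = sp.module_scores(expr, ["a", "b"], mod, g)
        assert np.allclose(scores[1], 0.0)

    def test_planted_patch_module_higher_inside(self, scenario):
        """Smoothed module scores are higher inside the planted patch than
        outside for each recovered tumor module."""
        truth, cfg = scenario.truth, scenario.cfg
        expr = np.log2(scenario.tum[:, scenario.expressed]
                       / np.maximum(scenario.tum[:, scenario.expressed].sum(1, keepdims=True), 1)
                       * 1e4 + 1)
        scores = sp.module_scores(expr, scenario.genes, scenario.modules, scenario.graph)
        fields = truth.module_field_values
        planted = [set(g) for c, g in truth.planted_modules if c == "tumor"]
        for mid, genes in scenario.modules.module_genes().items():
            overlap = [len(set(genes) & s) for s in planted]
            m = int(np.argmax(overlap))
            if overlap[m] < 10:
                continue
            inside = fields[:, m] > 0.2
            s = scores[mid].to_numpy()
            assert s[inside].mean() > s[~inside].mean()


def test_exchangeable_noise_yields_zero_modules():
    """With no planted signal the full detection chain returns no modules in
    at least 19 of 20 seeds (FDR 0.05 calibration of the module stage)."""
    g = _single_tissue_graph(12, 12, k=6)
    zero_mod = 0
    for seed in range(20):
        rng = np.random.default_rng(200 + seed)
        d = rng.integers(800, 1200, size=144).astype(float)
        p = rng.dirichlet(np.ones(40))
        counts = rng.poisson(np.outer(d, p))
        keep = counts.sum(axis=0) > 0
        X = sp.standardized_residuals(counts[:, keep], d)
        lc = sp.local_correlation(X, g, np.arange(min(30, keep.sum())),
                                  n_perm=100, seed=seed)
        mod = sp.detect_modules(lc)
        zero_mod += int(mod.n_modules == 0)
    assert zero_mod >= 19
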