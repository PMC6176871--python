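"""Signed-hybrid network, confidence pruning, tree-cut modules, NMF consensus."""

import numpy as np
import pandas as pd
import pytest

from stromatlas import coexpression_consensus as cc
from stromatlas import synthdata


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(10, dtype=float)
        expr = np.vstack([x, 2 * x + 1])
        a = cc.signed_hybrid_adjacency(expr, beta=4)
        assert a[0, 1] == pytest.approx(1.0)

    def test_negative_correlation_is_zeroed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        noise = rng.normal(0, 0.1, 200)
        expr = np.vstack([x, -0.8 * x + noise * np.sqrt(1 - 0.64)])
        a = cc.signed_hybrid_adjacency(expr, beta=4)
        assert a[0, 1] == 0.0

    def test_soft_power_applied(self):
        # construct two genes with exact correlation 0.5
        n = 400
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(0, 1, (2, n))
        # orthonormalize then mix for an exact r
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean() - z1 * (z2 @ z1) / (z1 @ z1) * 1.0
        z2 /= z2.std()
        y = 0.5 * z1 + np.sqrt(1 - 0.25) * z2
        a = cc.signed_hybrid_adjacency(np.vstack([z1, y]), beta=4)
        assert a[0, 1] == pytest.approx(0.5 ** 4, abs=1e-6)

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(2)
        a = cc.signed_hybrid_adjacency(rng.normal(0, 1, (30, 50)), beta=4)
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)
        assert a.min() >= 0 and a.max() <= 1

    def test_zero_variance_gene_warns(self):
        expr = np.vstack([np.ones(10), np.arange(10, dtype=float)])
        with pytest.warns(UserWarning, match="zero-variance"):
            a = cc.signed_hybrid_adjacency(expr, beta=2)
        assert a[0, 1] == 0.0


class TestConfidencePrune:
    def _expr(self, co_cells):
        # two genes exceeding threshold together in exactly `co_cells` cells
        expr = np.zeros((2, 10))
        expr[0, :co_cells] = 9.0
        expr[1, :co_cells] = 9.0
        expr[0, 8] = 9.0  # high-confidence in one gene only
        return expr

    @pytest.mark.parametrize("co_cells,removed", [(0, True), (2, True),
                                                  (3, False)])
    def test_min_cells_rule(self, co_cells, removed):
        dis = np.full((2, 2), 0.3)
        np.fill_diagonal(dis, 0.0)
        out = cc.confidence_prune(dis, self._expr(co_cells),
                                  hi_conf_expr=6.0, hi_conf_min_cells=3)
        assert (out[0, 1] == 1.0) == removed

    def test_zero_threshold_keeps_everything(self):
        rng = np.random.default_rng(0)
        expr = rng.uniform(1, 10, (5, 20))
        dis = rng.uniform(0, 1, (5, 5))
        dis = (dis + dis.T) / 2
        np.fill_diagonal(dis, 0)
        out = cc.confidence_prune(dis, expr, hi_conf_expr=0.0,
                                  hi_conf_min_cells=3)
        assert np.array_equal(out, dis)


class TestDynamicTreeModules:
    def _block_dissim(self, sizes, within=0.2):
        n = sum(sizes)
        d = np.ones((n, n))
        start = 0
        for s in sizes:
            d[start:start + s, start:start + s] = within
            start += s
        np.fill_diagonal(d, 0.0)
        return d

    def test_two_perfect_blocks(self):
        mods = cc.dynamic_tree_modules(self._block_dissim([60, 60]))
        assert len(mods.module_sizes) == 2
        assert sorted(mods.module_sizes.values()) == [60, 60]

    def test_min_size_larger_than_gene_count(self):
        with pytest.warns(UserWarning):
            mods = cc.dynamic_tree_modules(
                self._block_dissim([10]),
                cc.NetworkParams(min_module_size=30))
        assert (mods.module_of == 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_planted_modules_recovered(self, seed):
        from sklearn.metrics import adjusted_rand_score
        expr, truth = synthdata.simulate_gene_modules(seed=seed)
        a = cc.signed_hybrid_adjacency(expr, 4)
        mods = cc.dynamic_tree_modules(cc.adjacency_dissimilarity(a))
        assert adjusted_rand_score(truth, mods.module_of) >= 0.9

    def test_deep_split_monotone_in_module_count(self):
        expr, _ = synthdata.simulate_gene_modules(seed=0)
        dis = cc.adjacency_dissimilarity(cc.signed_hybrid_adjacency(expr, 4))
        counts = [len(cc.dynamic_tree_modules(
            dis, cc.NetworkParams(deep_split=ds)).module_sizes)
            for ds in (0, 2, 4)]
        assert counts[0] <= counts[1] <= counts[2]


class TestConsensus:
    def test_single_run_consensus_is_binary(self):
        rng = np.random.default_rng(0)
        X = np.abs(rng.normal(2, 1, (40, 30)))
        cons = cc.nmf_consensus(X, [2, 3, 4], n_runs=1, seed=0, max_iter=100)
        for C in cons.consensus.values():
            off = C[~np.eye(len(C), dtype=bool)]
            assert set(np.unique(off)) <= {0.0, 1.0}

    def test_perfect_block_consensus_metrics(self):
        C = np.zeros((40, 40))
        C[:20, :20] = 1.0
        C[20:, 20:] = 1.0
        coph, sil, disp, labels = cc._consensus_metrics(C, 2)
        assert coph == pytest.approx(1.0)
        assert disp == pytest.approx(1.0)
        assert len(set(labels)) == 2

    def test_all_half_consensus_has_zero_dispersion(self):
        C = np.full((30, 30), 0.5)
        np.fill_diagonal(C, 1.0)
        _, _, disp, _ = cc._consensus_metrics(C, 2)
        assert disp == pytest.approx(0.0, abs=1e-12)

    def test_consensus_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(1)
        X = np.abs(rng.normal(2, 1, (30, 25)))
        cons = cc.nmf_consensus(X, [2, 3, 4], n_runs=5, seed=0, max_iter=100)
        for C in cons.consensus.values():
            assert np.allclose(C, C.T)
            assert np.allclose(np.diag(C), 1.0)
            assert C.min() >= 0 and C.max() <= 1

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cc.nmf_consensus(np.array([[1.0, -1.0]]).T, [2], n_runs=1)

    def test_planted_clusters_peak_cophenetic_at_true_rank(self):
        rng = np.random.default_rng(3)
        X = np.zeros((40, 100))  # genes x cells, 4 planted cell clusters
        for k in range(4):
            X[k * 10:(k + 1) * 10, k * 25:(k + 1) * 25] = 5.0
        X = np.abs(X + rng.normal(0, 0.5, X.shape))
        cons = cc.nmf_consensus(X, range(2, 7), n_runs=20, seed=0,
                                max_iter=150)
        m = cons.metrics.set_index("rank")
        assert m["cophenetic"].idxmax() == 4
        assert cons.chosen_rank == 4


class TestRankSelect:
    def _metrics(self, coph, sil, disp, rss=None):
        n = len(coph)
        return pd.DataFrame({
            "rank": np.arange(2, 2 + n), "cophenetic": coph,
            "silhouette": sil, "dispersion": disp,
            "rss": rss if rss is not None else np.linspace(10, 1, n)})

    def test_decreasing_metrics_fall_back_to_smallest(self):
        v = [0.9, 0.8, 0.7, 0.6]
        with pytest.warns(UserWarning, match="local maximum"):
            assert cc.rank_select(self._metrics(v, v, v)) == 2

    def test_single_interior_peak(self):
        v = [0.5, 0.6, 0.9, 0.7, 0.6]
        assert cc.rank_select(self._metrics(v, v, v)) == 4

    def test_fewer_than_three_ranks_warns(self):
        with pytest.warns(UserWarning):
            assert cc.rank_select(self._metrics([0.5, 0.6], [0.5, 0.6],
                                                [0.5, 0.6])) == 2


class TestPermuteControl:
    def test_marginals_conserved(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (20, 50))
        P = cc.permute_control(X, seed=1)
        assert np.allclose(np.sort(P, axis=1), np.sort(X, axis=1))

    def test_correlations_destroyed(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 300)
        X = base[None, :] + rng.normal(0, 0.2, (30, 300))
        P = cc.permute_control(X, seed=0)
        r = np.corrcoef(P)
        off = np.abs(r[np.triu_indices(30, 1)])
        assert off.mean() < 2 / np.sqrt(300)

    def test_seed_reproducible(self):
        X = np.random.default_rng(2).normal(0, 1, (10, 40))
        assert np.array_equal(cc.permute_control(X, 5),
                              cc.permute_control(X, 5))
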