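"""Batch entropy, pseudo-bulk, quantile normalization, EB batch adjustment,
cluster trees, composition summaries."""

import numpy as np
import pandas as pd
import pytest

from stromatlas import integration_diag as idg
from stromatlas.integration_diag import EntropyParams


class TestEntropyValue:
    @pytest.mark.parametrize("counts,B,expected", [
        ([100, 0], 2, 0.0),
        ([50, 50], 2, 1.0),
        ([75, 25], 2, 0.8113),
        ([40, 30, 30], 3, 0.9912),
    ])
    def test_exact_values(self, counts, B, expected):
        assert idg.normalized_entropy(counts, B) == pytest.approx(expected,
                                                                  abs=5e-5)


class TestBatchEntropy:
    def _mixed(self, seed=0, n=400):
        rng = np.random.default_rng(seed)
        coords = rng.normal(0, 1, (n, 2))
        batches = rng.choice(["b1", "b2"], n)
        return coords, batches

    def test_well_mixed_overlaps_negative_control(self):
        coords, batches = self._mixed()
        clusters = (coords[:, 0] > 0).astype(str)
        out = idg.batch_entropy(coords, batches,
                                EntropyParams(n_boot=30, seed=0),
                                cluster_labels=clusters)
        lo, hi = np.quantile(out["negative_control"], [0.05, 0.95])
        assert lo <= out["observed"].mean() <= hi
        assert out["positive_control"].mean() < out["negative_control"].mean()

    def test_separated_batches_score_low(self):
        rng = np.random.default_rng(1)
        coords = np.vstack([rng.normal(0, 0.3, (150, 2)),
                            rng.normal(8, 0.3, (150, 2))])
        batches = np.array(["a"] * 150 + ["b"] * 150)
        out = idg.batch_entropy(coords, batches,
                                EntropyParams(n_boot=20, seed=0))
        assert out["observed"].mean() < 0.1
        assert out["negative_control"].mean() > 0.9

    def test_single_batch_rejected(self):
        with pytest.raises(ValueError):
            idg.batch_entropy(np.random.rand(50, 2), ["a"] * 50)

    def test_oversized_neighborhood_clamped(self):
        coords, batches = self._mixed(n=60)
        with pytest.warns(UserWarning, match="clamped"):
            idg.batch_entropy(coords, batches,
                              EntropyParams(neighborhood_size=100,
                                            n_boot=2, seed=0))


class TestPseudobulk:
    def test_hand_checked_means(self):
        expr = np.array([[1., 3., 5., 7.],
                         [0., 2., 4., 6.],
                         [1., 1., 1., 1.]])
        pb = idg.pseudobulk(expr, ["g1", "g1", "g2", "g2"])
        assert list(pb["g1"]) == [2.0, 1.0, 1.0]
        assert list(pb["g2"]) == [6.0, 5.0, 1.0]
        assert pb.attrs["group_sizes"] == {"g1": 2, "g2": 2}

    def test_single_cell_group_is_that_cell(self):
        expr = np.random.default_rng(0).normal(0, 1, (5, 3))
        pb = idg.pseudobulk(expr, ["a", "b", "b"])
        assert np.allclose(pb["a"], expr[:, 0])


class TestQuantileNormalize:
    def test_reference_column_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (50, 3)), columns=list("abc"))
        out = idg.quantile_normalize_to_reference(df, "b")
        assert np.allclose(out["b"], df["b"])

    def test_columns_inherit_reference_marginal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(0, 1, (80, 3)), columns=list("abc"))
        out = idg.quantile_normalize_to_reference(df, "a")
        for col in "bc":
            assert np.allclose(np.sort(out[col]), np.sort(df["a"]))

    def test_tie_maps_to_midrank_average(self):
        df = pd.DataFrame({"ref": [1.0, 2.0, 3.0], "x": [5.0, 5.0, 9.0]})
        out = idg.quantile_normalize_to_reference(df, "ref")
        # tied values at ranks 1 and 2 -> (1 + 2) / 2 = 1.5
        assert list(out["x"]) == [1.5, 1.5, 3.0]

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (40, 4)), columns=list("abcd"))
        once = idg.quantile_normalize_to_reference(df, "a")
        twice = idg.quantile_normalize_to_reference(once, "a")
        assert np.allclose(once, twice)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            idg.quantile_normalize_to_reference(
                pd.DataFrame({"a": [1.0]}), "zzz")


class TestEBBatchAdjust:
    def _shifted(self, delta=3.0, n=50, g=200, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(5, 1, (g, 1))
        b1 = base + rng.normal(0, 0.5, (g, n))
        b2 = base + delta + rng.normal(0, 0.5, (g, n))
        return np.hstack([b1, b2]), ["a"] * n + ["b"] * n

    def test_single_batch_is_identity_with_warning(self):
        M = np.random.default_rng(0).normal(0, 1, (10, 6))
        with pytest.warns(UserWarning):
            out = idg.eb_batch_adjust(M, ["x"] * 6)
        assert np.allclose(out, M)

    def test_planted_shift_removed(self):
        M, batches = self._shifted()
        out = idg.eb_batch_adjust(M, batches).to_numpy()
        diff = np.abs(out[:, :50].mean(axis=1) - out[:, 50:].mean(axis=1))
        assert np.median(diff) < 0.1

    def test_batch_f_statistic_reduced(self):
        from scipy.stats import f_oneway
        M, batches = self._shifted()
        out = idg.eb_batch_adjust(M, batches).to_numpy()
        f_before = np.median([f_oneway(r[:50], r[50:])[0] for r in M])
        f_after = np.median([f_oneway(r[:50], r[50:])[0] for r in out])
        assert f_before / max(f_after, 1e-12) >= 5

    def test_matches_reference_combat_implementation(self):
        import anndata as ad
        import scanpy as sc
        M, batches = self._shifted(g=100, n=30, seed=3)
        ours = idg.eb_batch_adjust(M, batches).to_numpy()
        A = ad.AnnData(M.T.copy())
        A.obs["batch"] = pd.Categorical(batches)
        sc.pp.combat(A)
        # both solve the same EB fixed point; stopping rules differ slightly
        assert np.allclose(ours, A.X.T, atol=5e-3)


class TestTrees:
    def test_first_merge_is_closest_pair(self):
        df = pd.DataFrame({"A": [0.0, 0], "B": [1.0, 0], "C": [10.0, 0]})
        Z, labels, newick = idg.complete_linkage_tree(df)
        # first merge joins columns 0 and 1 (A and B)
        assert sorted(Z[0, :2].astype(int)) == [0, 1]
        assert newick.endswith(";") and "A" in newick

    def test_duplicated_column_merges_at_zero_height(self):
        df = pd.DataFrame({"A": [1.0, 2], "B": [1.0, 2], "C": [9.0, 9]})
        Z, _, _ = idg.complete_linkage_tree(df)
        assert Z[0, 2] == 0.0

    def test_newick_parses_with_skbio(self):
        import io

        import skbio
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(0, 1, (20, 4)),
                          columns=["w", "x", "y", "z"])
        _, _, newick = idg.complete_linkage_tree(df)
        tree = skbio.TreeNode.read(io.StringIO(newick))
        assert {t.name for t in tree.tips()} == {"w", "x", "y", "z"}

    def test_cluster_tree_leaf_count_and_node_oobe(self):
        rng = np.random.default_rng(1)
        expr = np.hstack([rng.normal(0, 0.3, (30, 40)),
                          rng.normal(4, 0.3, (30, 40)),
                          rng.normal(8, 0.3, (30, 40))])
        labels = np.repeat(["x", "y", "z"], 40)
        Z, clusters = idg.cluster_mean_tree(expr, labels)
        assert len(clusters) == 3
        from stromatlas.crossspecies_rf import RFParams
        oob = idg.node_oobe(expr, labels, Z, clusters,
                            RFParams(ntree=100, seed=0))
        assert (oob["oob_error"].dropna() < 0.05).all()

    def test_indistinguishable_clusters_have_chance_oobe(self):
        rng = np.random.default_rng(2)
        expr = rng.normal(0, 1, (20, 120))
        labels = np.repeat(["p", "q"], 60)  # same distribution
        Z, clusters = idg.cluster_mean_tree(expr, labels)
        from stromatlas.crossspecies_rf import RFParams
        oob = idg.node_oobe(expr, labels, Z, clusters,
                            RFParams(ntree=200, seed=0))
        assert abs(oob["oob_error"].iloc[0] - 0.5) < 0.15


class TestComposition:
    def test_fractions_sum_to_one_and_planted_expansion_detected(self):
        rng = np.random.default_rng(0)
        labels, samples = [], []
        comp = {"ctrl": [0.34, 0.33, 0.33], "dss": [0.47, 0.265, 0.265]}
        cond = {}
        for cdx, (cname, fracs) in enumerate(comp.items()):
            for rep in range(3):
                sid = f"{cname}{rep}"
                cond[sid] = cname
                n = 400
                jitter = rng.normal(0, 0.01, 3)
                p = np.clip(np.asarray(fracs) + jitter, 0.01, None)
                p /= p.sum()
                counts = rng.multinomial(n, p)
                for cl, k in enumerate(counts):
                    labels += [f"c{cl}"] * k
                    samples += [sid] * k
        out = idg.composition_summary(labels, samples, cond)
        assert out.loc[out["p_value"].idxmin(), "cluster"] == "c0"

    def test_identical_compositions_not_significant(self):
        labels = ["a"] * 50 + ["b"] * 50
        out = idg.composition_summary(
            labels * 4,
            sum([[f"s{i}"] * 100 for i in range(4)], []),
            {"s0": "x", "s1": "x", "s2": "y", "s3": "y"})
        assert (out["p_value"].fillna(1.0) > 0.9).all()

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="without condition"):
            idg.composition_summary(["a", "b"], ["s1", "s2"], {"s1": "x"})
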