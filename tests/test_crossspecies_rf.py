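"""Ortholog bijection, SMOTE balancing, RFE, forest training and evaluation."""

import numpy as np
import pandas as pd
import pytest

from stromatlas import crossspecies_rf as rf


def toy_map():
    rows = [
        ("hA", "mA", "one2one", 80.0, 78.0),    # kept
        ("hB", "mB", "one2one", 70.0, 90.0),    # min identity below 75
        ("hC", "mC", "one2one", 95.0, 92.0),    # kept
        ("hD", "mD1", "one2many", 99.0, 99.0),  # multi-mapping
        ("hD", "mD2", "one2many", 99.0, 99.0),
        ("hE", "mE", "many2many", 99.0, 99.0),
        ("hF", "mE", "many2many", 99.0, 99.0),
    ]
    return pd.DataFrame(rows, columns=["gene_A", "gene_B", "homology_class",
                                       "pct_identity_AtoB",
                                       "pct_identity_BtoA"])


class TestFilterOrthologs:
    def test_exact_planted_bijection(self):
        out = rf.filter_orthologs(toy_map())
        assert sorted(zip(out["gene_A"], out["gene_B"])) == \
            [("hA", "mA"), ("hC", "mC")]

    def test_applying_twice_is_identity(self):
        once = rf.filter_orthologs(toy_map())
        twice = rf.filter_orthologs(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_output_is_bijection_on_planted_simulation(self):
        from stromatlas import synthdata
        cfg = synthdata.SimConfig(
            n_genes=400, n_cells_per_cluster=[30] * 3, n_clusters=3,
            ambient_barcodes=0, control_cell_fraction=0.0, seed=0)
        _, _, omap, _ = synthdata.simulate_two_species(cfg, n_orthologs=100)
        out = rf.filter_orthologs(omap)
        assert out["gene_A"].is_unique and out["gene_B"].is_unique
        assert (out["homology_class"] == "one2one").all()
        assert (out[["pct_identity_AtoB", "pct_identity_BtoA"]].min(axis=1)
                >= 75).all()


class TestBalanceClasses:
    def test_counts_exactly_equal(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (70, 4))
        y = np.array(["a"] * 40 + ["b"] * 20 + ["c"] * 10)
        Xb, yb = rf.balance_classes(X, y, smote_k=3, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert len(set(counts)) == 1 and counts[0] == 20  # median class size

    def test_synthetic_points_lie_on_segments(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (34, 3))
        y = np.array(["big"] * 30 + ["small"] * 4)
        Xb, yb = rf.balance_classes(X, y, target_per_class=20,
                                    smote_k=2, seed=0)
        small_orig = X[30:]
        synth = Xb[yb == "small"][4:]
        for p in synth:
            on_segment = False
            for i in range(4):
                for j in range(4):
                    if i == j:
                        continue
                    d = small_orig[j] - small_orig[i]
                    t = (p - small_orig[i]) @ d / (d @ d)
                    if 0 <= t <= 1 and np.allclose(small_orig[i] + t * d, p,
                                                   atol=1e-9):
                        on_segment = True
            assert on_segment

    def test_identical_minority_points_give_identical_synthetics(self):
        X = np.vstack([np.zeros((2, 3)), np.ones((10, 3))])
        y = np.array(["m"] * 2 + ["M"] * 10)
        Xb, yb = rf.balance_classes(X, y, target_per_class=6, smote_k=1,
                                    seed=0)
        assert np.allclose(Xb[yb == "m"], 0.0)

    def test_singleton_class_rejected(self):
        X = np.random.rand(5, 2)
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="2 members"):
            rf.balance_classes(X, y)

    def test_oversized_k_clamped_with_warning(self):
        X = np.random.default_rng(0).normal(0, 1, (13, 2))
        y = np.array(["a"] * 10 + ["b"] * 3)
        with pytest.warns(UserWarning, match="clamped"):
            rf.balance_classes(X, y, target_per_class=10, smote_k=5, seed=0)


class TestRFE:
    def test_single_size_schedule_returns_everything(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (60, 12))
        y = np.repeat(["a", "b"], 30)
        params = rf.RFParams(ntree=50, seed=0)
        sel, survey = rf.rfe_select(X, y, params, sizes_schedule=[12])
        assert len(sel) == 12 and len(survey) == 1

    def test_informative_features_survive(self):
        rng = np.random.default_rng(1)
        n = 90
        y = np.repeat(["a", "b", "c"], n // 3)
        info = np.zeros((n, 5))
        for i, cls in enumerate(["a", "b", "c"]):
            info[y == cls] = i * 3
        info += rng.normal(0, 0.3, info.shape)
        X = np.hstack([info, rng.normal(0, 1, (n, 60))])
        params = rf.RFParams(ntree=100, cv_folds=5, seed=0)
        sel, _ = rf.rfe_select(X, y, params, sizes_schedule=[65, 30, 10, 5],
                               feature_names=[f"f{i}" for i in range(65)])
        assert set(sel) >= {"f0", "f1", "f2", "f3", "f4"}

    def test_random_labels_score_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (80, 20))
        y = rng.choice(["a", "b"], 80)
        params = rf.RFParams(ntree=50, cv_folds=5, seed=0)
        _, survey = rf.rfe_select(X, y, params, sizes_schedule=[20, 10])
        assert abs(survey["cv_mean"].max() - 0.5) < 0.2


class TestTrainAndClassify:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.5, (40, 6)),
                       rng.normal(3, 0.5, (40, 6))])
        y = np.repeat(["a", "b"], 40)
        return X, y

    def test_separable_blobs_low_oob(self):
        X, y = self._blobs()
        model = rf.train_rf(X, y, rf.RFParams(ntree=200, seed=0))
        assert model.oob_error < 0.05

    def test_seed_determinism(self):
        X, y = self._blobs()
        q = pd.DataFrame(X, columns=list(range(6)))
        a = rf.train_rf(X, y, rf.RFParams(ntree=100, seed=1)).predict(q)
        b = rf.train_rf(X, y, rf.RFParams(ntree=100, seed=1)).predict(q)
        assert np.array_equal(a, b)

    def test_mtry_is_floor_sqrt(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 100))
        y = np.repeat(["a", "b"], 20)
        model = rf.train_rf(X, y, rf.RFParams(ntree=20, seed=0))
        assert model.metadata["mtry"] == 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rf.train_rf(np.random.rand(10, 3), ["a"] * 10)

    def test_confusion_rows_sum_to_one_and_identity_when_perfect(self):
        X, y = self._blobs()
        model = rf.train_rf(X, y, rf.RFParams(ntree=200, seed=0))
        q = pd.DataFrame(X, columns=model.features)
        _, conf, aucs = rf.classify_and_confuse(model, q, y)
        assert np.allclose(conf.sum(axis=1), 1.0)
        assert np.allclose(np.diag(conf.loc[model.classes, model.classes]), 1.0)
        assert np.allclose(aucs, 1.0)

    def test_missing_features_reported(self):
        X, y = self._blobs()
        model = rf.train_rf(X, y, rf.RFParams(ntree=20, seed=0))
        q = pd.DataFrame(X[:, :3], columns=model.features[:3])
        with pytest.raises(ValueError, match="lacks"):
            model.predict(q)


class TestSpecificity:
    def test_constant_feature_is_half_everywhere(self):
        expr = np.ones((1, 30))
        spec = rf.feature_specificity(expr, ["a"] * 15 + ["b"] * 15)
        assert (spec.to_numpy() == 0.5).all()

    def test_exclusive_feature_pattern(self):
        expr = np.zeros((1, 30))
        expr[0, :10] = 5.0
        labels = ["c"] * 10 + ["d"] * 10 + ["e"] * 10
        spec = rf.feature_specificity(expr, labels)
        assert spec.loc[0, "c"] == 1.0
        assert (spec.loc[0, ["d", "e"]] < 0.5).all()

    def test_identical_profiles_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        spec = pd.DataFrame(rng.uniform(0, 1, (20, 3)),
                            columns=["c1", "c2", "c3"])
        corr = rf.specificity_correlation(spec, spec.copy())
        assert np.allclose(corr, 1.0)
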