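"""Size factors, log transform, control genes, RUV, regression, HVG rules."""

import numpy as np
import pandas as pd
import pytest

from stromatlas import normalization
from stromatlas.matrix_io import CountMatrix
from stromatlas.normalization import HVGParams

from conftest import make_expr


class TestSizeFactors:
    def test_identical_cells_give_unit_factors(self):
        vals = np.tile(np.arange(1, 51)[:, None], (1, 60))
        cm = CountMatrix(vals, [f"g{i}" for i in range(50)],
                         [f"g{i}" for i in range(50)],
                         [f"c{i}" for i in range(60)])
        f = normalization.pooled_size_factors(cm)
        assert np.allclose(f, 1.0, atol=1e-6)

    def test_scaled_profiles_recover_scalars(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 40, 80)
        scalars = np.tile([1, 2, 4], 20)
        cm = CountMatrix(np.outer(base, scalars),
                         [f"g{i}" for i in range(80)],
                         [f"g{i}" for i in range(80)],
                         [f"c{i}" for i in range(60)])
        f = normalization.pooled_size_factors(cm)
        # oracle: in the scaling-only regime factors equal total-count ratios
        oracle = scalars / scalars.mean()
        assert np.allclose(f / f.mean(), oracle, rtol=0.05)

    def test_too_few_cells_falls_back_to_library_size(self):
        cm = CountMatrix(np.array([[1, 2], [3, 4]]), ["a", "b"], ["a", "b"],
                         ["c1", "c2"])
        with pytest.warns(UserWarning, match="library-size"):
            f = normalization.pooled_size_factors(cm)
        assert np.allclose(f, normalization.library_size_factors(cm))


class TestLogNormalize:
    @pytest.mark.parametrize("count,factor,expected", [
        (0, 1.0, 0.0),
        (3, 1.0, 2.0),
        (7, 2.0, np.log2(4.5)),
    ])
    def test_closed_form(self, count, factor, expected):
        cm = CountMatrix(np.array([[count]]), ["g"], ["g"], ["c"])
        expr = normalization.lognormalize(cm, np.array([factor]))
        assert expr.values[0, 0] == pytest.approx(expected)

    def test_monotone_and_invertible(self, droplet_sim):
        _, counts, _ = droplet_sim
        sub = counts.subset_cells(np.arange(30))
        f = normalization.library_size_factors(sub)
        expr = normalization.lognormalize(sub, f)
        back = (2.0 ** expr.values - 1.0) * f
        assert np.allclose(back, sub.dense(), atol=1e-9)

    def test_nonpositive_factor_rejected(self, toy_counts):
        with pytest.raises(ValueError):
            normalization.lognormalize(toy_counts, np.array([1.0, 0.0, 1.0]))


class TestControlGenes:
    def test_zero_variance_gene_is_control(self):
        rng = np.random.default_rng(0)
        V = rng.normal(3, 1, (120, 50))
        V[7] = 2.0
        _, controls = normalization.select_control_genes(make_expr(V))
        assert controls[7]

    def test_planted_technical_genes_recovered(self):
        # 200 purely technical genes among 2000: no biological factor,
        # variance falls below the trend fitted to the bulk
        rng = np.random.default_rng(1)
        n_cells = 150
        factor = rng.normal(0, 1, n_cells)
        bio = 3.0 + 1.5 * np.outer(rng.normal(1, 0.3, 1800), factor) \
            + rng.normal(0, 0.5, (1800, n_cells))
        tech = 3.0 + rng.normal(0, 0.5, (200, n_cells))
        expr = make_expr(np.vstack([bio, tech]))
        _, controls = normalization.select_control_genes(expr)
        assert controls[1800:].mean() >= 0.8


class TestRUV:
    def test_k_zero_is_identity(self):
        expr = make_expr(np.random.default_rng(0).normal(0, 1, (150, 40)))
        out = normalization.ruv_remove(expr, np.ones(150, bool), 0)
        assert np.array_equal(out.values, expr.values)

    def test_planted_factor_removed(self):
        rng = np.random.default_rng(2)
        n_genes, n_cells = 300, 120
        w = rng.normal(0, 1, n_cells)
        load = rng.normal(1, 0.2, n_genes)
        V = 4.0 + np.outer(load, w) + rng.normal(0, 0.3, (n_genes, n_cells))
        expr = make_expr(V)
        controls = np.zeros(n_genes, bool)
        controls[:60] = True
        out = normalization.ruv_remove(expr, controls, 1)
        cors = [abs(np.corrcoef(out.values[g], w)[0, 1])
                for g in range(60, n_genes)]
        assert np.mean(cors) < 0.2

    def test_constant_controls_rejected(self):
        V = np.random.default_rng(0).normal(0, 1, (100, 30))
        V[:20] = 1.0
        with pytest.raises(ValueError, match="constant"):
            normalization.ruv_remove(make_expr(V), np.arange(100) < 20, 1)

    def test_k_exceeding_controls_rejected(self):
        expr = make_expr(np.random.default_rng(0).normal(0, 1, (100, 30)))
        with pytest.raises(ValueError, match="exceeds"):
            normalization.ruv_remove(expr, np.arange(100) < 3, 5)


class TestRegressOut:
    def test_orthogonal_covariate_leaves_gene_unchanged(self):
        n = 52
        cov = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        gene = np.tile([1.0, -1.0], n // 2)  # orthogonal to cov (26 even)
        expr = make_expr(gene[None, :])
        out = normalization.regress_out(expr, pd.DataFrame({"c": cov}))
        assert np.allclose(out.values[0], gene)

    def test_gene_equal_to_covariate_becomes_flat(self):
        cov = np.arange(30, dtype=float)
        out = normalization.regress_out(make_expr(cov[None, :]),
                                        pd.DataFrame({"c": cov}))
        assert np.allclose(out.values[0], cov.mean())

    def test_planted_batch_shift_removed(self):
        rng = np.random.default_rng(3)
        n = 200
        batch = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        V = rng.normal(0, 0.5, (100, n))
        V[:, batch == "b"] += 2.0
        out = normalization.regress_out(make_expr(V),
                                        pd.DataFrame({"batch": batch}))
        diff = np.abs(out.values[:, batch == "a"].mean(axis=1)
                      - out.values[:, batch == "b"].mean(axis=1))
        assert diff.max() < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        V = rng.normal(0, 1, (50, 60))
        cov = pd.DataFrame({"x": rng.normal(0, 1, 60)})
        once = normalization.regress_out(make_expr(V), cov)
        twice = normalization.regress_out(once, cov)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        V = rng.normal(0, 1, (20, 40))
        x = rng.normal(0, 1, 40)
        with pytest.warns(UserWarning, match="collinear"):
            normalization.regress_out(make_expr(V),
                                      pd.DataFrame({"x": x, "y": 2 * x}))


class TestVariableGenes:
    def test_detection_floor_excludes_regardless_of_sd(self):
        V = np.zeros((1, 30))
        V[0, :2] = [8.0, 1.0]  # detected in only 2 cells, huge SD
        mask = normalization.select_variable_genes(make_expr(V))
        assert not mask[0]

    def test_constant_nonzero_gene_excluded(self):
        V = np.full((1, 30), 2.0)
        assert not normalization.select_variable_genes(make_expr(V))[0]

    def test_planted_markers_selected(self):
        # default-scale simulation: nearly all planted markers pass the
        # mean/SD window
        from stromatlas import synthdata
        cfg = synthdata.SimConfig(ambient_barcodes=0,
                                  control_cell_fraction=0.0, seed=0)
        counts, truth = synthdata.simulate_droplet_experiment(cfg)
        expr = normalization.lognormalize(
            counts, normalization.library_size_factors(counts))
        mask = normalization.select_variable_genes(expr)
        gid = {g: i for i, g in enumerate(expr.gene_ids)}
        marker_idx = [gid[g] for mk in truth.marker_genes.values()
                      for g in mk]
        assert mask[marker_idx].mean() >= 0.95

    def test_mean_window_is_exclusive(self):
        V = np.zeros((2, 30))
        V[0, :10] = 4.0      # non-zero mean exactly at the upper bound
        V[1, :10] = 0.0125   # exactly at the lower bound
        mask = normalization.select_variable_genes(
            make_expr(V), HVGParams(mean_low=0.0125, mean_high=4.0))
        assert not mask.any()
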