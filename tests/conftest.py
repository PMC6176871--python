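import numpy as np
import pytest

from stromatlas import normalization, synthdata
from stromatlas.matrix_io import CountMatrix, ExprMatrix


@pytest.fixture(scope="session")
def droplet_sim():
    """Small droplet experiment with ambient barcodes and a control cluster."""
    cfg = synthdata.SimConfig(
        n_genes=600, n_cells_per_cluster=[80] * 3, n_clusters=3,
        ambient_barcodes=800, cell_mean_umi=4000, ambient_mean_umi=100,
        seed=7)
    counts, truth = synthdata.simulate_droplet_experiment(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def clustered_expr():
    """Log expression with 3 planted clusters (no ambient, no controls)."""
    cfg = synthdata.SimConfig(
        n_genes=800, n_cells_per_cluster=[60] * 3, n_clusters=3,
        ambient_barcodes=0, control_cell_fraction=0.0,
        cell_mean_umi=2000, seed=3)
    counts, truth = synthdata.simulate_droplet_experiment(cfg)
    factors = normalization.library_size_factors(counts)
    expr = normalization.lognormalize(counts, factors)
    return counts, expr, truth


@pytest.fixture
def toy_counts():
    vals = np.array([[3, 0, 1], [0, 5, 2], [1, 1, 0], [4, 0, 0]])
    return CountMatrix(vals, [f"g{i}" for i in range(4)],
                       [f"G{i}" for i in range(4)], ["a", "b", "c"])


def make_expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExprMatrix(values,
                      [f"{prefix}{i}" for i in range(values.shape[0])],
                      [f"c{j}" for j in range(values.shape[1])])
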