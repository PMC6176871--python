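"""PCA with jackstraw PC significance, SNN graph community clustering, and
best-of-N t-SNE selection by Kullback-Leibler divergence."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
from scipy.stats import binomtest
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .matrix_io import ExprMatrix

log = logging.getLogger("stromatlas")


@dataclass
class Embedding:
    coords: np.ndarray              # cells x d
    method: str
    explained_variance: np.ndarray | None = None
    kl_divergence: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


def _scale_cells_by_genes(expr: ExprMatrix, variable_genes=None) -> np.ndarray:
    """Cells x genes matrix, genes centered and unit-scaled."""
    sub = expr if variable_genes is None else expr.subset_genes(variable_genes)
    X = sub.values.T.copy()
    X -= X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return X / sd


def pca(expr: ExprMatrix, n_components: int = 10,
        variable_genes=None) -> Embedding:
    """PCA on centered, unit-scaled genes with a deterministic sign convention
    (the largest-magnitude loading of each component is positive)."""
    X = _scale_cells_by_genes(expr, variable_genes)
    if n_components > min(X.shape):
        raise ValueError(f"n_components={n_components} exceeds min dim {min(X.shape)}")
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    for k in range(n_components):
        j = np.argmax(np.abs(model.components_[k]))
        if model.components_[k, j] < 0:
            model.components_[k] *= -1
            coords[:, k] *= -1
    return Embedding(coords, "pca", explained_variance=model.explained_variance_,
                     extras={"loadings": model.components_})


def jackstraw_pcs(expr: ExprMatrix, n_pc: int = 10, perm_fraction: float = 0.01,
                  n_reps: int = 100, alpha: float = 0.05,
                  variable_genes=None, seed: int = 0) -> list:
    """Significant principal components by the jackstraw permutation test.

    Each repetition permutes a small random fraction of genes across cells
    and recomputes the decomposition; the permuted genes' squared loadings
    form the null for per-gene PC association.  A PC is significant when the
    fraction of genes with association p-value below ``alpha`` exceeds
    ``alpha`` by a one-sided binomial test.  The largest prefix of
    significant PCs (PC1..PCk) is returned as a list of 0-based indices.
    """
    if n_reps < 20:
        raise ValueError("n_reps must be >= 20 for a usable null")
    rng = np.random.default_rng(seed)
    X = _scale_cells_by_genes(expr, variable_genes)
    n_cells, n_genes = X.shape
    n_pc = min(n_pc, min(X.shape) - 1)
    model = PCA(n_components=n_pc, svd_solver="full").fit(X)
    obs = model.components_.T ** 2              # genes x PCs
    m = max(1, int(round(perm_fraction * n_genes)))
    null = [[] for _ in range(n_pc)]
    for _ in range(n_reps):
        pick = rng.choice(n_genes, m, replace=False)
        Xp = X.copy()
        for g in pick:
            Xp[:, g] = Xp[rng.permutation(n_cells), g]
        comp = PCA(n_components=n_pc, svd_solver="full").fit(Xp).components_
        for k in range(n_pc):
            null[k].extend((comp[k, pick] ** 2).tolist())
    sig = []
    for k in range(n_pc):
        nk = np.sort(np.asarray(null[k]))
        # every gene contributes to the observed component, so observed
        # loadings are slightly overfit relative to held-out permuted genes;
        # align the (mostly-null) bulk of both distributions by their medians
        scale = np.median(nk) / max(np.median(obs[:, k]), 1e-300)
        stat = obs[:, k] * min(scale, 1.0)
        # p-value per gene: fraction of null loadings at least as extreme
        p = 1.0 - np.searchsorted(nk, stat, side="left") / len(nk)
        hits = int((p < alpha).sum())
        test = binomtest(hits, n_genes, alpha, alternative="greater")
        sig.append(test.pvalue < 0.05)
    prefix = []
    for k, s in enumerate(sig):
        if not s:
            break
        prefix.append(k)
    log.info("jackstraw: %d significant PCs (prefix) of %d tested",
             len(prefix), n_pc)
    return prefix


def snn_graph(coords: np.ndarray, k_neighbors: int = 20,
              prune_jaccard: float = 1.0 / 15.0) -> igraph.Graph:
    """Shared-nearest-neighbor graph with Jaccard edge weights.

    Every pair of cells sharing at least one of their ``k_neighbors``
    nearest neighbors (self included) is a candidate edge; the weight is
    the Jaccard overlap of the two neighbor lists and edges below
    ``prune_jaccard`` are dropped.
    """
    import scipy.sparse as _sp

    n = coords.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be below the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k_neighbors)
    B = _sp.csr_matrix((np.ones(rows.size), (rows, idx.ravel())),
                       shape=(n, n))
    shared = (B @ B.T).tocoo()
    mask = shared.row < shared.col
    r, c, s = shared.row[mask], shared.col[mask], shared.data[mask]
    jac = s / (2 * k_neighbors - s)
    keep = jac >= prune_jaccard
    g = igraph.Graph(n=n, edges=list(zip(r[keep].tolist(), c[keep].tolist())))
    g.es["weight"] = jac[keep].tolist()
    return g


def graph_cluster(embedding: Embedding | np.ndarray, k_neighbors: int = 20,
                  resolution: float = 0.8, seed: int = 0) -> np.ndarray:
    """Modularity community detection on the SNN graph.

    Labels are renumbered by decreasing community size ("0" largest) and are
    deterministic for a fixed seed.
    """
    coords = embedding.coords if isinstance(embedding, Embedding) else embedding
    g = snn_graph(coords, k_neighbors)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=g.es["weight"] if g.ecount() else None,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1)
    raw = np.asarray(part.membership)
    order = np.argsort([-np.sum(raw == c) for c in np.unique(raw)], kind="stable")
    remap = {int(np.unique(raw)[o]): i for i, o in enumerate(order)}
    return np.array([str(remap[int(c)]) for c in raw], dtype=object)


def tsne_best_of(coords: np.ndarray, n_runs: int = 10,
                 perplexity: float = 30.0, seed: int = 0) -> Embedding:
    """Run t-SNE ``n_runs`` times from random initializations and keep the
    solution with the lowest final KL divergence; all KL values are logged
    in ``extras['kl_runs']``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    n = coords.shape[0]
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for {n} cells")
    best = None
    kls = []
    for r in range(n_runs):
        ts = TSNE(n_components=2, perplexity=perplexity, init="random",
                  random_state=seed + r)
        out = ts.fit_transform(coords)
        kls.append(float(ts.kl_divergence_))
        if best is None or kls[-1] < best.kl_divergence:
            best = Embedding(out, "tsne", kl_divergence=kls[-1])
    best.extras["kl_runs"] = kls
    log.info("tsne_best_of: KL per run %s -> selected %.4f", kls,
             best.kl_divergence)
    return best
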