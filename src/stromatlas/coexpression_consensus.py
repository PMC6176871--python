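"""C1-track clustering: signed-hybrid co-expression network with
high-confidence edge pruning and dynamic tree cut for gene modules, then NMF
consensus clustering of cells with rank selection and a permuted-data
control.

The network is built from Pearson correlations with negative values zeroed
("signed hybrid"), raised to a soft-thresholding power (default 4).  Edges
supported by too few cells with high-confidence detection of both genes are
pruned.  Genes are hierarchically clustered (average linkage on the
dissimilarity 1 - adjacency) and modules cut adaptively subject to a minimum
size.  Cells are then clustered by repeated randomly-initialized NMF of the
module-gene expression; co-assignment frequencies across runs form a
consensus matrix whose cophenetic correlation, silhouette width, dispersion
and RSS guide the choice of rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import NMF
from sklearn.metrics import silhouette_score

log = logging.getLogger("stromatlas")

#: deep-split aggressiveness -> dendrogram height quantile for branch cutting
DEEP_SPLIT_QUANTILE = {0: 0.64, 1: 0.73, 2: 0.82, 3: 0.91, 4: 0.95}


@dataclass
class NetworkParams:
    soft_power: float = 4.0
    hi_conf_expr: float = 6.0
    hi_conf_min_cells: int = 3
    deep_split: int = 3
    min_module_size: int = 30

    def validate(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.deep_split not in DEEP_SPLIT_QUANTILE:
            raise ValueError("deep_split must be in 0..4")


@dataclass
class GeneModuleSet:
    module_of: np.ndarray       # int per gene; 0 = unassigned
    gene_ids: np.ndarray | None = None

    @property
    def module_sizes(self) -> dict:
        labs, counts = np.unique(self.module_of[self.module_of > 0],
                                 return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def signed_hybrid_adjacency(expr: np.ndarray, beta: float = 4.0) -> np.ndarray:
    """a_ij = max(cor(i, j), 0) ** beta with unit diagonal.

    ``expr`` is genes x cells.  Zero-variance genes get zero correlation to
    everything (warning), hence adjacency 0 off-diagonal.
    """
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 cells for correlations")
    sd = expr.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance genes: correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(expr)
    r[np.isnan(r)] = 0.0
    a = np.clip(r, 0.0, None) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def adjacency_dissimilarity(adjacency: np.ndarray) -> np.ndarray:
    d = 1.0 - adjacency
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def confidence_prune(dissim: np.ndarray, expr: np.ndarray,
                     hi_conf_expr: float = 6.0,
                     hi_conf_min_cells: int = 3) -> np.ndarray:
    """Remove edges supported by too few high-confidence co-detections.

    A cell detects a gene with high confidence when its normalized
    expression exceeds ``hi_conf_expr``.  Gene pairs co-detected in fewer
    than ``hi_conf_min_cells`` such cells have their dissimilarity set to 1
    (edge absent).
    """
    H = (np.asarray(expr) > hi_conf_expr).astype(float)
    co = H @ H.T
    out = dissim.copy()
    weak = co < hi_conf_min_cells
    np.fill_diagonal(weak, False)
    out[weak] = 1.0
    return out


# ---------------------------------------------------------------------------
# dynamic tree cut ("tree" variant)
# ---------------------------------------------------------------------------

def dynamic_tree_modules(dissim: np.ndarray,
                         params: NetworkParams | None = None) -> GeneModuleSet:
    """Average-linkage clustering plus adaptive branch cutting.

    The dendrogram is cut at the merge-height quantile mapped from
    ``deep_split`` (more aggressive splits cut lower, yielding more and
    smaller modules).  Branches below the cut qualify as modules when they
    hold at least ``min_module_size`` genes and their mean internal
    dissimilarity stays below the cut height; all other genes get label 0.
    Module labels are contiguous, ordered by decreasing size.
    """
    params = params or NetworkParams()
    params.validate()
    n = dissim.shape[0]
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: nothing assigned")
        return GeneModuleSet(np.zeros(n, dtype=int))
    condensed = squareform(np.clip(dissim, 0.0, 1.0), checks=False)
    Z = sch.linkage(condensed, method="average")
    heights = Z[:, 2]
    # cut at a fixed fraction of the merge-height range: quantiles of the
    # raw height distribution collapse when background merges pile up near
    # the maximum dissimilarity
    q = DEEP_SPLIT_QUANTILE[params.deep_split]
    cut_h = float(heights.min() + q * (heights.max() - heights.min()))
    raw = sch.fcluster(Z, t=cut_h, criterion="distance")
    labels = np.zeros(n, dtype=int)
    kept = []
    for cl in np.unique(raw):
        members = np.flatnonzero(raw == cl)
        if members.size < params.min_module_size:
            continue
        sub = dissim[np.ix_(members, members)]
        scatter = sub[np.triu_indices(members.size, 1)].mean()
        if scatter >= cut_h:
            continue
        # core membership: genes loosely attached to the branch (mean
        # dissimilarity to the rest well above the branch core) go to the
        # unassigned pool, as in adaptive branch pruning
        mean_d = (sub.sum(axis=1)) / max(members.size - 1, 1)
        core = np.median(mean_d)
        members = members[mean_d <= (core + cut_h) / 2.0]
        if members.size >= params.min_module_size:
            kept.append((members.size, members))
    kept.sort(key=lambda t: -t[0])
    for i, (_, members) in enumerate(kept, start=1):
        labels[members] = i
    log.info("dynamic_tree_modules: %d modules (cut height %.3f)",
             len(kept), cut_h)
    return GeneModuleSet(labels)


# ---------------------------------------------------------------------------
# NMF consensus clustering
# ---------------------------------------------------------------------------

@dataclass
class ConsensusClustering:
    rank_range: list
    consensus: dict                       # rank -> cells x cells matrix
    metrics: pd.DataFrame                 # per-rank quality metrics
    chosen_rank: int | None = None
    labels: np.ndarray | None = None
    control_metrics: pd.DataFrame | None = None
    labels_by_rank: dict = field(default_factory=dict)


def _consensus_metrics(C: np.ndarray, k: int):
    """Cophenetic correlation, silhouette on 1-C, dispersion, and labels."""
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 1.0)
    condensed = squareform(D, checks=False)
    Z = sch.linkage(condensed, method="average")
    if condensed.std() < 1e-12:
        coph = 1.0 if np.allclose(condensed, 0.0) else 0.0
    else:
        coph = float(sch.cophenet(Z, condensed)[0])
        if np.isnan(coph):
            coph = 1.0
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) > 1:
        sil = float(silhouette_score(D, labels, metric="precomputed"))
    else:
        sil = 0.0
    off = ~np.eye(C.shape[0], dtype=bool)
    disp = float(np.mean(4.0 * (C[off] - 0.5) ** 2))
    return coph, sil, disp, labels


def nmf_consensus(expr_modules: np.ndarray, rank_range, n_runs: int = 50,
                  seed: int = 0, max_iter: int = 300,
                  tol: float = 1e-5) -> ConsensusClustering:
    """Consensus clustering of cells by repeated random-start NMF.

    ``expr_modules`` is the non-negative module-gene x cell expression.  Per
    rank, ``n_runs`` KL-divergence multiplicative-update factorizations are
    run from random initializations; each run assigns every cell to its
    arg-max basis component and the consensus matrix records co-assignment
    frequencies.  Rank-quality metrics (cophenetic correlation, average
    silhouette width on 1 - consensus, dispersion, best-fit RSS) are
    computed per rank and the rank chosen by :func:`rank_select`.
    """
    est = NMFConsensusClustering(rank_range=list(rank_range), n_runs=n_runs,
                                 random_state=seed, max_iter=max_iter, tol=tol)
    est.fit(np.asarray(expr_modules).T)
    return ConsensusClustering(
        rank_range=list(rank_range), consensus=est.consensus_,
        metrics=est.metrics_, chosen_rank=est.chosen_rank_,
        labels=est.labels_, labels_by_rank=est.labels_by_rank_)


class NMFConsensusClustering(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator for NMF consensus clustering.

    Parameters follow the consensus methodology: ``n_runs`` random-start
    KL-divergence factorizations per candidate rank.  ``fit(X)`` takes the
    cells-by-genes non-negative matrix and exposes ``labels_``,
    ``chosen_rank_``, ``consensus_`` (rank -> matrix) and ``metrics_``.
    """

    def __init__(self, rank_range=(2, 3, 4, 5, 6), n_runs: int = 50,
                 random_state: int = 0, max_iter: int = 300,
                 tol: float = 1e-5):
        self.rank_range = rank_range
        self.n_runs = n_runs
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if np.any(X < 0):
            raise ValueError("NMF input must be non-negative")
        ranks = list(self.rank_range)
        n_cells = X.shape[0]
        if any(k < 2 or k > n_cells - 1 for k in ranks):
            raise ValueError("ranks must lie within [2, n_cells - 1]")
        rng = np.random.default_rng(self.random_state)
        consensus, rows = {}, []
        self.labels_by_rank_ = {}
        for k in ranks:
            C = np.zeros((n_cells, n_cells))
            best_rss = np.inf
            for _ in range(self.n_runs):
                rs = int(rng.integers(0, 2**31 - 1))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = NMF(n_components=k, init="random", solver="mu",
                                beta_loss="kullback-leibler",
                                max_iter=self.max_iter, tol=self.tol,
                                random_state=rs)
                    W = model.fit_transform(X)
                assign = np.argmax(W, axis=1)
                C += (assign[:, None] == assign[None, :])
                rss = float(np.sum((X - W @ model.components_) ** 2))
                best_rss = min(best_rss, rss)
            C /= self.n_runs
            np.fill_diagonal(C, 1.0)
            coph, sil, disp, labels = _consensus_metrics(C, k)
            consensus[k] = C
            self.labels_by_rank_[k] = labels
            rows.append({"rank": k, "cophenetic": coph, "silhouette": sil,
                         "dispersion": disp, "rss": best_rss})
        self.consensus_ = consensus
        self.metrics_ = pd.DataFrame(rows)
        self.chosen_rank_ = rank_select(self.metrics_)
        self.labels_ = self.labels_by_rank_[self.chosen_rank_]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def rank_select(metrics: pd.DataFrame,
                control_metrics: pd.DataFrame | None = None) -> int:
    """Choose the factorization rank from the per-rank quality survey.

    The chosen rank is the smallest that is simultaneously a local maximum
    of cophenetic correlation, silhouette width and dispersion; among
    several simultaneous candidates the one nearest the RSS inflection
    (maximal absolute second difference) wins.  With no simultaneous local
    maximum the smallest surveyed rank is returned with a warning.
    """
    m = metrics.sort_values("rank").reset_index(drop=True)
    if len(m) < 3:
        warnings.warn("fewer than 3 ranks surveyed; returning the smallest")
        return int(m["rank"].iloc[0])
    ranks = m["rank"].to_numpy()

    def local_max(v):
        """Interior local maxima with a noise tolerance scaled to the
        metric's dynamic range over the survey (cophenetic correlation in
        particular saturates near 1, so absolute differences shrink while
        the profile shape stays informative)."""
        v = np.asarray(v, dtype=float)
        tol = max(1e-3, 0.05 * float(np.ptp(v)))
        out = np.zeros(len(v), bool)
        for i in range(1, len(v) - 1):
            out[i] = (v[i] >= v[i - 1] - tol) and (v[i] >= v[i + 1] - tol)
        return out

    cand = (local_max(m["cophenetic"]) & local_max(m["silhouette"])
            & local_max(m["dispersion"]))
    if not cand.any():
        warnings.warn("no simultaneous local maximum of the three metrics; "
                      "returning the smallest surveyed rank")
        return int(ranks[0])
    idx = np.flatnonzero(cand)
    if idx.size == 1:
        return int(ranks[idx[0]])
    rss = m["rss"].to_numpy(dtype=float)
    second = np.abs(np.diff(rss, 2))
    inflect = int(1 + np.argmax(second)) if second.size else int(idx[0])
    best = min(idx, key=lambda i: (abs(i - inflect), i))
    return int(ranks[best])


def permute_control(expr: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independently permute each gene's values across cells.

    Destroys gene-gene and gene-cell structure while conserving every
    gene's marginal distribution — the randomized control for the rank
    survey.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(expr, dtype=float).copy()
    for g in range(out.shape[0]):
        out[g] = out[g, rng.permutation(out.shape[1])]
    return out
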