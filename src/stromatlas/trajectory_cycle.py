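"""Diffusion maps, diffusion pseudotime, and gene-pair cell-cycle scoring.

The diffusion map uses a Gaussian kernel on the k-nearest-neighbor graph
with a per-cell local bandwidth, density-normalized (alpha = 1) before
row-normalization of the transition operator.  Diffusion pseudotime is the
Euclidean distance from a root cell in the space of components scaled by
lambda / (1 - lambda).  Cell-cycle phase is read from marker gene *pairs*
whose within-cell expression ordering is phase-specific: the G1 and G2M
scores are the fractions of each phase's pairs satisfied, and the phase
call follows the half-majority rule (S when neither or both dominate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("stromatlas")


@dataclass
class DiffusionResult:
    eigenvalues: np.ndarray          # decreasing, trivial lambda=1 removed
    components: np.ndarray           # cells x d
    pseudotime: np.ndarray | None = None
    root_cell: int | None = None
    k_nn: int = 500
    sigma: str = "local"
    extras: dict = field(default_factory=dict)


def diffusion_map(X: np.ndarray, k_nn: int = 500,
                  n_components: int = 10) -> DiffusionResult:
    """Diffusion map of cells x feature data with local kernel bandwidths.

    The bandwidth of cell i is its distance to the ``ceil(k_nn / 100)``-th
    (at least 5th) nearest neighbor; the kernel is
    ``exp(-d_ij^2 / (2 s_i s_j))`` on the symmetrized k-NN graph, corrected
    for sampling density (alpha = 1) and row-normalized.  The trivial
    stationary eigenvector is dropped; components are scaled eigenvectors
    of the transition operator, eigenvalues sorted decreasing in (0, 1].
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k_nn >= n:
        warnings.warn(f"k_nn={k_nn} clamped to {n - 1}")
        k_nn = n - 1
    nn = NearestNeighbors(n_neighbors=k_nn + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    k_sigma = min(max(5, int(np.ceil(k_nn / 100))), k_nn)
    sig = np.maximum(dist[:, k_sigma], 1e-12)

    rows = np.repeat(np.arange(n), k_nn)
    cols = idx[:, 1:].ravel()
    d2 = dist[:, 1:].ravel() ** 2
    w = np.exp(-d2 / (2.0 * sig[rows] * sig[cols]))
    W = sp.coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    W = W.maximum(W.T)                      # symmetric union kNN graph
    W = W + sp.identity(n, format="csr")

    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        warnings.warn(f"k-NN graph has {n_comp} connected components; "
                      "diffusion coordinates are per-component")
    q = np.asarray(W.sum(axis=1)).ravel()
    Dq = sp.diags(1.0 / q)
    K = Dq @ W @ Dq                         # alpha = 1 density correction
    d = np.asarray(K.sum(axis=1)).ravel()
    Dh = sp.diags(1.0 / np.sqrt(d))
    S = Dh @ K @ Dh                         # symmetric conjugate of P
    S = (S + S.T) / 2.0
    k_eig = min(n_components + 1, n - 1)
    if n <= 500:
        evals, evecs = np.linalg.eigh(S.toarray())
        order = np.argsort(evals)[::-1][:k_eig]
        evals, evecs = evals[order], evecs[:, order]
    else:
        from scipy.sparse.linalg import eigsh
        evals, evecs = eigsh(S, k=k_eig, which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    psi = (Dh @ evecs)                      # right eigenvectors of P
    psi = psi / np.linalg.norm(psi, axis=0)
    # drop trivial eigenvectors (lambda ~ 1, one per connected component)
    trivial = evals > 1.0 - 1e-10
    lam = np.clip(evals[~trivial], 0.0, 1.0)[: n_components]
    comps = psi[:, ~trivial][:, : n_components]
    # deterministic sign: largest-magnitude entry positive
    for j in range(comps.shape[1]):
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] *= -1
    return DiffusionResult(lam, comps, k_nn=k_nn,
                           extras={"n_components_graph": n_comp,
                                   "trivial_multiplicity": int(trivial.sum())})


def diffusion_pseudotime(dmap: DiffusionResult, root_cell: int) -> np.ndarray:
    """Distance from the root in lambda/(1-lambda)-scaled component space.

    Components with eigenvalue numerically 1 are excluded from the scaling
    sum.  The root's pseudotime is exactly 0.
    """
    n = dmap.components.shape[0]
    if not 0 <= root_cell < n:
        raise ValueError("root cell outside the dataset")
    lam = dmap.eigenvalues
    usable = lam < 1.0 - 1e-10
    scale = lam[usable] / (1.0 - lam[usable])
    Z = dmap.components[:, usable] * scale
    d = np.linalg.norm(Z - Z[root_cell], axis=1)
    d[root_cell] = 0.0
    dmap.pseudotime = d
    dmap.root_cell = int(root_cell)
    return d


# ---------------------------------------------------------------------------
# gene-pair cell-cycle scoring
# ---------------------------------------------------------------------------

def train_cycle_pairs(expr: np.ndarray, phase_labels, gene_ids,
                      consistency: float = 0.7,
                      max_genes: int = 150) -> dict:
    """Learn phase-specific marker gene pairs from a labeled reference.

    A pair ``(g1, g2)`` is kept for phase P when ``expr(g1) > expr(g2)``
    holds in at least ``consistency`` of P cells and at most
    ``1 - consistency`` of non-P cells.  Only the ``max_genes`` most
    variable genes enter the pairwise search (the search is quadratic in
    genes).  Returns ``phase -> [(g_hi, g_lo), ...]`` without duplicates.
    """
    expr = np.asarray(expr, dtype=float)
    y = np.asarray(phase_labels)
    gene_ids = np.asarray(gene_ids)
    phases, counts = np.unique(y, return_counts=True)
    if len(phases) < 2 or counts.min() < 20:
        raise ValueError("need >= 2 phases with >= 20 cells each")
    var = expr.var(axis=1)
    top = np.argsort(var)[::-1][:max_genes]
    E = expr[top]
    pairs: dict = {}
    for ph in phases:
        m = y == ph
        inp = E[:, m]
        out = E[:, ~m]
        # frac[i, j] = fraction of cells with gene i > gene j
        gt_in = (inp[:, None, :] > inp[None, :, :]).mean(axis=2)
        gt_out = (out[:, None, :] > out[None, :, :]).mean(axis=2)
        ii, jj = np.nonzero((gt_in >= consistency)
                            & (gt_out <= 1.0 - consistency))
        found = []
        seen = set()
        for i, j in zip(ii, jj):
            key = (gene_ids[top[i]], gene_ids[top[j]])
            if key not in seen:
                seen.add(key)
                found.append(key)
        pairs[str(ph)] = found
    if all(len(v) == 0 for v in pairs.values()):
        raise ValueError("no qualifying pairs; try a lower consistency")
    return pairs


def score_cycle(expr: np.ndarray, pairs: dict, gene_ids) -> pd.DataFrame:
    """Per-cell G1/G2M scores and phase calls from marker gene pairs.

    The score for a phase is the fraction of its pairs with a strict
    ``g_hi > g_lo`` ordering; tied pairs leave the denominator.  Phase:
    G1 when g1 >= 0.5 > g2m; G2M when g2m >= 0.5 > g1; otherwise S (also
    when every pair is tied, score NaN).
    """
    expr = np.asarray(expr, dtype=float)
    pos = {g: i for i, g in enumerate(np.asarray(gene_ids))}
    n = expr.shape[1]

    def phase_score(plist):
        if not plist:
            return np.full(n, np.nan)
        wins = np.zeros(n)
        informative = np.zeros(n)
        for hi, lo in plist:
            a, b = expr[pos[hi]], expr[pos[lo]]
            wins += a > b
            informative += a != b
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(informative > 0, wins / informative, np.nan)

    g1 = phase_score(pairs.get("G1", []))
    g2m = phase_score(pairs.get("G2M", []))
    phase = np.where(np.isnan(g1) | np.isnan(g2m), "S",
                     np.where((g1 >= 0.5) & (g2m < 0.5), "G1",
                              np.where((g2m >= 0.5) & (g1 < 0.5), "G2M", "S")))
    return pd.DataFrame({"g1_score": g1, "g2m_score": g2m, "phase": phase})


def g2m_proportion_by_cluster(phases, clusters) -> pd.Series:
    """Fraction of G2M-phase cells per cluster, sorted decreasing."""
    df = pd.DataFrame({"phase": np.asarray(phases),
                       "cluster": np.asarray(clusters)})
    prop = df.groupby("cluster")["phase"].apply(lambda s: (s == "G2M").mean())
    return prop.sort_values(ascending=False)
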