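"""Batch-mixing entropy diagnostics, pseudo-bulk comparison utilities, and
cluster trees with node confidence.

Batch mixing is quantified by the normalized Shannon entropy of batch
proportions within fixed-size nearest-neighbor neighborhoods of randomly
picked cell locations, bootstrapped; a negative control shuffles batch
labels (no batch effect) and a positive control uses cluster labels as
batches (structure entirely batch-driven).  For comparison against bulk
references, clusters are collapsed to pseudo-bulk profiles, quantile
normalized against a reference column, and batch-adjusted by parametric
empirical Bayes (location/scale shrinkage).  Cluster relationships are
summarized by hierarchical trees over cluster average cells, with
out-of-bag error of a branch-classifying forest as per-node confidence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.stats import rankdata, ttest_ind
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger("stromatlas")


@dataclass
class EntropyParams:
    n_locations: int = 100
    neighborhood_size: int = 100
    n_boot: int = 100
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_locations, self.neighborhood_size, self.n_boot) < 1:
            raise ValueError("all entropy parameters must be >= 1")


def normalized_entropy(counts, n_categories: int | None = None) -> float:
    """-sum p ln p / ln(B) over category proportions; 0 when concentrated."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    B = n_categories if n_categories is not None else len(counts)
    if B < 2 or counts.size == 0:
        return 0.0
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(B))


def batch_entropy(coords: np.ndarray, batch_labels, params: EntropyParams
                  | None = None, cluster_labels=None) -> pd.DataFrame:
    """Entropy-of-mixing distributions: observed, negative, positive control.

    Per bootstrap, ``n_locations`` cells are sampled; the entropy of batch
    proportions within each cell's ``neighborhood_size`` nearest neighbors
    (embedding space) is averaged.  The negative control recomputes with
    uniformly shuffled batch labels; the positive control (supplied
    ``cluster_labels``) treats clusters as batches.  Returns a DataFrame
    with one row per bootstrap.
    """
    params = params or EntropyParams()
    params.validate()
    coords = np.asarray(coords, dtype=float)
    batches = np.asarray(batch_labels)
    n = coords.shape[0]
    if len(pd.unique(batches)) < 2:
        raise ValueError("need at least 2 batches")
    k = params.neighborhood_size
    if k >= n:
        warnings.warn(f"neighborhood_size={k} clamped to {n - 1}")
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    hoods = idx[:, 1:]
    rng = np.random.default_rng(params.seed)

    def mean_entropy(labels, locations):
        labs = np.asarray(labels)
        cats = pd.unique(labs)
        B = len(cats)
        code = pd.Categorical(labs, categories=cats).codes
        es = []
        for loc in locations:
            counts = np.bincount(code[hoods[loc]], minlength=B)
            es.append(normalized_entropy(counts, B))
        return float(np.mean(es))

    rows = []
    for b in range(params.n_boot):
        locs = rng.choice(n, params.n_locations, replace=False) \
            if params.n_locations <= n else rng.choice(n, params.n_locations)
        row = {"bootstrap": b,
               "observed": mean_entropy(batches, locs),
               "negative_control": mean_entropy(rng.permutation(batches), locs)}
        if cluster_labels is not None:
            row["positive_control"] = mean_entropy(cluster_labels, locs)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pseudo-bulk, quantile normalization, empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def pseudobulk(expr: np.ndarray, labels, gene_ids=None) -> pd.DataFrame:
    """Per-gene mean expression within each group (genes x groups)."""
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    out = pd.DataFrame(
        {g: expr[:, labels == g].mean(axis=1) for g in groups},
        index=(gene_ids if gene_ids is not None
               else np.arange(expr.shape[0])))
    out.attrs["group_sizes"] = {g: int((labels == g).sum()) for g in groups}
    return out


def quantile_normalize_to_reference(matrix: pd.DataFrame,
                                    reference_column) -> pd.DataFrame:
    """Map every column rank-wise onto the reference column's distribution.

    Each column's values are replaced by the reference's sorted values at
    the corresponding (mid)ranks; tied values receive the mean of the tied
    reference positions.  The reference column itself is unchanged and the
    transform is idempotent.
    """
    if reference_column not in matrix.columns:
        raise ValueError(f"reference column {reference_column!r} not in matrix")
    ref_sorted = np.sort(matrix[reference_column].to_numpy(dtype=float))
    m = len(ref_sorted)
    out = {}
    for col in matrix.columns:
        v = matrix[col].to_numpy(dtype=float)
        if len(v) != m:
            raise ValueError("column length mismatch")
        r = rankdata(v, method="average")      # 1-based midranks
        out[col] = np.interp(r, np.arange(1, m + 1), ref_sorted)
    return pd.DataFrame(out, index=matrix.index)


def eb_batch_adjust(matrix: pd.DataFrame | np.ndarray,
                    batch_labels) -> pd.DataFrame:
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Per gene the data are standardized against the grand mean and pooled
    variance; per-batch location (normal prior) and scale (inverse-gamma
    prior) parameters are shrunk toward their batch-wide moments by an
    iterative parametric EB solve, then removed and the data
    back-transformed.  A single batch returns the input with a warning.
    """
    df = pd.DataFrame(matrix).copy()
    X = df.to_numpy(dtype=float)
    batches = np.asarray(batch_labels)
    levels = pd.unique(batches)
    if len(levels) < 2:
        warnings.warn("single batch: nothing to adjust")
        return df
    for lev in levels:
        if (batches == lev).sum() < 2:
            raise ValueError(f"batch {lev!r} has fewer than 2 samples")
    n_genes, n_samples = X.shape
    design = np.column_stack([(batches == lev).astype(float)
                              for lev in levels])
    n_per = design.sum(axis=0)
    # gene-wise grand mean weighted by batch sizes, pooled variance
    beta = np.linalg.lstsq(design, X.T, rcond=None)[0]       # batch x gene
    grand = (n_per / n_samples) @ beta
    resid = X - (design @ beta).T
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.where(var_pooled > 0, var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)
    Z = (X - grand[:, None]) / sd[:, None]

    out = Z.copy()
    for bi, lev in enumerate(levels):
        m = batches == lev
        Zb = Z[:, m]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.where(delta_hat > 0, delta_hat, 1e-12)
        # parametric prior moments
        g_bar, t2 = gamma_hat.mean(), gamma_hat.var(ddof=1)
        d_bar, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        lam = (2 * s2 + d_bar ** 2) / max(s2, 1e-12)          # IG shape
        theta = (d_bar * s2 + d_bar ** 3) / max(s2, 1e-12)    # IG scale
        nb = int(m.sum())
        gamma_star, delta_star = gamma_hat.copy(), delta_hat.copy()
        for _ in range(30):
            g_new = (nb * t2 * gamma_hat + delta_star * g_bar) \
                / (nb * t2 + delta_star)
            ssq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ssq) / (nb / 2 + lam - 1)
            if (np.max(np.abs(g_new - gamma_star)) < 1e-8
                    and np.max(np.abs(d_new - delta_star)) < 1e-8):
                gamma_star, delta_star = g_new, d_new
                break
            gamma_star, delta_star = g_new, d_new
        out[:, m] = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
    adjusted = out * sd[:, None] + grand[:, None]
    return pd.DataFrame(adjusted, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = sch.to_tree(Z)
    labels = list(labels)

    def rec(node):
        if node.is_leaf():
            return str(labels[node.id])
        l = f"{rec(node.left)}:{max(node.dist - node.left.dist, 0):.6g}"
        r = f"{rec(node.right)}:{max(node.dist - node.right.dist, 0):.6g}"
        return f"({l},{r})"

    return rec(tree) + ";"


def complete_linkage_tree(matrix: pd.DataFrame, feature_subset=None):
    """Complete-linkage tree over columns (Euclidean on a feature subset).

    Returns ``(linkage matrix, column labels, newick string)``.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    sub = matrix.loc[feature_subset] if feature_subset is not None else matrix
    X = sub.to_numpy(dtype=float).T
    Z = sch.linkage(X, method="complete", metric="euclidean")
    return Z, list(matrix.columns), linkage_to_newick(Z, matrix.columns)


def cluster_mean_tree(expr: np.ndarray, labels, gene_mask=None,
                      method: str = "complete"):
    """Hierarchical tree over cluster average cells (variable genes)."""
    expr = np.asarray(expr, dtype=float)
    if gene_mask is not None:
        expr = expr[np.asarray(gene_mask)]
    labels = np.asarray(labels)
    clusters = list(pd.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    means = np.column_stack([expr[:, labels == c].mean(axis=1)
                             for c in clusters])
    Z = sch.linkage(means.T, method=method, metric="euclidean")
    return Z, clusters


def node_oobe(expr: np.ndarray, labels, Z: np.ndarray, clusters,
              params=None, gene_mask=None) -> pd.DataFrame:
    """Out-of-bag error of a left-vs-right forest at each internal tree node.

    For every internal node of the cluster tree, the member cells of the
    clusters under its left and right children are classified by a random
    forest; the OOB error measures how confidently cells separate at that
    split.  Nodes where either side has < 2 cells report NaN.
    """
    from sklearn.ensemble import RandomForestClassifier

    from .crossspecies_rf import RFParams
    params = params or RFParams()
    expr = np.asarray(expr, dtype=float)
    if gene_mask is not None:
        expr = expr[np.asarray(gene_mask)]
    labels = np.asarray(labels)
    tree = sch.to_tree(Z)
    rows = []

    def leaves(node):
        return [clusters[i] for i in node.pre_order(lambda x: x.id)]

    def walk(node):
        if node.is_leaf():
            return
        left, right = leaves(node.left), leaves(node.right)
        m_left = np.isin(labels, left)
        m_right = np.isin(labels, right)
        if m_left.sum() < 2 or m_right.sum() < 2:
            oob = np.nan
        else:
            X = expr[:, m_left | m_right].T
            y = np.where(m_left[m_left | m_right], "left", "right")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rf = RandomForestClassifier(
                    n_estimators=params.ntree, max_features="sqrt",
                    oob_score=True, random_state=params.seed,
                    n_jobs=1).fit(X, y)
            oob = 1.0 - float(rf.oob_score_)
        rows.append({"node_id": node.id, "left": ",".join(map(str, left)),
                     "right": ",".join(map(str, right)), "oob_error": oob})
        walk(node.left)
        walk(node.right)

    walk(tree)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cluster composition summaries
# ---------------------------------------------------------------------------

def composition_summary(labels, sample_ids, condition_of_sample: dict) -> pd.DataFrame:
    """Per-cluster cell fractions per replicate and a Welch t-test between
    conditions.

    ``condition_of_sample`` maps each sample/replicate id to its condition
    (exactly 2 conditions, >= 2 replicates each).  Fractions within a
    replicate sum to 1 across clusters.
    """
    labels = np.asarray(labels)
    samples = np.asarray(sample_ids)
    missing = set(pd.unique(samples)) - set(condition_of_sample)
    if missing:
        raise ValueError(f"samples without condition: {sorted(missing)}")
    conds = sorted(set(condition_of_sample.values()))
    if len(conds) != 2:
        raise ValueError("exactly 2 conditions required")
    frac = pd.crosstab(samples, labels, normalize="index")
    for c in conds:
        reps = [s for s in frac.index if condition_of_sample[s] == c]
        if len(reps) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 replicates")
    rows = []
    for cl in frac.columns:
        a = frac.loc[[s for s in frac.index if condition_of_sample[s] == conds[0]], cl]
        b = frac.loc[[s for s in frac.index if condition_of_sample[s] == conds[1]], cl]
        t = ttest_ind(a, b, equal_var=False)
        rows.append({"cluster": cl,
                     f"mean_{conds[0]}": float(a.mean()),
                     f"sd_{conds[0]}": float(a.std(ddof=1)),
                     f"mean_{conds[1]}": float(b.mean()),
                     f"sd_{conds[1]}": float(b.std(ddof=1)),
                     "p_value": float(t.pvalue)})
    return pd.DataFrame(rows)
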