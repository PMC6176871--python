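"""Normalization: size factors, log transform, technical-gene discovery,
control-gene factor removal, covariate regression, variable-gene selection.

Per-cell scaling factors come from a pooling/deconvolution estimator (ranked
cells on a ring, overlapping pools, per-cell factors solved by least
squares).  Counts are log2(x/f + 1)-transformed.  Technical "control" genes
are those whose total variance falls below a loess mean-variance trend; the
unwanted variation they capture is removed by regressing out their leading
singular vectors (RUV on control genes).  Library size, batch and cell-cycle
scores can be regressed out per gene.  Variable genes follow the
mean-of-nonzero / SD filter (0.0125 < mean < 4 and SD > 0.5, genes in >= 3
cells).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import lsqr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix_io import CountMatrix, ExprMatrix

log = logging.getLogger("stromatlas")

DEFAULT_POOL_SIZES = (21, 26, 31, 36, 41)


@dataclass
class MeanVarTrend:
    mean: np.ndarray
    fitted_variance: np.ndarray
    method: str = "loess"

    def __post_init__(self) -> None:
        self.fitted_variance = np.maximum(np.asarray(self.fitted_variance), 0.0)


@dataclass
class HVGParams:
    mean_low: float = 0.0125
    mean_high: float = 4.0
    sd_min: float = 0.5

    def validate(self) -> None:
        if not self.mean_low < self.mean_high:
            raise ValueError("mean_low must be below mean_high")


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def library_size_factors(counts: CountMatrix) -> np.ndarray:
    totals = counts.total_umis().astype(float)
    totals = np.where(totals > 0, totals, 1.0)
    return totals / totals.mean()


def pooled_size_factors(counts: CountMatrix,
                        pool_sizes=DEFAULT_POOL_SIZES,
                        clusters=None) -> np.ndarray:
    """Deconvolution size factors (pool-and-solve), normalized to unit mean.

    Cells are ranked by total count and laid on a ring; for each pool size,
    sums over overlapping windows are compared with a reference pseudo-cell
    (the average profile), giving one equation per pool in the unknown
    per-cell factors, solved jointly by sparse least squares.  When cluster
    labels are supplied the procedure runs within each cluster and factors
    are rescaled across clusters via the cluster pseudo-cells.  Fewer cells
    than the smallest pool, or non-positive estimates, fall back to
    library-size factors with a warning.
    """
    if clusters is not None:
        clusters = np.asarray(clusters)
        factors = np.empty(counts.n_cells)
        for cl in pd.unique(clusters):
            idx = np.flatnonzero(clusters == cl)
            sub = counts.subset_cells(idx)
            f = pooled_size_factors(sub, pool_sizes, clusters=None)
            # rescale by the cluster pseudo-cell depth so factors are
            # comparable across clusters
            f *= sub.total_umis().mean() / counts.total_umis().mean()
            factors[idx] = f
        return factors / factors.mean()

    n = counts.n_cells
    lib = library_size_factors(counts)
    if n < min(pool_sizes):
        warnings.warn("fewer cells than the smallest pool size; "
                      "using library-size factors")
        return lib
    X = np.asarray(counts.values.todense(), dtype=float)
    totals = X.sum(axis=0)
    # reference pseudo-cell: the average raw profile; pool-vs-reference
    # median ratios estimate sums of per-cell factors (robust to a minority
    # of differentially expressed genes)
    ref = X.mean(axis=1)
    expressed = ref > 0
    order = np.argsort(totals, kind="stable")
    rows, cols_, vals, b = [], [], [], []
    eq = 0
    for ps in pool_sizes:
        if ps > n:
            continue
        for start in range(n):
            pool = order[(start + np.arange(ps)) % n]
            pooled = X[:, pool].sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratios = pooled[expressed] / ref[expressed]
            theta = np.median(ratios)
            rows.extend([eq] * ps)
            cols_.extend(pool.tolist())
            vals.extend([1.0] * ps)
            b.append(theta)
            eq += 1
    # anchor: mean factor = 1 (heavily weighted row fixes the free scale)
    w = np.sqrt(n) * 10.0
    rows.extend([eq] * n)
    cols_.extend(range(n))
    vals.extend([w] * n)
    b.append(w * n)
    A = sp.csr_matrix((vals, (rows, cols_)), shape=(eq + 1, n))
    factors = lsqr(A, np.asarray(b), atol=1e-10, btol=1e-10)[0]
    bad = ~(factors > 0)
    if bad.any():
        warnings.warn(f"{bad.sum()} non-positive deconvolution factors "
                      "replaced by library-size factors")
        factors[bad] = lib[bad] * factors[~bad].mean()
    return factors / factors.mean()


def lognormalize(counts: CountMatrix, factors: np.ndarray) -> ExprMatrix:
    """log2(count / factor + 1) on the full matrix."""
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    X = np.asarray(counts.values.todense(), dtype=float) / factors
    return ExprMatrix(np.log2(X + 1.0), counts.gene_ids, counts.barcodes,
                      provenance=["lognormalize(log2, offset 1)"])


# ---------------------------------------------------------------------------
# technical control genes and RUV
# ---------------------------------------------------------------------------

def select_control_genes(expr: ExprMatrix, span: float = 0.3):
    """Genes with total variance below the loess mean-variance trend.

    These show only technical variability and feed the RUV step.  Returns
    ``(MeanVarTrend, boolean control mask over genes)``; strict "<" so genes
    exactly on the trend are not controls.
    """
    if expr.n_genes < 100:
        warnings.warn("fewer than 100 genes; trend fit may be unstable")
    means = expr.values.mean(axis=1)
    variances = expr.values.var(axis=1, ddof=1)
    if np.allclose(variances, variances[0]):
        if variances[0] == 0:
            warnings.warn("degenerate constant matrix: empty control set")
            trend = MeanVarTrend(means, np.zeros_like(means))
            return trend, np.zeros(expr.n_genes, bool)
    fitted = lowess(variances, means, frac=span, return_sorted=False)
    fitted = np.maximum(fitted, 0.0)
    controls = variances < fitted
    trend = MeanVarTrend(means, fitted)
    log.info("select_control_genes: %d/%d genes below trend",
             int(controls.sum()), expr.n_genes)
    return trend, controls


def ruv_remove(expr: ExprMatrix, control_genes, k_unwanted: int = 1) -> ExprMatrix:
    """Remove unwanted variation estimated from technical control genes.

    The first ``k_unwanted`` cell-wise singular vectors of the row-centered
    control-gene submatrix are treated as unwanted factors and regressed out
    of every gene (residual + gene mean).  ``k_unwanted = 0`` is the
    identity.
    """
    mask = np.asarray(control_genes)
    if mask.dtype != bool:
        mask = np.isin(expr.gene_ids, mask)
    n_ctrl = int(mask.sum())
    if k_unwanted == 0:
        return expr.with_step("ruv(k=0)")
    if k_unwanted > n_ctrl:
        raise ValueError(f"k_unwanted={k_unwanted} exceeds {n_ctrl} control genes")
    C = expr.values[mask]
    C = C - C.mean(axis=1, keepdims=True)
    if not np.any(np.abs(C) > 1e-12):
        raise ValueError("control genes are constant; unwanted factors undefined")
    _, _, vt = np.linalg.svd(C, full_matrices=False)
    W = vt[:k_unwanted].T                      # cells x k
    Y = expr.values
    mu = Y.mean(axis=1, keepdims=True)
    Yc = Y - mu
    beta, *_ = np.linalg.lstsq(W, Yc.T, rcond=None)
    out = Yc - (W @ beta).T + mu
    return expr.with_step(f"ruv(k={k_unwanted})", out)


def regress_out(expr: ExprMatrix, covariates: pd.DataFrame) -> ExprMatrix:
    """Regress per-cell covariates out of every gene (residual + gene mean).

    Categorical columns are one-hot encoded (first level dropped); an
    intercept is always included; collinear columns are dropped with a
    warning.  Applying the same regression twice is a no-op.
    """
    X = _design_matrix(covariates)
    Y = expr.values
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    mu = Y.mean(axis=1, keepdims=True)
    out = resid.T + mu
    return expr.with_step(f"regress_out({list(covariates.columns)})", out)


def _design_matrix(covariates: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(covariates))]
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype) \
                or pd.api.types.is_string_dtype(col):
            dummies = pd.get_dummies(col, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
        else:
            cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient design; dropping collinear columns")
        q, r, piv = _qr_pivot(X)
        keep = sorted(piv[:rank])
        X = X[:, keep]
    return X


def _qr_pivot(X):
    import scipy.linalg
    q, r, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
    return q, r, piv


# ---------------------------------------------------------------------------
# variable genes
# ---------------------------------------------------------------------------

def select_variable_genes(expr: ExprMatrix, params: HVGParams | None = None,
                          min_cells: int = 3) -> np.ndarray:
    """Boolean mask of biologically variable genes.

    Genes detected (expr > 0) in fewer than ``min_cells`` cells are removed
    first; the survivors must satisfy ``mean_low < mean of non-zero values <
    mean_high`` and ``SD over all cells > sd_min``.
    """
    params = params or HVGParams()
    params.validate()
    V = expr.values
    detected = (V > 0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        nz_mean = np.where(detected > 0,
                           V.sum(axis=1) / np.maximum(detected, 1), 0.0)
    sd = V.std(axis=1, ddof=1) if V.shape[1] > 1 else np.zeros(V.shape[0])
    mask = ((detected >= min_cells)
            & (nz_mean > params.mean_low) & (nz_mean < params.mean_high)
            & (sd > params.sd_min))
    log.info("select_variable_genes: %d/%d genes", int(mask.sum()), expr.n_genes)
    return mask
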