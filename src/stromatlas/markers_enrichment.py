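"""Marker discovery and differential expression statistics.

Markers are ranked by the area under the ROC curve of each gene as a
one-gene classifier of its top-mean cluster versus the rest (rank-sum AUC
with midrank ties).  Filtered marker testing applies detection-fraction and
log-fold-change prefilters before either the AUC test or a negative-binomial
GLM with latent covariates (total UMIs, cell-cycle scores, batch) and a log
size-factor offset.  Gene-set enrichment is an upper-tail hypergeometric
test with Benjamini-Hochberg adjustment; marker-set overlap between two
clusterings is screened by one-sided Fisher exact tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import digamma, gammaln
from scipy.stats import fisher_exact, hypergeom, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

log = logging.getLogger("stromatlas")


@dataclass
class MarkerParams:
    min_pct: float = 0.25
    logfc_threshold: float = 0.25
    return_thresh: float = 0.3
    top_n: int = 200

    def validate(self) -> None:
        if min(self.min_pct, self.logfc_threshold, self.return_thresh) < 0:
            raise ValueError("thresholds must be >= 0")


def _auc_rank(x: np.ndarray, positive: np.ndarray) -> float:
    """Rank-sum AUC with midranks for ties (ties count 1/2)."""
    n1 = int(positive.sum())
    n0 = len(x) - n1
    if n1 == 0 or n0 == 0:
        return 0.5
    ranks = rankdata(x)
    r1 = ranks[positive].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _log_fc(x_in: np.ndarray, x_out: np.ndarray) -> float:
    """Natural-log fold change of de-logged means on the normalized scale."""
    a = np.mean(2.0 ** x_in - 1.0) + 1.0
    b = np.mean(2.0 ** x_out - 1.0) + 1.0
    return float(np.log(a) - np.log(b))


def auc_markers(expr: np.ndarray, labels, gene_ids=None,
                top_n: int = 200) -> pd.DataFrame:
    """AUC-ranked candidate markers, top ``top_n`` per cluster.

    For each gene the target cluster is the one with the highest mean
    expression; the AUC measures how well the gene separates that cluster
    from all remaining cells.  Size-1 clusters are flagged, not dropped.
    """
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    gene_ids = np.asarray(gene_ids if gene_ids is not None
                          else [f"g{i}" for i in range(expr.shape[0])])
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    masks = {cl: labels == cl for cl in uniq}
    sizes = {cl: int(m.sum()) for cl, m in masks.items()}
    means = np.column_stack([expr[:, masks[cl]].mean(axis=1) for cl in uniq])
    target = np.asarray(uniq)[np.argmax(means, axis=1)]
    rows = []
    for g in range(expr.shape[0]):
        cl = target[g]
        pos = masks[cl]
        x = expr[g]
        auc = _auc_rank(x, pos)
        if np.ptp(x) == 0:
            p = 1.0
        else:
            p = float(mannwhitneyu(x[pos], x[~pos],
                                   alternative="two-sided").pvalue)
        rows.append({
            "gene": gene_ids[g], "cluster": cl, "auc": auc,
            "pct_in": float((x[pos] > 0).mean()),
            "pct_out": float((x[~pos] > 0).mean()),
            "log_fc": _log_fc(x[pos], x[~pos]),
            "p_value": p,
            "flag_small_cluster": sizes[cl] < 2,
        })
    tbl = pd.DataFrame(rows)
    tbl["p_adj"] = multipletests(tbl["p_value"], method="fdr_bh")[1]
    tbl = (tbl.sort_values(["cluster", "auc"], ascending=[True, False])
              .groupby("cluster", group_keys=False).head(top_n)
              .reset_index(drop=True))
    return tbl


def filtered_markers(expr: np.ndarray, labels, gene_ids=None,
                     params: MarkerParams | None = None, test: str = "auc",
                     counts=None, latent: pd.DataFrame | None = None,
                     size_factors=None) -> pd.DataFrame:
    """Per-cluster marker tests behind detection and fold-change prefilters.

    A gene enters testing for cluster c only if it is detected in at least
    ``min_pct`` of cells inside or outside c AND its absolute log fold
    change is at least ``logfc_threshold``.  ``test='auc'`` reports genes
    with discriminative power |AUC - 0.5| >= 0.5 - return_thresh;
    ``test='negbinom'`` delegates to :func:`nb_glm_de` (requires raw
    ``counts``).
    """
    params = params or MarkerParams()
    params.validate()
    expr = np.asarray(expr, dtype=float)
    labels = np.asarray(labels)
    gene_ids = np.asarray(gene_ids if gene_ids is not None
                          else [f"g{i}" for i in range(expr.shape[0])])
    out = []
    for cl in pd.unique(labels):
        pos = labels == cl
        det_in = (expr[:, pos] > 0).mean(axis=1)
        det_out = (expr[:, ~pos] > 0).mean(axis=1)
        lfc = np.array([_log_fc(expr[g, pos], expr[g, ~pos])
                        for g in range(expr.shape[0])])
        testable = (((det_in >= params.min_pct) | (det_out >= params.min_pct))
                    & (np.abs(lfc) >= params.logfc_threshold))
        idx = np.flatnonzero(testable)
        if idx.size == 0:
            continue
        if test == "auc":
            power_min = 0.5 - params.return_thresh
            for g in idx:
                auc = _auc_rank(expr[g], pos)
                if abs(auc - 0.5) >= power_min:
                    out.append({"gene": gene_ids[g], "cluster": cl,
                                "auc": auc, "pct_in": det_in[g],
                                "pct_out": det_out[g], "log_fc": lfc[g],
                                "p_value": np.nan})
        elif test == "negbinom":
            if counts is None:
                raise ValueError("negbinom test requires raw counts")
            sub = nb_glm_de(np.asarray(counts)[idx], pos.astype(int),
                            latent=latent, size_factors=size_factors,
                            gene_ids=gene_ids[idx])
            sub["cluster"] = cl
            meta = pd.DataFrame({"gene": gene_ids[idx], "pct_in": det_in[idx],
                                 "pct_out": det_out[idx]})
            sub = sub.merge(meta, on="gene", how="left")
            out.extend(sub.to_dict("records"))
        else:
            raise ValueError(f"unknown test {test!r}")
    tbl = pd.DataFrame(out)
    if len(tbl) and tbl["p_value"].notna().any():
        ok = tbl["p_value"].notna()
        adj = np.full(len(tbl), np.nan)
        adj[ok.to_numpy()] = multipletests(tbl.loc[ok, "p_value"],
                                           method="fdr_bh")[1]
        tbl["p_adj"] = adj
    return tbl


# ---------------------------------------------------------------------------
# negative binomial GLM differential expression
# ---------------------------------------------------------------------------

def _nb_loglik_dr(y, mu, r):
    """First derivative of the NB log-likelihood w.r.t. size r = 1/phi."""
    return float(np.sum(digamma(y + r) - digamma(r)
                        + np.log(r / (r + mu)) + (mu - y) / (r + mu)))


def _estimate_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion followed by one Newton refinement."""
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu ** 2)
    phi = max(num / den, 1e-8) if den > 0 else 1e-8
    r = 1.0 / phi
    eps = max(1e-4 * r, 1e-8)
    d1 = _nb_loglik_dr(y, mu, r)
    d2 = (_nb_loglik_dr(y, mu, r + eps) - _nb_loglik_dr(y, mu, r - eps)) / (2 * eps)
    if np.isfinite(d1) and np.isfinite(d2) and d2 < 0:
        r_new = r - d1 / d2
        if np.isfinite(r_new) and r_new > 0:
            r = r_new
    return float(1.0 / r)


def nb_glm_de(counts: np.ndarray, group, latent: pd.DataFrame | None = None,
              size_factors=None, gene_ids=None) -> pd.DataFrame:
    """Per-gene NB log-linear model with a Wald test on the group effect.

    Design: intercept + group indicator + latent covariates (categoricals
    one-hot encoded), with offset log(size factor).  Dispersion is estimated
    per gene by method of moments with one Newton refinement on the NB
    likelihood.  All-zero genes are excluded; non-converged fits are
    reported with p = NaN.  ``log_fc`` is the natural-log group coefficient.
    """
    counts = np.asarray(counts, dtype=float)
    group = np.asarray(group)
    gvals = pd.unique(group)
    if len(gvals) != 2:
        raise ValueError("group must have exactly 2 levels")
    gind = (group == gvals[-1]).astype(float)
    if gind.sum() == 0 or gind.sum() == len(gind):
        raise ValueError("both groups must be non-empty")
    n = counts.shape[1]
    gene_ids = np.asarray(gene_ids if gene_ids is not None
                          else [f"g{i}" for i in range(counts.shape[0])])
    cols = [np.ones(n), gind]
    names = ["intercept", "group"]
    if latent is not None:
        for c in latent.columns:
            col = latent[c]
            if col.dtype == object or pd.api.types.is_string_dtype(col):
                for lev, d in pd.get_dummies(col, drop_first=True).items():
                    cols.append(d.to_numpy(dtype=float))
                    names.append(f"{c}[{lev}]")
            else:
                v = col.to_numpy(dtype=float)
                sd = v.std()
                cols.append((v - v.mean()) / (sd if sd > 0 else 1.0))
                names.append(c)
    X = np.column_stack(cols)
    offset = np.log(np.asarray(size_factors, dtype=float)) \
        if size_factors is not None else np.zeros(n)

    rows = []
    for g in range(counts.shape[0]):
        y = counts[g]
        if y.sum() == 0:
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pois = sm.GLM(y, X, family=sm.families.Poisson(),
                              offset=offset).fit(maxiter=50)
                phi = _estimate_dispersion(y, pois.fittedvalues)
                fam = sm.families.NegativeBinomial(alpha=max(phi, 1e-8))
                fit = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            beta = fit.params[1]
            se = fit.bse[1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0):
                raise ValueError("non-finite fit")
            z = beta / se
            p = 2.0 * _norm_sf(abs(z))
            rows.append({"gene": gene_ids[g], "log_fc": float(beta),
                         "dispersion": phi, "p_value": float(p),
                         "converged": bool(fit.converged)})
        except Exception:
            rows.append({"gene": gene_ids[g], "log_fc": np.nan,
                         "dispersion": np.nan, "p_value": np.nan,
                         "converged": False})
    tbl = pd.DataFrame(rows)
    if len(tbl):
        ok = tbl["p_value"].notna()
        adj = np.full(len(tbl), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(tbl.loc[ok, "p_value"],
                                               method="fdr_bh")[1]
        tbl["p_adj"] = adj
    return tbl


def _norm_sf(z: float) -> float:
    from scipy.stats import norm
    return float(norm.sf(z))


# ---------------------------------------------------------------------------
# gene-set enrichment and marker overlap
# ---------------------------------------------------------------------------

def geneset_enrichment(query, gene_sets: dict, background,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    ``background`` is the expressed-gene universe; sets are intersected with
    it.  BH adjustment across sets; ``significant`` marks both raw p and
    adjusted p below ``fdr``.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    query = set(query) & background
    if set(query) - background:
        raise ValueError("query genes outside the background")
    N = len(background)
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & background
        k = len(query & s)
        p = float(hypergeom.sf(k - 1, N, len(s), len(query))) if s else 1.0
        rows.append({"set": name, "overlap": k, "set_size": len(s),
                     "query_size": len(query), "universe": N, "p_value": p})
    tbl = pd.DataFrame(rows)
    if len(tbl):
        tbl["p_adj"] = multipletests(tbl["p_value"], method="fdr_bh")[1]
        tbl["significant"] = (tbl["p_value"] < fdr) & (tbl["p_adj"] < fdr)
    return tbl.sort_values("p_value").reset_index(drop=True)


def marker_overlap_table(markers_a: dict, markers_b: dict, universe):
    """Fisher cross-tabulation of marker sets between two clusterings.

    For every pair of clusters, a one-sided (enrichment) Fisher exact test
    on the 2x2 membership table over ``universe``.  Returns
    ``(shared_counts, p_values, neglog10_p)`` DataFrames (rows = clustering
    A, columns = clustering B).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    a_keys, b_keys = list(markers_a), list(markers_b)
    shared = pd.DataFrame(0, index=a_keys, columns=b_keys, dtype=int)
    pvals = pd.DataFrame(1.0, index=a_keys, columns=b_keys, dtype=float)
    for ka in a_keys:
        sa = set(markers_a[ka]) & universe
        for kb in b_keys:
            sb = set(markers_b[kb]) & universe
            inter = len(sa & sb)
            table = [[inter, len(sa) - inter],
                     [len(sb) - inter, len(universe) - len(sa) - len(sb) + inter]]
            _, p = fisher_exact(table, alternative="greater")
            shared.loc[ka, kb] = inter
            pvals.loc[ka, kb] = p
    neglog = -np.log10(pvals.clip(lower=1e-300))
    return shared, pvals, neglog
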