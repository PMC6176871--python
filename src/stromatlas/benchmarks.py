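"""Desk-scale synthetic benchmarks exercising every analysis track.

Each function simulates data under the generator's study conditions, runs
the corresponding part of the pipeline, and returns scalar summaries
measured against the known ground truth.  They back both the validation
suite and the ``scripts/acceptance.py`` reproduction script; problem sizes
are chosen so the full battery completes on a single CPU in minutes (the
methods note records the sizes used).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from . import (cellcall_qc, coexpression_consensus as cc, crossspecies_rf,
               integration_diag, markers_enrichment as me, normalization,
               synthdata, trajectory_cycle as tc)
from .synthdata import SimConfig


def barcode_calling(seed: int = 0, n_seeds: int = 10) -> dict:
    """Density-minimum barcode calling on the default droplet mixture.

    1,000 planted cells vs 4,000 ambient barcodes per replicate; reports the
    worst relative error of the called-cell count across replicates.
    """
    errors = []
    for s in range(n_seeds):
        cfg = SimConfig(n_cells_per_cluster=[200] * 5, n_clusters=5,
                        ambient_barcodes=4000, cell_mean_umi=5000,
                        ambient_mean_umi=100, control_cell_fraction=0.0,
                        seed=seed + s)
        counts, truth = synthdata.simulate_droplet_experiment(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, is_cell = cellcall_qc.call_cells(counts)
        planted = int(truth.is_cell.sum())
        errors.append(abs(int(is_cell.sum()) - planted) / planted)
    return {"max_rel_error": float(np.max(errors)),
            "mean_rel_error": float(np.mean(errors)), "n_seeds": n_seeds,
            "planted": 1000}


def _c1_modules(counts):
    factors = normalization.pooled_size_factors(counts)
    expr = normalization.lognormalize(counts, factors)
    _, controls = normalization.select_control_genes(expr)
    sub = expr.subset_genes(~controls)
    adj = cc.signed_hybrid_adjacency(sub.values, 4.0)
    dis = cc.adjacency_dissimilarity(adj)
    dis = cc.confidence_prune(dis, 2.0 ** sub.values - 1.0, 6.0, 3)
    mods = cc.dynamic_tree_modules(dis)
    return sub, mods


def c1_rank_recovery(seed: int = 0, n_seeds: int = 10, true_rank: int = 4,
                     n_runs: int = 50) -> dict:
    """C1 track end to end: modules, NMF consensus, rank survey, control.

    Planted ``true_rank``-cluster, 300-cell simulations at C1 depth; counts
    how often the rank survey picks the planted rank and compares observed
    vs permuted-control cophenetic correlation at that rank.
    """
    hits, obs_coph, ctl_coph, aris = 0, [], [], []
    for s in range(n_seeds):
        cfg = SimConfig(n_genes=2000, n_cells_per_cluster=[75] * true_rank,
                        n_clusters=true_rank, ambient_barcodes=0,
                        control_cell_fraction=0.0, cell_mean_umi=1e5,
                        seed=seed + s)
        counts, truth = synthdata.simulate_droplet_experiment(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub, mods = _c1_modules(counts)
            ME = np.clip(sub.values[mods.module_of > 0], 0.0, None)
            cons = cc.nmf_consensus(ME, range(2, 8), n_runs=n_runs,
                                    seed=seed + s, max_iter=200)
            control = cc.permute_control(ME, seed=seed + s)
            est = cc.NMFConsensusClustering(rank_range=[true_rank],
                                            n_runs=n_runs,
                                            random_state=seed + s,
                                            max_iter=200)
            est.fit(control.T)
        hits += cons.chosen_rank == true_rank
        m = cons.metrics.set_index("rank")
        obs_coph.append(float(m.loc[true_rank, "cophenetic"]))
        ctl_coph.append(float(est.metrics_.set_index("rank")
                              .loc[true_rank, "cophenetic"]))
        labels = cons.labels_by_rank[true_rank]
        aris.append(adjusted_rand_score(truth.cell_labels, labels))
    return {"recovery_rate": hits / n_seeds, "n_seeds": n_seeds,
            "cophenetic_observed": float(np.mean(obs_coph)),
            "cophenetic_control": float(np.mean(ctl_coph)),
            "ari_at_true_rank": float(np.mean(aris))}


def module_detection(seed: int = 0) -> dict:
    """Dynamic tree cut on 4 planted correlation modules (within r = 0.8)."""
    expr, truth = synthdata.simulate_gene_modules(within_r=0.8, seed=seed)
    adj = cc.signed_hybrid_adjacency(expr, 4.0)
    mods = cc.dynamic_tree_modules(cc.adjacency_dissimilarity(adj))
    return {"ari": float(adjusted_rand_score(truth, mods.module_of)),
            "n_modules": len(mods.module_sizes), "n_genes": len(truth)}


def auc_oracle(seed: int = 0, n_instances: int = 100) -> dict:
    """Rank-sum AUC vs brute-force pair counting on random tied instances."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(6, 30))
        x = rng.integers(0, 6, n).astype(float)
        pos = np.zeros(n, bool)
        pos[rng.choice(n, int(rng.integers(2, n - 1)), replace=False)] = True
        a, b = x[pos], x[~pos]
        brute = ((a[:, None] > b[None, :]).sum()
                 + 0.5 * (a[:, None] == b[None, :]).sum()) / (len(a) * len(b))
        worst = max(worst, abs(me._auc_rank(x, pos) - brute))
    return {"max_abs_diff": float(worst), "n_instances": n_instances}


def nb_glm_calibration(seed: int = 0, n_null_genes: int = 2000,
                       n_planted: int = 300, n_per_group: int = 200,
                       phi: float = 0.2) -> dict:
    """NB GLM type-I error under the null and log2FC recovery at truth 1."""
    rng = np.random.default_rng(seed)
    r = 1.0 / phi

    def nb(mean, size):
        return rng.negative_binomial(r, r / (r + mean), size)

    mu = rng.lognormal(1.2, 0.9, n_null_genes)
    null = np.vstack([nb(m, 2 * n_per_group) for m in mu])
    group = np.repeat([0, 1], n_per_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tbl = me.nb_glm_de(null, group)
    type1 = float((tbl["p_value"].dropna() < 0.05).mean())

    mu2 = rng.lognormal(1.2, 0.9, n_planted)
    planted = np.vstack([np.concatenate([nb(m, n_per_group),
                                         nb(2 * m, n_per_group)])
                         for m in mu2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tbl2 = me.nb_glm_de(planted, group)
    med = float(np.median(tbl2["log_fc"].dropna() / np.log(2)))
    return {"type1_error": type1, "n_null_genes": int(len(tbl)),
            "median_log2fc": med, "n_planted": n_planted}


def crossspecies_transfer(seed: int = 0, use_rfe: bool = True) -> dict:
    """Cross-species forest transfer with a divergent, mimicking class.

    Conserved-class recall should stay high while the divergent class is
    the most-confused, mirroring cross-species plasticity of one stromal
    subset.
    """
    cfg = SimConfig(n_genes=1200, n_cells_per_cluster=[120] * 4, n_clusters=4,
                    ambient_barcodes=0, control_cell_fraction=0.0,
                    cell_mean_umi=3000, seed=seed)
    cma, cmb, omap, truth = synthdata.simulate_two_species(
        cfg, n_orthologs=500, divergent_clusters=("C1",))

    def norm(cm):
        f = normalization.library_size_factors(cm)
        e = normalization.lognormalize(cm, f)
        return pd.DataFrame(e.values.T, columns=cm.gene_ids)

    ea, eb = norm(cma), norm(cmb)
    ya = truth.cell_labels[:cma.n_cells]
    yb = truth.cell_labels[cma.n_cells:]
    bij = crossspecies_rf.filter_orthologs(omap)
    Xa = ea[list(bij["gene_A"])].to_numpy()
    Xb = eb[list(bij["gene_B"])].to_numpy()
    params = crossspecies_rf.RFParams(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xbal, ybal = crossspecies_rf.balance_classes(Xa, ya, smote_k=5,
                                                     seed=seed)
        names = list(bij["gene_A"])
        if use_rfe:
            sel, _ = crossspecies_rf.rfe_select(
                Xbal, ybal, params, [Xbal.shape[1], 120],
                feature_names=names)
            idx = [names.index(f) for f in sel]
        else:
            sel, idx = names, list(range(len(names)))
        model = crossspecies_rf.train_rf(Xbal[:, idx], ybal, params,
                                         feature_names=sel)
        query = pd.DataFrame(Xb[:, idx], columns=sel)
        _, conf, _ = crossspecies_rf.classify_and_confuse(model, query, yb)
    recalls = {c: float(conf.loc[c, c]) for c in conf.index}
    conserved = [c for c, ok in truth.ortholog_truth["conserved"].items() if ok]
    divergent = [c for c, ok in truth.ortholog_truth["conserved"].items()
                 if not ok]
    most_confused = min(recalls, key=recalls.get)
    return {"conserved_recall": float(np.mean([recalls[c] for c in conserved])),
            "divergent_recall": float(np.mean([recalls[c] for c in divergent])),
            "most_confused_is_divergent": most_confused in divergent,
            "n_orthologs_used": len(bij), "n_features": len(sel)}


def ortholog_filter_exactness(seed: int = 0) -> dict:
    """Map filtering vs the planted >=75%-identity one-to-one bijection."""
    cfg = SimConfig(n_genes=600, n_cells_per_cluster=[20] * 3, n_clusters=3,
                    ambient_barcodes=0, control_cell_fraction=0.0, seed=seed)
    _, _, omap, _ = synthdata.simulate_two_species(cfg, n_orthologs=200)
    out = crossspecies_rf.filter_orthologs(omap)
    expected = omap[(omap["homology_class"] == "one2one")
                    & (omap[["pct_identity_AtoB", "pct_identity_BtoA"]]
                       .min(axis=1) >= 75)]
    got = set(zip(out["gene_A"], out["gene_B"]))
    want = set(zip(expected["gene_A"], expected["gene_B"]))
    return {"exact_match": float(got == want), "n_pairs": len(want)}


def dpt_linear(seed: int = 0, n_cells: int = 500) -> dict:
    """Diffusion pseudotime vs latent time on a linear trajectory."""
    cfg = SimConfig(n_genes=1000, n_cells_per_cluster=[n_cells], n_clusters=1,
                    ambient_barcodes=0, control_cell_fraction=0.0,
                    cell_mean_umi=3000, seed=seed)
    counts, truth = synthdata.simulate_trajectory(cfg)
    expr = normalization.lognormalize(
        counts, normalization.library_size_factors(counts))
    hvg = normalization.select_variable_genes(expr)
    dmap = tc.diffusion_map(expr.values[hvg].T, k_nn=min(500, n_cells - 1))
    root = int(np.argmin(truth.true_pseudotime))
    dpt = tc.diffusion_pseudotime(dmap, root)
    return {"spearman": float(spearmanr(dpt, truth.true_pseudotime)[0]),
            "root_pseudotime": float(dpt[root]), "n_cells": n_cells}


def cellcycle_calling(seed: int = 0) -> dict:
    """Gene-pair phase calling accuracy and the proliferative-cluster check."""
    cfg = SimConfig(n_genes=500, n_cells_per_cluster=[120] * 3, n_clusters=3,
                    ambient_barcodes=0, control_cell_fraction=0.0,
                    cell_mean_umi=5000, seed=seed)
    counts, truth, _ = synthdata.simulate_cellcycle(cfg, n_pairs_per_phase=8)
    expr = np.log2(counts.dense().astype(float) + 1.0)
    pairs = tc.train_cycle_pairs(expr, truth.phase_labels, counts.gene_ids,
                                 consistency=0.7)
    out = tc.score_cycle(expr, pairs, counts.gene_ids)
    acc = float((out["phase"].to_numpy() == truth.phase_labels).mean())
    prop = tc.g2m_proportion_by_cluster(out["phase"], truth.cell_labels)
    return {"phase_accuracy": acc,
            "proliferative_cluster_ranks_first": float(prop.index[0] == "C3"),
            "n_cells": counts.n_cells}


def batch_entropy_controls(seed: int = 0) -> dict:
    """Exact entropy arithmetic plus control ordering on a mixed embedding."""
    exact = integration_diag.normalized_entropy([75, 25], 2)
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 1, (500, 2))
    batches = rng.choice(["b1", "b2"], 500)
    clusters = (coords[:, 0] > 0).astype(str)
    out = integration_diag.batch_entropy(
        coords, batches,
        integration_diag.EntropyParams(n_boot=50, seed=seed),
        cluster_labels=clusters)
    lo, hi = np.quantile(out["negative_control"], [0.05, 0.95])
    return {"entropy_75_25": float(exact),
            "observed_mean": float(out["observed"].mean()),
            "negative_control_mean": float(out["negative_control"].mean()),
            "positive_control_mean": float(out["positive_control"].mean()),
            "observed_within_negative_band": float(
                lo <= out["observed"].mean() <= hi),
            "positive_below_negative": float(
                out["positive_control"].mean()
                < out["negative_control"].mean())}


def reference_normalization(seed: int = 0) -> dict:
    """Quantile normalization marginals and EB batch-shift removal."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(rng.normal(5, 2, (400, 5)),
                      columns=[f"pb{i}" for i in range(5)])
    qn = integration_diag.quantile_normalize_to_reference(df, "pb0")
    ref_sorted = np.sort(df["pb0"].to_numpy())
    marg = max(float(np.abs(np.sort(qn[c].to_numpy()) - ref_sorted).max())
               for c in qn.columns)
    base = rng.normal(5, 1, (300, 1))
    b1 = base + rng.normal(0, 0.5, (300, 50))
    b2 = base + 3.0 + rng.normal(0, 0.5, (300, 50))
    M = np.hstack([b1, b2])
    adj = integration_diag.eb_batch_adjust(
        M, ["a"] * 50 + ["b"] * 50).to_numpy()
    resid = float(np.median(np.abs(adj[:, :50].mean(axis=1)
                                   - adj[:, 50:].mean(axis=1))))
    return {"qn_marginal_max_diff": marg, "combat_residual_shift": resid,
            "planted_shift": 3.0}
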