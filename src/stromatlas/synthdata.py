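"""Synthetic droplet/C1 scRNA-seq data with known ground truth.

Every generator emulates one statistical structure the analysis pipeline
assumes, and returns the generating truth alongside the counts so each
downstream stage can be scored against it:

* :func:`simulate_droplet_experiment` — negative-binomial UMI counts with
  planted clusters and marker genes, a bimodal barcode total distribution
  (ambient gel beads vs. cell-containing ones), per-cell mitochondrial
  fractions, gene-wise multiplicative batch effects, and a transgene-bearing
  control-cell cluster spiked in at a configurable fraction.
* :func:`simulate_two_species` — a pair of datasets ("human"/"mouse"-like)
  sharing conserved clusters through a one-to-one ortholog map, with
  divergent clusters carrying species-private markers, plus planted
  one-to-many / many-to-many map rows and a range of sequence identities.
* :func:`simulate_trajectory` — smooth gene programs along a latent time
  t in [0, 1], optionally branching at t = 0.5.
* :func:`simulate_cellcycle` — phase-specific marker gene *pairs* whose
  within-cell ordering encodes G1/S/G2M, with one planted proliferative
  cluster enriched for G2M cells.
* :func:`simulate_gene_modules` — blocks of correlated genes for
  co-expression module detection.

Counts follow a gamma-Poisson mixture, i.e. NB with variance
``mu + phi * mu**2``.  A single :class:`numpy.random.Generator` seeded from
``SimConfig.seed`` drives everything, so identical configs give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix_io import CountMatrix

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-ATP8", "MT-ATP6", "MT-CO3",
    "MT-ND3", "MT-ND4L", "MT-ND4", "MT-ND5", "MT-ND6", "MT-CYB",
]
TRANSGENE = "LV-BSD"  # lentiviral blasticidin-resistance analogue
CONTROL_LABEL = "control"


@dataclass
class SimConfig:
    """Parameters of the synthetic droplet experiment.

    ``nb_dispersion`` is the NB dispersion phi in ``var = mu + phi mu^2``;
    ``batch_logfc_sd`` is the SD of gene-wise log2 multiplicative batch
    factors; ``ambient_mean_umi`` / ``cell_mean_umi`` are the expected totals
    of the two barcode modes.
    """

    n_genes: int = 2000
    n_cells_per_cluster: list = field(default_factory=lambda: [200] * 5)
    n_clusters: int = 5
    de_fraction: float = 0.10
    logfc: float = 2.0
    nb_dispersion: float = 0.3
    n_batches: int = 2
    batch_logfc_sd: float = 0.1
    ambient_barcodes: int = 4000
    ambient_mean_umi: float = 100.0
    cell_mean_umi: float = 5000.0
    mito_fraction_mean: float = 0.02
    control_cell_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < len(MITO_GENES) + 1 + 10:
            raise ValueError("n_genes too small for the fixed gene panel")
        if len(self.n_cells_per_cluster) != self.n_clusters:
            raise ValueError("n_cells_per_cluster length must equal n_clusters")
        if any(n < 0 for n in self.n_cells_per_cluster):
            raise ValueError("cell counts must be >= 0")
        for name in ("de_fraction", "mito_fraction_mean", "control_cell_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.ambient_barcodes < 0 or self.n_batches < 1:
            raise ValueError("counts must be non-negative")
        if self.ambient_barcodes > 0 and self.ambient_mean_umi >= self.cell_mean_umi:
            raise ValueError(
                "ambient_mean_umi must be below cell_mean_umi: the two barcode "
                "modes would overlap and the mixture would be unidentifiable")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class SynthTruth:
    """Ground truth accompanying a simulated dataset (aligned to barcodes)."""

    cell_labels: np.ndarray          # cluster id per barcode ("" for ambient)
    is_cell: np.ndarray              # bool per barcode
    marker_genes: dict               # cluster -> {gene: true log2FC}
    batch_labels: np.ndarray         # per barcode ("ambient" for empties)
    true_pseudotime: np.ndarray | None = None
    phase_labels: np.ndarray | None = None
    ortholog_truth: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        d = {"cell_label": self.cell_labels, "is_cell": self.is_cell,
             "batch": self.batch_labels}
        if self.true_pseudotime is not None:
            d["true_pseudotime"] = self.true_pseudotime
        if self.phase_labels is not None:
            d["phase"] = self.phase_labels
        return pd.DataFrame(d)


def _nb(rng: np.random.Generator, mean: np.ndarray, phi) -> np.ndarray:
    """Gamma-Poisson (NB) draw with var = mu + phi mu^2; phi=0 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, dtype=float), mean.shape)
    lam = np.where(phi > 0,
                   rng.gamma(np.where(phi > 0, 1.0 / np.maximum(phi, 1e-12), 1.0),
                             np.maximum(phi, 1e-12) * mean),
                   mean)
    return rng.poisson(lam)


def _gene_panel(cfg: SimConfig, rng: np.random.Generator):
    """Gene ids/symbols and a base relative-abundance profile."""
    n_bio = cfg.n_genes - len(MITO_GENES) - 1
    bio = [f"G{i:05d}" for i in range(n_bio)]
    ids = np.array(MITO_GENES + [TRANSGENE] + bio, dtype=object)
    base = rng.lognormal(0.0, 1.2, cfg.n_genes)
    base[len(MITO_GENES)] = 0.0            # transgene silent outside controls
    return ids, base


def _assign_markers(cfg: SimConfig, rng: np.random.Generator, ids, clusters,
                    base=None):
    """Disjoint per-cluster marker gene sets among the biological genes.

    Markers are drawn from mid-abundance genes (30th-90th percentile of the
    base profile): cell-type markers are moderately expressed, and a fold
    change on a near-zero or saturating base would be undetectable or
    implausible.
    """
    bio_idx = np.arange(len(MITO_GENES) + 1, cfg.n_genes)
    if base is not None:
        lo, hi = np.quantile(base[bio_idx], [0.30, 0.90])
        mid = bio_idx[(base[bio_idx] >= lo) & (base[bio_idx] <= hi)]
        if mid.size >= len(clusters) * 3:
            bio_idx = mid
    n_total = int(round(cfg.de_fraction * cfg.n_genes))
    per = max(1, n_total // max(len(clusters), 1)) if clusters else 0
    chosen = rng.choice(bio_idx, size=min(per * len(clusters), len(bio_idx)),
                        replace=False)
    markers = {}
    for i, cl in enumerate(clusters):
        block = chosen[i * per:(i + 1) * per]
        markers[cl] = {ids[g]: cfg.logfc for g in block}
    return markers


def _cluster_profiles(cfg, base, ids, markers, clusters):
    """Per-cluster relative profiles: markers up-shifted by 2**logfc."""
    id_pos = {g: i for i, g in enumerate(ids)}
    profs = {}
    for cl in clusters:
        p = base.copy()
        for g, lfc in markers.get(cl, {}).items():
            p[id_pos[g]] *= 2.0 ** lfc
        profs[cl] = p
    return profs


def _compose_cell_means(profile, depth, mito_frac, mito_weights, n_mito):
    """Split expected depth between mitochondrial and nuclear genes."""
    p = profile.copy()
    nuc = p[n_mito:]
    nuc_sum = nuc.sum()
    means = np.empty_like(p)
    means[:n_mito] = depth * mito_frac * mito_weights
    means[n_mito:] = depth * (1.0 - mito_frac) * nuc / nuc_sum
    return means


def simulate_droplet_experiment(config: SimConfig):
    """Simulate a full droplet run: cells + control cells + ambient barcodes.

    Returns ``(CountMatrix over all barcodes, SynthTruth)``.  Barcode order
    is randomly permuted so callers cannot rely on block structure.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids, base = _gene_panel(config, rng)
    n_mito = len(MITO_GENES)
    tg_pos = n_mito

    clusters = [f"C{i + 1}" for i in range(config.n_clusters)]
    n_real = int(sum(config.n_cells_per_cluster))
    n_control = int(round(config.control_cell_fraction * n_real))
    all_clusters = clusters + ([CONTROL_LABEL] if n_control else [])
    markers = _assign_markers(config, rng, ids, all_clusters, base=base)
    profs = _cluster_profiles(config, base, ids, markers, all_clusters)
    if n_control:
        # transgene: ~1% of the control-cell transcriptome
        profs[CONTROL_LABEL][tg_pos] = 0.01 * profs[CONTROL_LABEL].sum()

    labels = np.concatenate([
        np.repeat(clusters, config.n_cells_per_cluster),
        np.repeat([CONTROL_LABEL], n_control),
    ]) if n_real + n_control else np.array([], dtype=object)
    n_cells = len(labels)

    batch_of_cell = rng.integers(0, config.n_batches, n_cells)
    batch_factor = 2.0 ** rng.normal(0.0, config.batch_logfc_sd,
                                     (config.n_batches, config.n_genes))
    mito_w = rng.dirichlet(np.full(n_mito, 5.0))
    sigma = 0.25
    depths = rng.lognormal(np.log(config.cell_mean_umi) - sigma**2 / 2, sigma,
                           n_cells)
    mito_m = max(config.mito_fraction_mean, 1e-4)
    conc = 80.0
    mito_fracs = rng.beta(mito_m * conc, (1 - mito_m) * conc, n_cells)

    cols = np.empty((n_cells, config.n_genes), dtype=np.int64)
    for j in range(n_cells):
        prof = profs[labels[j]] * batch_factor[batch_of_cell[j]]
        mu = _compose_cell_means(prof, depths[j], mito_fracs[j], mito_w, n_mito)
        cols[j] = _nb(rng, mu, config.nb_dispersion)

    # ambient barcodes: library-wide mean profile, Poisson, shallow totals
    n_amb = config.ambient_barcodes
    if n_cells:
        lib_prof = np.mean([profs[c] for c in all_clusters], axis=0)
    else:
        lib_prof = base.copy()
    lib_prof = lib_prof / lib_prof.sum()
    amb_depths = rng.lognormal(np.log(config.ambient_mean_umi) - 0.3**2 / 2,
                               0.3, n_amb) if n_amb else np.empty(0)
    amb = np.empty((n_amb, config.n_genes), dtype=np.int64)
    for j in range(n_amb):
        amb[j] = rng.poisson(amb_depths[j] * lib_prof)

    values = np.vstack([cols, amb]).T if (n_cells or n_amb) else \
        np.zeros((config.n_genes, 0), dtype=np.int64)
    n_bc = n_cells + n_amb
    barcodes = np.array([f"BC{i:06d}" for i in range(n_bc)], dtype=object)
    is_cell = np.concatenate([np.ones(n_cells, bool), np.zeros(n_amb, bool)])
    cell_labels = np.concatenate([labels,
                                  np.repeat([""], n_amb)]).astype(object)
    batch_labels = np.concatenate([
        np.array([f"B{b + 1}" for b in batch_of_cell], dtype=object),
        np.repeat(["ambient"], n_amb)]).astype(object)

    perm = rng.permutation(n_bc)
    counts = CountMatrix(sp.csr_matrix(values[:, perm]), ids, ids,
                         barcodes)
    truth = SynthTruth(cell_labels[perm], is_cell[perm], markers,
                       batch_labels[perm])
    return counts, truth


# ---------------------------------------------------------------------------
# two species linked by an ortholog map
# ---------------------------------------------------------------------------

def simulate_two_species(config: SimConfig, n_orthologs: int = 600,
                         identity_range=(60.0, 99.0),
                         divergent_clusters=("C1",),
                         n_one2many: int = 10, n_many2many: int = 10,
                         low_identity_fraction: float = 0.2):
    """Two datasets with conserved and divergent clusters plus an ortholog map.

    Conserved clusters express the same markers through one-to-one ortholog
    pairs; clusters named in ``divergent_clusters`` get species-private
    markers that never enter the map.  The map additionally carries planted
    one-to-many and many-to-many rows and pairwise identities spanning
    ``identity_range`` (a ``low_identity_fraction`` of one-to-one rows falls
    below 75%, exercising the identity filter).
    """
    config.validate()
    if n_orthologs > config.n_genes - len(MITO_GENES) - 1:
        raise ValueError("n_orthologs exceeds the biological gene count")
    clusters = [f"C{i + 1}" for i in range(config.n_clusters)]
    unknown = set(divergent_clusters) - set(clusters)
    if unknown:
        raise ValueError(f"divergent_clusters not in cluster ids: {unknown}")

    rng = np.random.default_rng(config.seed)
    n_mito = len(MITO_GENES)
    n_bio = config.n_genes - n_mito - 1
    ids_a = np.array(MITO_GENES + [TRANSGENE]
                     + [f"HUM{i:05d}" for i in range(n_bio)], dtype=object)
    ids_b = np.array([m.lower().capitalize() for m in MITO_GENES] + [TRANSGENE]
                     + [f"Mus{i:05d}" for i in range(n_bio)], dtype=object)
    base = rng.lognormal(0.0, 1.2, config.n_genes)
    base[n_mito] = 0.0

    bio_idx = np.arange(n_mito + 1, config.n_genes)
    ortho_idx = rng.choice(bio_idx, n_orthologs, replace=False)
    private_pool = np.setdiff1d(bio_idx, ortho_idx)

    n_marker_total = int(round(config.de_fraction * config.n_genes))
    per = max(4, n_marker_total // config.n_clusters)
    markers_a, markers_b = {}, {}
    o_cursor, p_cursor = 0, 0
    ortho_shuffled = rng.permutation(ortho_idx)
    priv_shuffled = rng.permutation(private_pool)
    conserved = [cl for cl in clusters if cl not in divergent_clusters]
    if not conserved:
        raise ValueError("at least one cluster must remain conserved")
    for cl in conserved:
        g = ortho_shuffled[o_cursor:o_cursor + per]
        o_cursor += per
        markers_a[cl] = {ids_a[i]: config.logfc for i in g}
        markers_b[cl] = {ids_b[i]: config.logfc for i in g}
    # divergent clusters: species-private markers plus *discordant*
    # ortholog-gene signatures, and in species B a half-strength copy of a
    # conserved cluster's markers — a cross-species model sees conflicting
    # shared-gene profiles and confuses the divergent class with its mimic
    mimic_of = {}
    for cl in divergent_clusters:
        ga = priv_shuffled[p_cursor:p_cursor + per]
        gb = priv_shuffled[p_cursor + per:p_cursor + 2 * per]
        p_cursor += 2 * per
        oa = ortho_shuffled[o_cursor:o_cursor + per // 2]
        ob = ortho_shuffled[o_cursor + per // 2:o_cursor + per]
        o_cursor += per
        markers_a[cl] = {ids_a[g]: config.logfc for g in ga}
        markers_a[cl].update({ids_a[i]: config.logfc for i in oa})
        markers_b[cl] = {ids_b[g]: config.logfc for g in gb}
        markers_b[cl].update({ids_b[i]: config.logfc for i in ob})
        mimic = conserved[0]
        mimic_of[cl] = mimic
        markers_b[cl].update({ids_b[i]: 0.5 * config.logfc
                              for i in ortho_idx
                              if ids_b[i] in markers_b[mimic]})

    def _counts(ids, markers, seed_off):
        sub = SimConfig(**{**config.__dict__, "seed": config.seed + seed_off,
                           "ambient_barcodes": 0,
                           "control_cell_fraction": 0.0})
        r = np.random.default_rng(sub.seed)
        labels = np.repeat(clusters, sub.n_cells_per_cluster).astype(object)
        profs = _cluster_profiles(sub, base, ids, markers, clusters)
        batch = r.integers(0, sub.n_batches, len(labels))
        bf = 2.0 ** r.normal(0.0, sub.batch_logfc_sd,
                             (sub.n_batches, sub.n_genes))
        mito_w = r.dirichlet(np.full(n_mito, 5.0))
        depths = r.lognormal(np.log(sub.cell_mean_umi) - 0.25**2 / 2, 0.25,
                             len(labels))
        fr = r.beta(max(sub.mito_fraction_mean, 1e-4) * 80,
                    (1 - max(sub.mito_fraction_mean, 1e-4)) * 80, len(labels))
        vals = np.empty((len(labels), sub.n_genes), dtype=np.int64)
        for j in range(len(labels)):
            mu = _compose_cell_means(profs[labels[j]] * bf[batch[j]],
                                     depths[j], fr[j], mito_w, n_mito)
            vals[j] = _nb(r, mu, sub.nb_dispersion)
        bcs = np.array([f"{ids[n_mito + 1][:3]}BC{i:05d}"
                        for i in range(len(labels))], dtype=object)
        cm = CountMatrix(sp.csr_matrix(vals.T), ids, ids, bcs)
        return cm, labels, np.array([f"B{b + 1}" for b in batch], dtype=object)

    cm_a, lab_a, batch_a = _counts(ids_a, markers_a, 1)
    cm_b, lab_b, batch_b = _counts(ids_b, markers_b, 2)

    # ortholog map: genuine one2one rows + planted multi-mapping rows
    lo, hi = identity_range
    n_low = int(round(low_identity_fraction * n_orthologs))
    ident = np.concatenate([rng.uniform(lo, 74.9, n_low),
                            rng.uniform(75.0, hi, n_orthologs - n_low)])
    rng.shuffle(ident)
    # ortholog genes carrying marker signal must survive the 75% filter
    all_marked = set()
    for cl in clusters:
        all_marked |= set(markers_a[cl]) | set(markers_b[cl])
    marker_ortho = {i for i in ortho_idx
                    if ids_a[i] in all_marked or ids_b[i] in all_marked}
    rows = []
    for pos, i in enumerate(ortho_idx):
        pid = max(ident[pos], 80.0) if i in marker_ortho else ident[pos]
        jitter = rng.uniform(-2, 2)
        rows.append((ids_a[i], ids_b[i], "one2one",
                     round(pid, 2), round(np.clip(pid + jitter, 0, 100), 2)))
    multi_pool = rng.permutation(private_pool[2 * per * len(divergent_clusters):])
    cursor = 0
    for _ in range(n_one2many):
        a = multi_pool[cursor]; b1, b2 = multi_pool[cursor + 1], multi_pool[cursor + 2]
        cursor += 3
        for b in (b1, b2):
            rows.append((ids_a[a], ids_b[b], "one2many",
                         round(rng.uniform(lo, hi), 2), round(rng.uniform(lo, hi), 2)))
    m2m = 0
    while m2m < n_many2many:
        a1, a2, b1, b2 = multi_pool[cursor:cursor + 4]; cursor += 4
        for a, b in [(a1, b1), (a1, b2), (a2, b1), (a2, b2)]:
            if m2m >= n_many2many:
                break
            rows.append((ids_a[a], ids_b[b], "many2many",
                         round(rng.uniform(lo, hi), 2), round(rng.uniform(lo, hi), 2)))
            m2m += 1
    omap = pd.DataFrame(rows, columns=["gene_A", "gene_B", "homology_class",
                                       "pct_identity_AtoB", "pct_identity_BtoA"])

    truth = SynthTruth(
        cell_labels=np.concatenate([lab_a, lab_b]),
        is_cell=np.ones(len(lab_a) + len(lab_b), bool),
        marker_genes={"A": markers_a, "B": markers_b},
        batch_labels=np.concatenate([batch_a, batch_b]),
        ortholog_truth={"conserved": {cl: (cl not in divergent_clusters)
                                      for cl in clusters},
                        "mimic_of": mimic_of},
    )
    return cm_a, cm_b, omap, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def simulate_trajectory(config: SimConfig, branch: bool = False):
    """Cells along a latent time t in [0,1] with smooth gene programs.

    A ``de_fraction`` of genes is *dynamic*: their expected expression rises
    with t following a mix of sigmoid and linear programs (up to 2**logfc
    fold).  With ``branch=True`` cells past t = 0.5 split into two lineages
    whose branch-specific programs diverge.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cells = int(sum(config.n_cells_per_cluster))
    ids, base = _gene_panel(config, rng)
    n_mito = len(MITO_GENES)

    t = rng.uniform(0.0, 1.0, n_cells)
    lineage = np.where(t < 0.5, "trunk",
                       np.where(rng.uniform(size=n_cells) < 0.5, "branchA",
                                "branchB")) if branch else \
        np.repeat(["trunk"], n_cells)

    bio_idx = np.arange(n_mito + 1, config.n_genes)
    n_dyn = int(round(config.de_fraction * config.n_genes))
    dyn = rng.choice(bio_idx, n_dyn, replace=False)
    half = n_dyn // 2
    sig_genes, lin_genes = dyn[:half], dyn[half:]
    amp = 2.0 ** config.logfc - 1.0
    branch_genes = {}
    if branch:
        extra = np.setdiff1d(bio_idx, dyn)
        pick = rng.choice(extra, 2 * max(10, n_dyn // 4), replace=False)
        branch_genes = {"branchA": pick[:len(pick) // 2],
                        "branchB": pick[len(pick) // 2:]}

    depths = rng.lognormal(np.log(config.cell_mean_umi) - 0.25**2 / 2, 0.25,
                           n_cells)
    vals = np.empty((n_cells, config.n_genes), dtype=np.int64)
    for j in range(n_cells):
        p = base.copy()
        s = 1.0 / (1.0 + np.exp(-10.0 * (t[j] - 0.5)))
        p[sig_genes] *= 1.0 + amp * s
        p[lin_genes] *= 1.0 + amp * t[j]
        if branch and lineage[j] != "trunk":
            prog = np.clip((t[j] - 0.5) * 2.0, 0.0, 1.0)
            p[branch_genes[lineage[j]]] *= 1.0 + amp * prog
        mu = depths[j] * p / p.sum()
        vals[j] = _nb(rng, mu, config.nb_dispersion)

    bcs = np.array([f"TBC{i:05d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(vals.T), ids, ids, bcs)
    truth = SynthTruth(
        cell_labels=lineage.astype(object),
        is_cell=np.ones(n_cells, bool),
        marker_genes={"dynamic": {ids[g]: config.logfc for g in dyn}},
        batch_labels=np.repeat(["B1"], n_cells).astype(object),
        true_pseudotime=t,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# cell cycle
# ---------------------------------------------------------------------------

PHASES = ("G1", "S", "G2M")


def simulate_cellcycle(config: SimConfig, n_pairs_per_phase: int = 10):
    """Counts with phase-encoding marker gene pairs and cluster structure.

    For each phase P and each of its pairs ``(g_hi, g_lo)``, the expected
    expression satisfies ``g_hi >> g_lo`` in P cells and ``g_hi << g_lo``
    elsewhere, so the strict ordering holds in >=90% / <=10% of cells.  One
    cluster (the last) is *proliferative*: its cells are G2M-enriched.
    Returns ``(CountMatrix, SynthTruth, pairs)`` with ``pairs`` a dict
    ``phase -> [(g_hi, g_lo), ...]``.
    """
    config.validate()
    if n_pairs_per_phase < 1:
        raise ValueError("n_pairs_per_phase must be >= 1")
    rng = np.random.default_rng(config.seed)
    n_cells = int(sum(config.n_cells_per_cluster))
    ids, base = _gene_panel(config, rng)
    n_mito = len(MITO_GENES)
    clusters = [f"C{i + 1}" for i in range(config.n_clusters)]
    labels = np.repeat(clusters, config.n_cells_per_cluster).astype(object)

    base_p = np.array([0.6, 0.2, 0.2])
    prolif_p = np.array([0.2, 0.2, 0.6])
    phases = np.array([
        PHASES[rng.choice(3, p=prolif_p if labels[j] == clusters[-1] else base_p)]
        for j in range(n_cells)], dtype=object)

    bio_idx = np.arange(n_mito + 1, config.n_genes)
    need = 3 * n_pairs_per_phase * 2
    picked = rng.choice(bio_idx, need, replace=False)
    pairs = {}
    k = 0
    for ph in PHASES:
        pairs[ph] = [(ids[picked[k + 2 * i]], ids[picked[k + 2 * i + 1]])
                     for i in range(n_pairs_per_phase)]
        k += 2 * n_pairs_per_phase
    pos = {g: i for i, g in enumerate(ids)}

    depths = rng.lognormal(np.log(config.cell_mean_umi) - 0.25**2 / 2, 0.25,
                           n_cells)
    hi_rel, lo_rel = 30.0, 1.0  # strong separation so ordering is near-certain
    vals = np.empty((n_cells, config.n_genes), dtype=np.int64)
    for j in range(n_cells):
        p = base.copy()
        for ph in PHASES:
            a, b = (hi_rel, lo_rel) if phases[j] == ph else (lo_rel, hi_rel)
            for g_hi, g_lo in pairs[ph]:
                p[pos[g_hi]] = a
                p[pos[g_lo]] = b
        mu = depths[j] * p / p.sum()
        vals[j] = _nb(rng, mu, config.nb_dispersion)

    bcs = np.array([f"CCBC{i:05d}" for i in range(n_cells)], dtype=object)
    cm = CountMatrix(sp.csr_matrix(vals.T), ids, ids, bcs)
    truth = SynthTruth(
        cell_labels=labels,
        is_cell=np.ones(n_cells, bool),
        marker_genes={},
        batch_labels=np.repeat(["B1"], n_cells).astype(object),
        phase_labels=phases,
    )
    return cm, truth, pairs


# ---------------------------------------------------------------------------
# correlated gene blocks (co-expression module truth)
# ---------------------------------------------------------------------------

def simulate_gene_modules(n_modules: int = 4, genes_per_module: int = 60,
                          n_background: int = 200, n_cells: int = 300,
                          within_r: float = 0.8, seed: int = 0):
    """Log-scale expression with planted correlated gene modules.

    Genes in module m share a latent factor so that within-module Pearson
    correlation is about ``within_r``; background genes are independent
    noise.  Returns ``(expr genes x cells, module_truth)`` where
    ``module_truth[i]`` is the 1-based module of gene i (0 = background).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_modules * genes_per_module + n_background
    load = np.sqrt(within_r)
    noise_sd = np.sqrt(1.0 - within_r)
    expr = np.empty((n_genes, n_cells))
    truth = np.zeros(n_genes, dtype=int)
    row = 0
    for m in range(n_modules):
        factor = rng.normal(0.0, 1.0, n_cells)
        for _ in range(genes_per_module):
            expr[row] = load * factor + noise_sd * rng.normal(0, 1, n_cells)
            truth[row] = m + 1
            row += 1
    expr[row:] = rng.normal(0.0, 1.0, (n_background, n_cells))
    expr += 5.0  # shift to a plausible log-expression range
    return expr, truth
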