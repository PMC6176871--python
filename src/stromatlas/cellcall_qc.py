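"""Barcode calling and cell-level QC for droplet and C1 data.

Cell-containing barcodes are separated from ambient gel beads by the first
local minimum of a kernel density fitted to log10 total UMIs, after a hard
floor of 250 molecules.  Cells with >5% mitochondrial UMIs are removed, and
clusters dominated by a spiked-in transgene-bearing control population are
excluded wholesale.  C1 libraries are flagged by robust outlier rules over
the standard per-library metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .matrix_io import CountMatrix, annotate_cell_table

log = logging.getLogger("stromatlas")


@dataclass
class QCParams:
    min_umi_floor: int = 250
    mito_max_pct: float = 5.0
    kde_bandwidth: float | str = "auto"   # "auto" = Silverman's rule
    control_feature: str | None = None
    mito_prefix: str = "MT-"

    def validate(self) -> None:
        if self.min_umi_floor < 0:
            raise ValueError("min_umi_floor must be >= 0")
        if not 0 < self.mito_max_pct <= 100:
            raise ValueError("mito_max_pct must lie in (0, 100]")


def call_cells(counts: CountMatrix, params: QCParams | None = None):
    """Identify cell-containing barcodes by the density local-minimum rule.

    Barcodes below the 250-UMI floor are discarded first; a Gaussian kernel
    density of log10 totals is then evaluated on a 512-point grid and the
    threshold set at the first interior local minimum scanning from low to
    high totals.  If the density has no interior minimum (unimodal), the
    floor itself is used with a warning.

    Returns ``(threshold_umis, is_cell flags)`` aligned to all input barcodes.
    """
    params = params or QCParams()
    params.validate()
    totals = counts.total_umis().astype(float)
    above = totals >= params.min_umi_floor
    if above.sum() < 2:
        warnings.warn("fewer than 2 barcodes above the UMI floor")
        return float(params.min_umi_floor), above
    x = np.log10(totals[above])
    if np.ptp(x) < 1e-9:
        warnings.warn("degenerate UMI distribution; falling back to floor threshold")
        return float(params.min_umi_floor), above
    bw = None if params.kde_bandwidth == "auto" else params.kde_bandwidth
    kde = gaussian_kde(x, bw_method="silverman" if bw is None else bw)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] < dens[2:]))
    if interior.size == 0:
        warnings.warn("unimodal UMI density: no interior local minimum; "
                      "using the floor threshold")
        threshold = float(params.min_umi_floor)
        is_cell = above.copy()
    else:
        threshold = float(10 ** grid[interior[0] + 1])
        threshold = max(threshold, float(params.min_umi_floor))
        is_cell = (totals > threshold) & above
    log.info("call_cells: threshold=%.1f UMIs, %d/%d barcodes called",
             threshold, int(is_cell.sum()), counts.n_cells)
    return threshold, is_cell


def qc_filter(counts: CountMatrix, cell_table: pd.DataFrame | None,
              params: QCParams | None = None):
    """Remove cells whose mitochondrial UMI percentage exceeds the cutoff.

    The comparison is strict (``> mito_max_pct``): a cell at exactly the
    threshold is retained.  Returns the filtered matrix and an updated cell
    table (totals, genes detected, pct_mito, qc_pass recomputed).
    """
    params = params or QCParams()
    params.validate()
    table = annotate_cell_table(counts, cell_table, params.mito_prefix)
    has_mito = any(str(s).upper().startswith(params.mito_prefix.upper())
                   for s in counts.gene_symbols)
    if not has_mito:
        warnings.warn(f"no gene matches mito prefix {params.mito_prefix!r}; "
                      "skipping the mitochondrial filter")
        keep = np.ones(counts.n_cells, bool)
    else:
        keep = table["pct_mito"].to_numpy() <= params.mito_max_pct
    table = table[keep].copy()
    table["qc_pass"] = True
    out = counts.subset_cells(keep)
    log.info("qc_filter: removed %d cells with pct_mito > %.1f",
             int((~keep).sum()), params.mito_max_pct)
    return out, table


def remove_control_cells(counts: CountMatrix, cell_table: pd.DataFrame,
                         clusters, control_feature: str):
    """Drop whole clusters dominated by the transgene-bearing control cells.

    A cluster is removed when more than half of its cells detect the control
    feature (the lentiviral selection-marker analogue).  Requires an initial
    clustering; removal is cluster-wise, never cell-wise.
    """
    gene_pos = np.flatnonzero((counts.gene_ids == control_feature)
                              | (counts.gene_symbols == control_feature))
    if gene_pos.size == 0:
        raise ValueError(f"control feature {control_feature!r} absent from gene axis")
    detected = np.asarray((counts.values[gene_pos[0]] > 0).todense()).ravel()
    clusters = np.asarray(clusters)
    bad = set()
    for cl in pd.unique(clusters):
        members = clusters == cl
        if detected[members].mean() > 0.5:
            bad.add(cl)
    keep = ~np.isin(clusters, list(bad))
    log.info("remove_control_cells: removed clusters %s (%d cells)",
             sorted(map(str, bad)), int((~keep).sum()))
    return counts.subset_cells(keep), cell_table[keep].copy(), clusters[keep]


# ---------------------------------------------------------------------------
# C1 per-library QC
# ---------------------------------------------------------------------------

C1_METRICS = ["reads_in_features", "genes_detected", "saturation",
              "ercc_fraction", "mito_fraction"]


def qc_filter_c1(metrics: pd.DataFrame, *, mad_k: float = 3.0,
                 ercc_max: float = 0.2, mito_max: float = 0.2,
                 saturation_min: float = 0.0) -> pd.Series:
    """Flag C1 libraries by robust outlier rules over standard QC metrics.

    Fails a library when its log10 total reads or genes detected falls below
    ``median - mad_k * MAD``, or its ERCC / mitochondrial read fraction
    exceeds the caps, or saturation falls below ``saturation_min``.
    Returns a boolean pass/fail Series aligned to the metric table.
    """
    missing = [c for c in C1_METRICS if c not in metrics.columns]
    if missing:
        raise ValueError(f"metric table missing columns: {missing}")
    passed = pd.Series(True, index=metrics.index)
    for col in ("reads_in_features", "genes_detected"):
        x = np.log10(metrics[col].astype(float) + 1.0)
        med, mad = np.median(x), np.median(np.abs(x - np.median(x)))
        passed &= x >= med - mad_k * max(mad, 1e-12) - 1e-12
    passed &= metrics["ercc_fraction"].astype(float) <= ercc_max
    passed &= metrics["mito_fraction"].astype(float) <= mito_max
    passed &= metrics["saturation"].astype(float) >= saturation_min
    passed &= metrics["reads_in_features"].astype(float) > 0
    return passed


def qc_report(table: pd.DataFrame, path: str) -> None:
    """Write the per-barcode/library QC table as TSV."""
    table.to_csv(path, sep="\t")
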