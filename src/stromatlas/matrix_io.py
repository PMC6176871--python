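"""Core dataset containers and readers/writers for the standard exchange formats.

The central object is :class:`CountMatrix` — a genes x cells sparse integer
UMI/read count matrix with gene and barcode identifiers — accompanied by a
per-cell metadata table (:func:`new_cell_table`) and a log-scale
:class:`ExprMatrix` produced by normalization.  On-disk formats are the 10x
Matrix Market triplet (``matrix.mtx`` + ``barcodes.tsv`` + ``genes.tsv``),
dense TSV/CSV count tables with ERCC spike-in rows (Fluidigm C1 style), GMT
gene sets and YAML configuration.
"""

from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

log = logging.getLogger("stromatlas")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Genes x cells non-negative integer count matrix with identifiers.

    Parameters
    ----------
    values
        ``(n_genes, n_cells)`` sparse (CSR) or dense array of non-negative
        integers.
    gene_ids
        Unique gene identifiers (one per row).
    gene_symbols
        Display symbols, aligned to ``gene_ids``.
    barcodes
        Unique cell barcodes (one per column).
    """

    values: sp.spmatrix
    gene_ids: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values))
        else:
            self.values = self.values.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        ng, nc = self.values.shape
        if len(self.gene_ids) != ng or len(self.gene_symbols) != ng:
            raise FormatError("gene identifier length does not match matrix rows")
        if len(self.barcodes) != nc:
            raise FormatError("barcode count does not match matrix columns")
        if len(set(self.gene_ids)) != ng:
            raise FormatError("gene_ids are not unique")
        if len(set(self.barcodes)) != nc:
            raise FormatError("barcodes are not unique")
        data = self.values.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def total_umis(self) -> np.ndarray:
        """Per-cell total counts."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one count."""
        return np.asarray((self.values > 0).sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        return CountMatrix(self.values[:, idx], self.gene_ids,
                           self.gene_symbols, self.barcodes[idx])

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        return CountMatrix(self.values[idx, :], self.gene_ids[idx],
                           self.gene_symbols[idx], self.barcodes)

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class ExprMatrix:
    """Genes x cells real-valued (log-scale) expression with provenance."""

    values: np.ndarray
    gene_ids: np.ndarray
    barcodes: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise FormatError("expression matrix dims inconsistent with identifiers")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("expression values must be finite")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def with_step(self, step: str, values: np.ndarray | None = None) -> "ExprMatrix":
        out = replace(self, values=self.values if values is None else values)
        out.provenance = list(self.provenance) + [step]
        return out

    def subset_genes(self, mask_or_idx) -> "ExprMatrix":
        idx = _as_index(mask_or_idx, self.n_genes)
        out = ExprMatrix(self.values[idx], self.gene_ids[idx], self.barcodes)
        out.provenance = list(self.provenance)
        return out

    def subset_cells(self, mask_or_idx) -> "ExprMatrix":
        idx = _as_index(mask_or_idx, self.n_cells)
        out = ExprMatrix(self.values[:, idx], self.gene_ids, self.barcodes[idx])
        out.provenance = list(self.provenance)
        return out


CELL_TABLE_COLUMNS = [
    "total_umis", "n_genes_detected", "pct_mito", "batch", "sample",
    "cluster", "g1_score", "g2m_score", "phase", "qc_pass",
]


def new_cell_table(barcodes) -> pd.DataFrame:
    """Fresh per-cell metadata table indexed by barcode."""
    tbl = pd.DataFrame(index=pd.Index(np.asarray(barcodes, dtype=object),
                                      name="barcode"))
    tbl["total_umis"] = 0
    tbl["n_genes_detected"] = 0
    tbl["pct_mito"] = np.nan
    tbl["batch"] = "0"
    tbl["sample"] = "0"
    tbl["cluster"] = pd.array([pd.NA] * len(tbl), dtype="string")
    tbl["g1_score"] = np.nan
    tbl["g2m_score"] = np.nan
    tbl["phase"] = pd.array([pd.NA] * len(tbl), dtype="string")
    tbl["qc_pass"] = True
    return tbl


def annotate_cell_table(counts: CountMatrix, table: pd.DataFrame | None = None,
                        mito_prefix: str = "MT-") -> pd.DataFrame:
    """Fill totals, genes detected and mitochondrial percentage."""
    if table is None:
        table = new_cell_table(counts.barcodes)
    totals = counts.total_umis().astype(float)
    table = table.loc[list(counts.barcodes)].copy()
    table["total_umis"] = totals.astype(int)
    table["n_genes_detected"] = counts.genes_detected()
    is_mito = np.array([str(s).upper().startswith(mito_prefix.upper())
                        for s in counts.gene_symbols])
    if is_mito.any():
        mito = np.asarray(counts.values[is_mito].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            table["pct_mito"] = np.where(totals > 0, 100.0 * mito / totals, 0.0)
    else:
        table["pct_mito"] = 0.0
    return table


def _as_index(mask_or_idx, n: int) -> np.ndarray:
    arr = np.asarray(mask_or_idx)
    if arr.dtype == bool:
        if arr.size != n:
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(arr)
    return arr.astype(int)


# ---------------------------------------------------------------------------
# 10x-style Matrix Market triplets
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str, mode: str = "rt"):
    return gzip.open(path, mode) if path.endswith(".gz") else open(path, mode)


def _find(dir_path: str, stems) -> str:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = os.path.join(dir_path, stem + suffix)
            if os.path.exists(p):
                return p
    raise FormatError(f"none of {stems} found in {dir_path}")


def read_mtx_triplet(dir_path: str) -> CountMatrix:
    """Read a 10x-style triplet directory into a :class:`CountMatrix`.

    ``matrix.mtx`` uses 1-based Matrix Market coordinates (genes x cells);
    ``genes.tsv``/``features.tsv`` carries ``gene_id<TAB>symbol`` rows and
    ``barcodes.tsv`` one barcode per line.
    """
    mtx_path = _find(dir_path, ["matrix.mtx"])
    genes_path = _find(dir_path, ["genes.tsv", "features.tsv"])
    bc_path = _find(dir_path, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)

    genes = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    if genes.shape[1] < 2:
        genes[1] = genes[0]
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]
    if len(set(barcodes)) != len(barcodes):
        raise FormatError(f"duplicate barcodes in {bc_path}")
    if mat.shape[0] != len(genes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[0]} rows but {len(genes)} genes in {genes_path}")
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {mat.shape[1]} cols but {len(barcodes)} barcodes in {bc_path}")
    return CountMatrix(mat, genes[0].to_numpy(dtype=object),
                       genes[1].to_numpy(dtype=object),
                       np.asarray(barcodes, dtype=object))


def write_mtx_triplet(counts: CountMatrix, dir_path: str) -> None:
    """Write a triplet directory that :func:`read_mtx_triplet` round-trips."""
    os.makedirs(dir_path, exist_ok=True)
    coo = counts.values.tocoo()
    scipy.io.mmwrite(os.path.join(dir_path, "matrix.mtx"),
                     sp.coo_matrix((coo.data.astype(np.int64),
                                    (coo.row, coo.col)), shape=coo.shape),
                     field="integer")
    pd.DataFrame({0: counts.gene_ids, 1: counts.gene_symbols}).to_csv(
        os.path.join(dir_path, "genes.tsv"), sep="\t", header=False, index=False)
    with open(os.path.join(dir_path, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(map(str, counts.barcodes)) + "\n")


# ---------------------------------------------------------------------------
# dense tables (Fluidigm C1 style, ERCC spike-in rows)
# ---------------------------------------------------------------------------

def read_dense_table(path: str, spike_prefix: str = "ERCC-"):
    """Read a dense gene x cell count table, partitioning spike-in rows.

    Returns ``(CountMatrix, spike_rows)`` where ``spike_rows`` is a dense
    DataFrame of rows whose gene id starts with ``spike_prefix`` (ERCC
    synthetic spike-in controls by convention), removed from the matrix.
    """
    sep = "," if path.endswith(".csv") else "\t"
    tbl = pd.read_csv(path, sep=sep, index_col=0)
    vals = tbl.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals != np.floor(vals)):
        raise FormatError(f"{path}: count table has non-integer entries")
    if np.any(vals < 0):
        raise FormatError(f"{path}: negative counts")
    is_spike = tbl.index.astype(str).str.startswith(spike_prefix)
    spikes = tbl.loc[is_spike]
    body = tbl.loc[~is_spike]
    cm = CountMatrix(sp.csr_matrix(body.to_numpy(dtype=np.int64)),
                     body.index.to_numpy(dtype=object),
                     body.index.to_numpy(dtype=object),
                     body.columns.to_numpy(dtype=object))
    return cm, spikes


# ---------------------------------------------------------------------------
# sample merging (no depth normalization — counts conserved)
# ---------------------------------------------------------------------------

def merge_samples(matrices, batch_labels):
    """Concatenate per-sample matrices over the union of gene ids.

    No down-sampling or depth normalization is performed: every count value
    is conserved.  Barcodes are suffixed ``-<label>`` so they stay unique;
    batch/sample labels are recorded in the returned cell table.
    """
    if len(matrices) != len(batch_labels):
        raise ValueError("one batch label per matrix required")
    union_ids: list = []
    seen = {}
    symbols = {}
    for m in matrices:
        for gid, sym in zip(m.gene_ids, m.gene_symbols):
            if gid not in seen:
                seen[gid] = len(union_ids)
                union_ids.append(gid)
                symbols[gid] = sym
    n_genes = len(union_ids)
    blocks = []
    barcodes: list = []
    batches: list = []
    for m, lab in zip(matrices, batch_labels):
        rows = np.array([seen[g] for g in m.gene_ids])
        coo = m.values.tocoo()
        block = sp.coo_matrix((coo.data, (rows[coo.row], coo.col)),
                              shape=(n_genes, m.n_cells))
        blocks.append(block)
        barcodes.extend(f"{bc}-{lab}" for bc in m.barcodes)
        batches.extend([str(lab)] * m.n_cells)
    if len(set(barcodes)) != len(barcodes):
        raise FormatError("duplicate suffixed barcodes after merge")
    merged = CountMatrix(sp.hstack(blocks).tocsr(),
                         np.asarray(union_ids, dtype=object),
                         np.asarray([symbols[g] for g in union_ids], dtype=object),
                         np.asarray(barcodes, dtype=object))
    table = new_cell_table(merged.barcodes)
    table["batch"] = batches
    table["sample"] = batches
    log.info("merge_samples: %d samples -> %d genes x %d cells",
             len(matrices), merged.n_genes, merged.n_cells)
    return merged, table


# ---------------------------------------------------------------------------
# GMT gene sets and YAML config
# ---------------------------------------------------------------------------

def read_gmt(path: str) -> dict:
    """Read a GMT file: ``name<TAB>description<TAB>gene1<TAB>...`` per line."""
    sets = {}
    with _open_maybe_gz(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def read_yaml_config(path: str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def write_yaml_config(cfg: dict, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
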