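"""Per-cell scRNA-seq quality control on gene-by-cell count matrices.

Low-quality droplets (empty, dying, or multiplet cells) are removed on four
per-cell metrics computed from the raw UMI counts:

* ``n_genes`` — genes with at least one count; very low values indicate empty
  droplets or degraded RNA, very high values indicate doublets;
* ``total_umi`` — library size;
* ``mito_fraction`` — share of UMIs from mitochondrial genes (``MT-`` prefix
  by default); high values indicate dying cells leaking cytoplasmic RNA.

A cell is **removed** iff

    n_genes < min_genes  OR  n_genes > max_genes  OR
    mito_fraction > max_mito_fraction  OR  total_umi < min_total_umi

with defaults 200 / 5000 / 0.10 / 500. The inequalities are strict, so a
cell at exactly 200 genes or exactly 10% mitochondrial UMIs is kept. Every
removed cell carries the list of rules it violated. The UMI rule is read as
a minimum *total* library size of 500; both it and the mitochondrial cutoff
are configurable, since conventions differ between pipelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .errors import EmptyInputError, ValidationError

MITO_PREFIX = "MT-"


@dataclass
class QCThresholds:
    """Per-cell filter cutoffs (see module docstring for the removal rule)."""

    min_genes: int = 200
    max_genes: int = 5000
    max_mito_fraction: float = 0.10
    min_total_umi: int = 500

    def __post_init__(self) -> None:
        if not self.min_genes < self.max_genes:
            raise ValidationError("min_genes must be < max_genes")
        if min(self.min_genes, self.max_genes, self.min_total_umi) <= 0 \
                or self.max_mito_fraction <= 0:
            raise ValidationError("thresholds must be positive")


class CountMatrix:
    """Gene-by-cell UMI count matrix with a declared mitochondrial gene set.

    ``counts`` is stored as a CSR sparse matrix of shape
    ``(n_genes, n_cells)`` with non-negative integer entries. Mitochondrial
    genes default to the ``MT-`` prefix rule; an explicit set overrides it.
    """

    def __init__(self, genes, cells, counts, mito_genes=None):
        self.genes = list(genes)
        self.cells = list(cells)
        counts = sparse.csr_matrix(counts)
        if counts.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {counts.shape} != (genes={len(self.genes)}, "
                f"cells={len(self.cells)})")
        if counts.nnz and counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        self.counts = counts
        if mito_genes is None:
            mito_genes = {g for g in self.genes if g.startswith(MITO_PREFIX)}
        else:
            mito_genes = set(mito_genes)
            unknown = mito_genes - set(self.genes)
            if unknown:
                raise ValidationError(
                    f"mito_genes not in gene list: {sorted(unknown)[:5]}")
        self.mito_genes = mito_genes

    @property
    def shape(self):
        return self.counts.shape

    def subset_cells(self, keep_mask) -> "CountMatrix":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        cells = [c for c, k in zip(self.cells, keep_mask) if k]
        return CountMatrix(self.genes, cells, self.counts[:, keep_mask],
                           mito_genes=self.mito_genes)

    # ---- I/O ------------------------------------------------------------

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, barcodes_path, mito_genes=None):
        """Load a MatrixMarket triplet (matrix + gene and barcode sidecars,
        one identifier per line), genes on the rows."""
        counts = sparse.csr_matrix(mmread(str(mtx_path)))
        genes = Path(genes_path).read_text().split()
        cells = Path(barcodes_path).read_text().split()
        return cls(genes, cells, counts, mito_genes=mito_genes)

    @classmethod
    def from_dense_csv(cls, path, mito_genes=None):
        """Load a dense genes x cells CSV (gene ids in the first column,
        cell barcodes in the header)."""
        df = pd.read_csv(path, index_col=0)
        return cls(df.index, df.columns, df.to_numpy(), mito_genes=mito_genes)

    def to_mtx(self, mtx_path, genes_path, barcodes_path) -> None:
        mmwrite(str(mtx_path), sparse.coo_matrix(self.counts))
        Path(genes_path).write_text("\n".join(self.genes) + "\n")
        Path(barcodes_path).write_text("\n".join(self.cells) + "\n")

    def to_dense_csv(self, path) -> None:
        pd.DataFrame(self.counts.toarray(), index=self.genes,
                     columns=self.cells).to_csv(path)


def compute_qc_metrics(matrix: CountMatrix) -> pd.DataFrame:
    """Per-cell QC metrics, indexed by cell barcode.

    Columns: ``n_genes``, ``total_umi``, ``mito_umi``, ``mito_fraction``.
    ``mito_fraction`` is defined as 0 for an all-zero cell (which fails the
    library-size rule regardless).
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise EmptyInputError("empty count matrix")
    counts = matrix.counts
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel()
    if matrix.mito_genes:
        mito_rows = [i for i, g in enumerate(matrix.genes)
                     if g in matrix.mito_genes]
        mito = np.asarray(counts[mito_rows, :].sum(axis=0)).ravel()
    else:
        warnings.warn("no mitochondrial genes declared; mito_fraction is 0 "
                      "for every cell", stacklevel=2)
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return pd.DataFrame({
        "n_genes": n_genes.astype(int),
        "total_umi": total.astype(int),
        "mito_umi": mito.astype(int),
        "mito_fraction": frac,
    }, index=pd.Index(matrix.cells, name="cell"))


def apply_qc_filter(matrix: CountMatrix, thresholds: QCThresholds = None):
    """Apply the removal rule; returns ``(filtered_matrix, report)``.

    The report has one row per input cell with the QC metrics, a boolean
    ``keep`` column, and a ``reasons`` column (semicolon-joined names of the
    violated rules, empty for kept cells). The gene axis is never changed,
    and the filter is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    metrics = compute_qc_metrics(matrix)
    reasons = []
    for _, m in metrics.iterrows():
        why = []
        if m["n_genes"] < thresholds.min_genes:
            why.append("low_n_genes")
        if m["n_genes"] > thresholds.max_genes:
            why.append("high_n_genes")
        if m["mito_fraction"] > thresholds.max_mito_fraction:
            why.append("high_mito_fraction")
        if m["total_umi"] < thresholds.min_total_umi:
            why.append("low_total_umi")
        reasons.append(";".join(why))
    report = metrics.copy()
    report["reasons"] = reasons
    report["keep"] = [r == "" for r in reasons]
    return matrix.subset_cells(report["keep"].to_numpy()), report


def simulate_counts(n_genes: int, n_cells: int, mito_gene_count: int = 10,
                    seed: int = 0, mean_library_size: float = 5000.0,
                    library_sigma: float = 0.35,
                    mito_beta: tuple = (2.0, 38.0),
                    n_high_mito: int = 0,
                    high_mito_beta: tuple = (30.0, 70.0),
                    dirichlet_alpha: float = 0.3) -> CountMatrix:
    """Synthetic UMI count matrix with realistic per-cell structure.

    Per-cell library sizes are log-normal with the given mean (on the natural
    scale) and log-sd ``library_sigma``; gene propensities are a single
    Dirichlet draw shared by all cells (so genes differ widely in expression,
    as in real data); each cell's mitochondrial share is Beta-distributed
    (default mean 5%), with an optional dying subpopulation of
    ``n_high_mito`` cells drawn from ``high_mito_beta`` (default mean 30%,
    above the 10% cutoff). Deterministic under ``seed``.
    """
    if min(n_genes, n_cells) < 1 or mito_gene_count < 0 \
            or mito_gene_count > n_genes:
        raise ValidationError("invalid matrix dimensions")
    rng = np.random.default_rng(seed)
    genes = [f"{MITO_PREFIX}{i}" for i in range(mito_gene_count)] + \
            [f"GENE{i}" for i in range(n_genes - mito_gene_count)]
    cells = [f"cell{i:05d}" for i in range(n_cells)]

    mu = np.log(mean_library_size) - library_sigma ** 2 / 2
    libsize = np.maximum(1, np.round(
        rng.lognormal(mu, library_sigma, n_cells))).astype(int)

    n_nuc = n_genes - mito_gene_count
    p_mito = rng.dirichlet(np.full(max(mito_gene_count, 1), dirichlet_alpha)) \
        if mito_gene_count else np.empty(0)
    p_nuc = rng.dirichlet(np.full(max(n_nuc, 1), dirichlet_alpha)) \
        if n_nuc else np.empty(0)

    frac = rng.beta(*mito_beta, size=n_cells)
    if n_high_mito:
        high = rng.choice(n_cells, size=min(n_high_mito, n_cells), replace=False)
        frac[high] = rng.beta(*high_mito_beta, size=len(high))
    if not mito_gene_count:
        frac[:] = 0.0

    mat = np.zeros((n_genes, n_cells), dtype=np.int64)
    for j in range(n_cells):
        m = rng.binomial(libsize[j], frac[j])
        if mito_gene_count and m:
            mat[:mito_gene_count, j] = rng.multinomial(m, p_mito)
        if n_nuc and libsize[j] - m:
            mat[mito_gene_count:, j] = rng.multinomial(libsize[j] - m, p_nuc)
    return CountMatrix(genes, cells, sparse.csr_matrix(mat))
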