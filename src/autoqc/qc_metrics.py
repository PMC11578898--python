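"""Per-cell quality-control metrics for droplet scRNA-seq count matrices.

Eight metrics are computed per cell/droplet and drive everything downstream:

* ``log1p_n_counts`` — natural log of (1 + total UMI counts),
* ``log1p_n_genes`` — natural log of (1 + number of genes detected),
* ``percent_mito`` / ``percent_ribo`` / ``percent_hb`` — percentage of counts
  in mitochondrial, ribosomal-protein and haemoglobin genes,
* ``percent_top50`` — percentage of counts concentrated in the cell's 50
  most-expressed genes (low-complexity indicator),
* ``percent_soup`` — percentage of counts attributed to ambient RNA by an
  upstream ambient-removal tool (consumed, not computed here),
* ``percent_spliced`` — percentage of spliced molecules among
  spliced + unspliced totals (debris / nuclei indicator).

The last two derive from optional auxiliary inputs; when absent they are
missing (NaN), never silently zero.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import AlignmentError, IOFormatError

#: Fixed metric column order used by every writer and reader in the package.
METRIC_COLUMNS = [
    "log1p_n_counts",
    "log1p_n_genes",
    "percent_mito",
    "percent_ribo",
    "percent_hb",
    "percent_top50",
    "percent_soup",
    "percent_spliced",
]


@dataclass
class CountsMatrix:
    """Cells-by-genes raw count matrix with barcode and gene identifiers.

    ``counts`` is stored as CSR so that per-cell nonzero iteration is cheap.
    Entries must be non-negative integers; barcodes and gene IDs unique.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: sp.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        n_cells, n_genes = self.counts.shape
        if n_cells < 1 or n_genes < 1:
            raise IOFormatError("count matrix needs at least 1 cell and 1 gene")
        if len(self.cell_ids) != n_cells:
            raise IOFormatError(
                f"{len(self.cell_ids)} barcodes for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise IOFormatError(
                f"{len(self.gene_ids)} features for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise IOFormatError("duplicate cell barcodes")
        if len(set(self.gene_ids)) != n_genes:
            raise IOFormatError("duplicate gene identifiers")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise IOFormatError("negative entries in count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            data = self.counts.data
            if not np.allclose(data, np.round(data)):
                raise IOFormatError("non-integer entries in count matrix")
            self.counts = self.counts.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]


@dataclass
class AuxiliaryCellData:
    """Optional per-cell vectors produced by upstream tools.

    Each vector, when present, must align 1:1 (positionally) with
    ``CountsMatrix.cell_ids``.  ``soup_fraction`` and ``doublet_score`` live
    in [0, 1]; spliced/unspliced totals are non-negative.
    """

    spliced_total: np.ndarray | None = None
    unspliced_total: np.ndarray | None = None
    soup_fraction: np.ndarray | None = None
    doublet_score: np.ndarray | None = None

    def validate(self, n_cells: int) -> None:
        for name in ("spliced_total", "unspliced_total", "soup_fraction", "doublet_score"):
            vec = getattr(self, name)
            if vec is None:
                continue
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (n_cells,):
                raise AlignmentError(
                    f"{name} has length {vec.shape[0]}, expected {n_cells}"
                )
            finite = vec[np.isfinite(vec)]
            if name in ("soup_fraction", "doublet_score"):
                if finite.size and (finite.min() < 0 or finite.max() > 1):
                    raise AlignmentError(f"{name} values outside [0, 1]")
            elif finite.size and finite.min() < 0:
                raise AlignmentError(f"{name} contains negative totals")
            setattr(self, name, vec)


@dataclass
class GeneSetConfig:
    """Gene-symbol matchers for the percentage metrics (human defaults)."""

    mito_prefixes: tuple[str, ...] = ("MT-",)
    ribo_prefixes: tuple[str, ...] = ("RPS", "RPL")
    hb_regex: str = r"^HB[ABDEGMQZ]"
    top_n: int = 50

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    def mito_mask(self, gene_ids: list[str]) -> np.ndarray:
        return np.array(
            [any(g.upper().startswith(p) for p in self.mito_prefixes) for g in gene_ids]
        )

    def ribo_mask(self, gene_ids: list[str]) -> np.ndarray:
        return np.array(
            [any(g.upper().startswith(p) for p in self.ribo_prefixes) for g in gene_ids]
        )

    def hb_mask(self, gene_ids: list[str]) -> np.ndarray:
        pat = re.compile(self.hb_regex)
        return np.array([bool(pat.match(g.upper())) for g in gene_ids])


def _percent_top_n(counts: sp.csr_matrix, total: np.ndarray, top_n: int) -> np.ndarray:
    """Share (in %) of each cell's counts held by its top_n largest genes."""
    out = np.full(counts.shape[0], np.nan)
    indptr = counts.indptr
    data = counts.data
    for i in range(counts.shape[0]):
        if total[i] <= 0:
            continue
        row = data[indptr[i]: indptr[i + 1]]
        if row.size <= top_n:
            out[i] = 100.0
        else:
            top = np.partition(row, row.size - top_n)[row.size - top_n:]
            out[i] = 100.0 * top.sum() / total[i]
    return out


def compute_qc_metrics(
    counts: CountsMatrix,
    aux: AuxiliaryCellData | None = None,
    genesets: GeneSetConfig | None = None,
) -> pd.DataFrame:
    """Compute the eight per-cell QC metrics.

    Returns a DataFrame indexed by barcode with the columns of
    :data:`METRIC_COLUMNS` plus a boolean ``valid`` column.  Cells with zero
    total counts are flagged ``valid=False`` (their percentage metrics are
    NaN) and automatically fail QC downstream.  Metrics whose auxiliary input
    is absent are NaN, not zero.
    """
    genesets = genesets or GeneSetConfig()
    aux = aux or AuxiliaryCellData()
    aux.validate(counts.n_cells)

    mat = counts.counts
    total = np.asarray(mat.sum(axis=1)).ravel().astype(float)
    n_genes = np.asarray((mat > 0).sum(axis=1)).ravel().astype(float)
    valid = total > 0

    def pct(mask: np.ndarray) -> np.ndarray:
        sub = np.asarray(mat[:, mask].sum(axis=1)).ravel().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(valid, 100.0 * sub / total, np.nan)

    out = pd.DataFrame(index=pd.Index(counts.cell_ids, name="barcode"))
    out["log1p_n_counts"] = np.log1p(total)
    out["log1p_n_genes"] = np.log1p(n_genes)
    out["percent_mito"] = pct(genesets.mito_mask(counts.gene_ids))
    out["percent_ribo"] = pct(genesets.ribo_mask(counts.gene_ids))
    out["percent_hb"] = pct(genesets.hb_mask(counts.gene_ids))
    out["percent_top50"] = _percent_top_n(mat, total, genesets.top_n)

    if aux.soup_fraction is not None:
        out["percent_soup"] = 100.0 * aux.soup_fraction
    else:
        out["percent_soup"] = np.nan

    if aux.spliced_total is not None and aux.unspliced_total is not None:
        denom = aux.spliced_total + aux.unspliced_total
        with np.errstate(divide="ignore", invalid="ignore"):
            spliced = np.where(denom > 0, 100.0 * aux.spliced_total / denom, np.nan)
        out["percent_spliced"] = spliced
    else:
        out["percent_spliced"] = np.nan

    out.loc[~valid, [c for c in METRIC_COLUMNS if c.startswith("percent")]] = np.nan
    out["valid"] = valid
    return out
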