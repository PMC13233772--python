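"""Shared in-memory containers for the analysis pipeline.

The central object is :class:`CountMatrix`, a thin wrapper around a sparse
cells x genes UMI count matrix with aligned per-cell metadata. It converts
to/from :class:`anndata.AnnData`, which is the on-disk interchange format.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "REMOVED"]

#: Sentinel state label for cells dropped during outlier removal / refinement.
REMOVED = "removed"


@dataclass
class CountMatrix:
    """Sparse cells x genes UMI count matrix plus per-cell metadata.

    Parameters
    ----------
    counts
        Nonnegative integer-valued sparse matrix, one row per cell.
    cell_meta
        DataFrame indexed by cell identifier, one row per cell. A
        ``cell_type`` column is used by the refinement rules when present.
    gene_ids
        Ordered gene symbols, one per column.
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_ids: pd.Index

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        n, g = self.counts.shape
        if len(self.cell_meta) != n:
            raise ValueError(
                f"cell_meta has {len(self.cell_meta)} rows for {n} cells"
            )
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries for {g} genes"
            )
        if self.counts.nnz:
            data = self.counts.data
            if data.min() < 0:
                raise ValueError("counts must be nonnegative")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integer-valued UMIs")
        if self.cell_meta.index.has_duplicates:
            raise ValueError("duplicate cell identifiers")

    # -- accessors ---------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_meta.index

    def gene_index(self, symbols) -> np.ndarray:
        """Column positions of ``symbols`` (raises on a missing symbol)."""
        idx = self.gene_ids.get_indexer(list(symbols))
        if (idx < 0).any():
            missing = [s for s, i in zip(symbols, idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing}")
        return idx

    # -- subsetting --------------------------------------------------------
    def subset_genes(self, positions) -> "CountMatrix":
        positions = np.asarray(positions)
        return CountMatrix(
            counts=self.counts[:, positions],
            cell_meta=self.cell_meta,
            gene_ids=self.gene_ids[positions],
        )

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            positions = np.flatnonzero(mask)
        else:
            positions = mask
        return CountMatrix(
            counts=self.counts[positions],
            cell_meta=self.cell_meta.iloc[positions],
            gene_ids=self.gene_ids,
        )

    # -- interchange -------------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        return ad.AnnData(
            X=self.counts.copy(),
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.gene_ids),
        )

    @classmethod
    def from_anndata(cls, adata, sum_layers: bool = True) -> "CountMatrix":
        """Build from an AnnData; sums spliced+unspliced layers when present."""
        X = adata.X
        if sum_layers and {"spliced", "unspliced"} <= set(adata.layers):
            X = adata.layers["spliced"] + adata.layers["unspliced"]
        X = sp.csr_matrix(X)
        return cls(
            counts=X,
            cell_meta=adata.obs.copy(),
            gene_ids=pd.Index(adata.var_names),
        )


def log_normalize(matrix: CountMatrix, target_sum: float = 1e4) -> np.ndarray:
    """Counts-per-``target_sum`` log1p normalization, returned dense.

    Cells with zero total counts are left at zero.
    """
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    scale = np.divide(
        target_sum, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0
    )
    X = matrix.counts.multiply(scale[:, None]).tocsr()
    X.data = np.log1p(X.data)
    return np.asarray(X.todense())
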