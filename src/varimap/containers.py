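"""Core in-memory containers shared across the pipeline.

Count data are held genes x cells (the orientation of a 10x MatrixMarket
file); per-cell metadata are a :class:`pandas.DataFrame` indexed by cell
barcode. Containers validate their invariants on construction so that
downstream stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "SpatialDataset",
    "ValidationError",
]


class ValidationError(ValueError):
    """A container or configuration violated one of its invariants."""


def _check_ids(ids, n: int, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(ids) != n:
        raise ValidationError(
            f"{what}: got {len(ids)} identifiers for {n} matrix rows/columns"
        )
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, genes x cells.

    Parameters
    ----------
    X
        Sparse matrix of shape ``(n_genes, n_cells)``; coerced to CSR.
    gene_ids
        Unique gene identifiers, one per row.
    cell_ids
        Unique cell barcodes, one per column.
    """

    X: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.X = sp.csr_matrix(self.X)
        self.gene_ids = _check_ids(self.gene_ids, self.X.shape[0], "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.X.shape[1], "cell_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids are not unique")
        if self.X.nnz and self.X.data.min() < 0:
            raise ValidationError("count matrix has negative entries")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_cells(self) -> int:
        return self.X.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total counts per cell (column sums)."""
        return np.asarray(self.X.sum(axis=0)).ravel()

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        """Subset columns by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(int)
        return CountMatrix(
            self.X[:, idx],
            self.gene_ids,
            [self.cell_ids[i] for i in idx],
        )

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return CountMatrix(self.X[idx, :], list(genes), self.cell_ids)


@dataclass
class NormalizedMatrix:
    """Real-valued expression, genes x cells, with normalization provenance.

    ``provenance`` records the transformations applied (e.g. the log
    scale factor, whether genes were centered/scaled) so that serialized
    artifacts are self-describing.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("normalized matrix must be 2-D")
        self.gene_ids = _check_ids(self.gene_ids, self.values.shape[0], "gene_ids")
        self.cell_ids = _check_ids(self.cell_ids, self.values.shape[1], "cell_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("normalized matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "NormalizedMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return NormalizedMatrix(
            self.values[idx, :], list(genes), self.cell_ids, dict(self.provenance)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class SpatialDataset:
    """Spot-level counts plus array coordinates for spatial transcriptomics.

    ``counts`` is genes x spots; ``positions`` is indexed by spot barcode
    with integer array coordinates ``x``/``y`` and an optional ``layer``
    annotation (1-based zonation layer along the lobule axis).
    """

    counts: CountMatrix
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"x", "y"}
        if not need.issubset(self.positions.columns):
            raise ValidationError("spot positions need 'x' and 'y' columns")
        if list(self.positions.index) != list(self.counts.cell_ids):
            raise ValidationError("positions index does not match spot barcodes")
        if self.positions[["x", "y"]].duplicated().any():
            raise ValidationError("spot coordinates are not unique")

    @property
    def n_spots(self) -> int:
        return self.counts.n_cells

    def subset_genes(self, genes: list[str]) -> "SpatialDataset":
        return SpatialDataset(self.counts.subset_genes(genes), self.positions)
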