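"""Ingest, per-cell QC, filtering, normalization, HVG selection and scaling.

Implements the standard preprocessing chain feeding the factor model:
read a 10x-style MTX triplet, compute per-cell library size / expressed
genes / mitochondrial fraction, apply per-sample thresholds, log-normalize
counts-per-``scale``, pick highly variable genes by cross-cell variance,
and z-scale genes with clipping.

Thresholds are per sample because dissociation quality differs between
preparations: a cell is retained iff its library size is at least the
sample's minimum AND its mitochondrial percentage is at most the sample's
maximum (a cell exactly on either boundary is retained).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, NormalizedMatrix, SpatialDataset, ValidationError

__all__ = [
    "QCThresholds",
    "read_10x_mtx",
    "compute_cell_qc",
    "filter_cells",
    "normalize_log",
    "select_hvgs",
    "scale_genes",
    "spatial_gene_filter",
    "MITO_PATTERN",
]

logger = logging.getLogger("varimap")

#: Default mitochondrial gene pattern: case-insensitive "Mt-" prefix
#: (the rat/mouse symbol convention).
MITO_PATTERN = r"(?i)^mt-"


@dataclass
class QCThresholds:
    """Per-sample QC cutoffs.

    ``min_library_size`` and ``max_mito_percent`` map sample_id -> value.
    Cells with library size below the minimum or mitochondrial percentage
    above the maximum are removed.
    """

    min_library_size: dict[str, float] = field(default_factory=dict)
    max_mito_percent: dict[str, float] = field(default_factory=dict)

    def validate(self, samples: list[str]) -> None:
        for s in samples:
            if s not in self.min_library_size or s not in self.max_mito_percent:
                raise ValidationError(f"no QC thresholds configured for sample {s!r}")
        for s, v in self.min_library_size.items():
            if v < 0:
                raise ValidationError(f"min_library_size for {s!r} must be >= 0")
        for s, v in self.max_mito_percent.items():
            if not (0 < v <= 100):
                raise ValidationError(
                    f"max_mito_percent for {s!r} must be in (0, 100]"
                )


def _open_maybe_gz(path: Path):
    return gzip.open(path, "rt") if path.suffix == ".gz" else open(path)


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {stem}[.gz] in {directory}")


def read_10x_mtx(directory: str | Path) -> CountMatrix:
    """Read a 10x MTX triplet directory (plain or gzipped).

    Gene identifiers come from the second column of features.tsv (the
    symbol) when present, else the first; duplicate symbols are
    disambiguated deterministically with ".1", ".2", ... suffixes in file
    order.
    """
    directory = Path(directory)
    mtx_path = _find(directory, "matrix.mtx")
    try:
        features_path = _find(directory, "features.tsv")
    except FileNotFoundError:
        features_path = _find(directory, "genes.tsv")  # CellRanger v2 layout
    barcodes_path = _find(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path) as fh:
        X = scipy.io.mmread(fh)
    X = sp.csr_matrix(X)

    with _open_maybe_gz(features_path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    symbols = [r[1] if len(r) > 1 else r[0] for r in rows]
    with _open_maybe_gz(barcodes_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if X.shape[0] != len(symbols) or X.shape[1] != len(barcodes):
        raise ValidationError(
            f"matrix is {X.shape[0]}x{X.shape[1]} but features/barcodes have "
            f"{len(symbols)}/{len(barcodes)} entries"
        )

    seen: dict[str, int] = {}
    unique: list[str] = []
    for s in symbols:
        if s in seen:
            seen[s] += 1
            unique.append(f"{s}.{seen[s]}")
        else:
            seen[s] = 0
            unique.append(s)
    return CountMatrix(X, unique, barcodes)


def compute_cell_qc(
    counts: CountMatrix, mito_pattern: str = MITO_PATTERN
) -> pd.DataFrame:
    """Per-cell QC statistics: library size, expressed genes, mito fraction.

    ``mito_fraction`` is the share of counts on genes matching
    ``mito_pattern``; it is defined as 0 for cells with zero library size.
    """
    pat = re.compile(mito_pattern)
    mito_mask = np.array([bool(pat.search(g)) for g in counts.gene_ids])
    if not mito_mask.any():
        logger.warning(
            "mito pattern %r matched no genes; mito fractions set to 0", mito_pattern
        )
    lib = counts.library_sizes().astype(float)
    csc = counts.X.tocsc()
    n_genes = np.diff(csc.indptr)
    mito_counts = (
        np.asarray(csc[mito_mask, :].sum(axis=0)).ravel()
        if mito_mask.any()
        else np.zeros(counts.n_cells)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(lib > 0, mito_counts / np.maximum(lib, 1e-300), 0.0)
    return pd.DataFrame(
        {
            "library_size": lib,
            "n_genes_expressed": n_genes,
            "mito_fraction": mito_frac,
        },
        index=counts.cell_ids,
    )


def filter_cells(
    counts: CountMatrix, meta: pd.DataFrame, thresholds: QCThresholds
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply per-sample library-size / mitochondrial filters.

    ``meta`` must carry ``sample_id``, ``library_size`` and
    ``mito_fraction`` columns aligned to the cells. Retains exactly the
    cells with ``library_size >= min_library_size(sample)`` and
    ``mito_fraction * 100 <= max_mito_percent(sample)``, preserving cell
    order, and logs per-sample retained counts.
    """
    for col in ("sample_id", "library_size", "mito_fraction"):
        if col not in meta.columns:
            raise ValidationError(f"cell metadata lacks required column {col!r}")
    samples = list(pd.unique(meta["sample_id"]))
    thresholds.validate(samples)

    min_lib = meta["sample_id"].map(thresholds.min_library_size).to_numpy(float)
    max_mito = meta["sample_id"].map(thresholds.max_mito_percent).to_numpy(float)
    keep = (meta["library_size"].to_numpy(float) >= min_lib) & (
        meta["mito_fraction"].to_numpy(float) * 100.0 <= max_mito
    )
    for s in samples:
        in_s = (meta["sample_id"] == s).to_numpy()
        logger.info(
            "QC sample %s: retained %d / %d cells", s, int(keep[in_s].sum()), int(in_s.sum())
        )
    return counts.subset_cells(keep), meta.loc[keep].copy()


def normalize_log(counts: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Log-normalize: ``log(1 + scale * count / library_size)`` per cell.

    Cells with zero library size must have been removed upstream.
    """
    if scale <= 0:
        raise ValidationError("normalization scale must be positive")
    lib = counts.library_sizes().astype(float)
    if np.any(lib <= 0):
        raise ValidationError("normalize_log requires positive library sizes")
    X = counts.X.astype(float).multiply(scale / lib[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return NormalizedMatrix(
        X.toarray(),
        counts.gene_ids,
        counts.cell_ids,
        provenance={"normalization": "log1p_cp", "scale": scale},
    )


def select_hvgs(norm: NormalizedMatrix, n: int) -> list[str]:
    """Top-``n`` genes by variance of normalized expression across cells.

    Ties are broken by gene order (stable sort on decreasing variance).
    """
    if n > norm.n_genes:
        raise ValidationError(f"requested {n} HVGs from {norm.n_genes} genes")
    var = norm.values.var(axis=1, ddof=1) if norm.n_cells > 1 else np.zeros(norm.n_genes)
    order = np.argsort(-var, kind="stable")
    return [norm.gene_ids[i] for i in order[:n]]


def scale_genes(norm: NormalizedMatrix, clip: float = 10.0) -> NormalizedMatrix:
    """Center each gene to mean 0 and unit sample variance, clipping to ±clip.

    Constant genes become all zeros (no division by zero).
    """
    vals = norm.values
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True) if vals.shape[1] > 1 else np.ones_like(mean)
    centered = vals - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
    scaled = np.clip(scaled, -clip, clip)
    prov = dict(norm.provenance)
    prov.update({"scaled": True, "clip": clip, "sd_ddof": 1})
    return NormalizedMatrix(scaled, norm.gene_ids, norm.cell_ids, prov)


def spatial_gene_filter(
    spots: SpatialDataset,
    min_detection_freq: float = 0.05,
    min_max_count: int = 3,
    combine: str = "and",
) -> tuple[SpatialDataset, list[str]]:
    """Remove weakly captured genes from a spatial dataset.

    With ``combine='and'`` (default) a gene is removed when its detection
    frequency is below ``min_detection_freq`` AND its maximum count is
    below ``min_max_count``; ``combine='or'`` removes on either criterion.
    Returns the gene-subset dataset and the removed genes.
    """
    if not (0 <= min_detection_freq <= 1):
        raise ValidationError("min_detection_freq must be in [0, 1]")
    if min_max_count < 0:
        raise ValidationError("min_max_count must be >= 0")
    if combine not in ("and", "or"):
        raise ValidationError("combine must be 'and' or 'or'")
    X = spots.counts.X.tocsr()
    n_spots = spots.n_spots
    det_freq = np.asarray((X > 0).sum(axis=1)).ravel() / max(n_spots, 1)
    max_count = X.max(axis=1).toarray().ravel() if X.nnz else np.zeros(X.shape[0])
    low_freq = det_freq < min_detection_freq
    low_max = max_count < min_max_count
    remove = (low_freq & low_max) if combine == "and" else (low_freq | low_max)
    kept = [g for g, r in zip(spots.counts.gene_ids, remove) if not r]
    removed = [g for g, r in zip(spots.counts.gene_ids, remove) if r]
    logger.info("spatial gene filter: removed %d / %d genes", len(removed), X.shape[0])
    return spots.subset_genes(kept), removed
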