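"""Lobule-zonation axis detection and cross-profile correlation.

In liver spatial data the dominant axis of variation is the periportal
to pericentral zonation gradient. Here a PCA over spots is anchored on
known marker sets: for each candidate factor the separation between
periportal- and pericentral-marker loading ranks picks the zonation
axis, whose sign is set so periportal markers load positively. Per-spot
zonation scores are the standardized signed factor scores.

The module also provides the two cross-profile correlation analyses
used to place clusters on the zonation axis and across species:
z-score-based cluster-vs-layer correlation (each side z-scored per gene
across its own columns) and ortholog-restricted cluster-cluster
correlation with Ward ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from scipy.cluster.hierarchy import leaves_list, ward
from scipy.spatial.distance import squareform

from .containers import SpatialDataset, ValidationError
from .factor import FactorModel, fit_pca
from .qc import normalize_log, scale_genes

__all__ = [
    "MarkerSets",
    "ZonationAxis",
    "fit_spatial_pca",
    "identify_zonation_axis",
    "zonation_score",
    "layer_cluster_correlation",
    "ortholog_cluster_correlation",
]

logger = logging.getLogger("varimap")


@dataclass
class MarkerSets:
    """Periportal and pericentral marker gene lists (disjoint, non-empty)."""

    periportal: list[str]
    pericentral: list[str]

    def __post_init__(self) -> None:
        if not self.periportal or not self.pericentral:
            raise ValidationError("both marker lists must be non-empty")
        if set(self.periportal) & set(self.pericentral):
            raise ValidationError("marker sets overlap")


@dataclass
class ZonationAxis:
    """The factor carrying the zonation gradient, signed periportal-positive."""

    factor: int
    sign: int  # +1 toward periportal after signing
    rank_difference: float
    periportal_p: float  # one-sided enrichment of PP markers at the + pole
    pericentral_p: float

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValidationError("axis sign must be -1 or +1")


def fit_spatial_pca(
    spots: SpatialDataset, K: int, scale: float = 1e4, clip: float = 10.0
) -> FactorModel:
    """PCA over spots: log-normalize, z-scale genes, then fit.

    Spots play the role of cells; apply :func:`~varimap.qc.spatial_gene_filter`
    first to drop weakly captured genes.
    """
    norm = normalize_log(spots.counts, scale=scale)
    scaled = scale_genes(norm, clip=clip)
    return fit_pca(scaled, K)


def identify_zonation_axis(
    model: FactorModel,
    markers: MarkerSets,
    n_candidates: int = 5,
    alpha: float = 0.05,
) -> ZonationAxis:
    """Pick the factor separating periportal from pericentral markers.

    For each of the first ``n_candidates`` factors, loadings are ranked
    over genes and the statistic is the difference in mean loading rank
    between periportal and pericentral markers; the factor maximizing
    |difference| is selected and signed so periportal markers load
    positively. Per-pole enrichment is a one-sided rank-sum test of the
    marker loadings against all other genes; if neither pole of any
    candidate is significant at ``alpha`` an error advises marker review.
    """
    gene_pos = {g: i for i, g in enumerate(model.gene_ids)}
    pp = [gene_pos[g] for g in markers.periportal if g in gene_pos]
    pc = [gene_pos[g] for g in markers.pericentral if g in gene_pos]
    if len(pp) < 3 or len(pc) < 3:
        raise ValidationError(
            f"need >= 3 markers of each pole in the loading universe "
            f"(found {len(pp)} periportal, {len(pc)} pericentral)"
        )
    n_candidates = min(n_candidates, model.n_factors)

    best = None
    for k in range(n_candidates):
        ranks = scipy.stats.rankdata(model.loadings[:, k])
        diff = ranks[pp].mean() - ranks[pc].mean()
        if best is None or abs(diff) > abs(best[1]):
            best = (k, diff)
    k, diff = best
    sign = 1 if diff >= 0 else -1
    signed = sign * model.loadings[:, k]

    other = np.setdiff1d(np.arange(len(model.gene_ids)), np.array(pp + pc))
    pp_p = scipy.stats.mannwhitneyu(
        signed[pp], signed[other], alternative="greater"
    ).pvalue
    pc_p = scipy.stats.mannwhitneyu(
        signed[pc], signed[other], alternative="less"
    ).pvalue
    if pp_p > alpha and pc_p > alpha:
        raise ValidationError(
            "no candidate factor separates the marker poles "
            f"(best factor {k + 1}: periportal p={pp_p:.3g}, pericentral p={pc_p:.3g}); "
            "review the marker sets"
        )
    return ZonationAxis(
        factor=k,
        sign=sign,
        rank_difference=float(diff),
        periportal_p=float(pp_p),
        pericentral_p=float(pc_p),
    )


def zonation_score(
    spots: SpatialDataset, axis: ZonationAxis, model: FactorModel
) -> pd.Series:
    """Standardized signed factor score per spot (mean 0, sd 1).

    Positive scores are periportal-like; flipping the axis sign negates
    the scores.
    """
    s = axis.sign * model.scores[:, axis.factor]
    sd = s.std(ddof=0)
    s = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return pd.Series(s, index=model.cell_ids)


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    """z-score each gene (row) across the frame's columns; drop constants."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    keep = sd > 0
    if (~keep).any():
        logger.warning("dropping %d constant genes before z-scoring", int((~keep).sum()))
    return df.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)


def _corr_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t approximation at n samples."""
    if n < 3 or not np.isfinite(r) or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n >= 3 else np.nan
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * scipy.stats.t.sf(abs(t), df=n - 2))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def layer_cluster_correlation(
    cluster_means: pd.DataFrame,
    layer_means: pd.DataFrame,
    shared_genes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate cluster profiles with zonation-layer profiles.

    Each side is z-scored per gene across its own columns (so the result
    is invariant to per-gene affine transforms on either side), then
    Pearson r is computed between every cluster and every layer over the
    shared genes. Returns the r matrix (clusters x layers) and matching
    significance stars (two-sided t approximation: * <0.05, ** <0.01,
    *** <0.001).
    """
    shared = [
        g for g in shared_genes if g in cluster_means.index and g in layer_means.index
    ]
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared genes, found {len(shared)}")
    a = _zscore_rows(cluster_means.loc[shared])
    b = _zscore_rows(layer_means.loc[shared])
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    n = len(common)
    r = pd.DataFrame(index=a.columns, columns=b.columns, dtype=float)
    stars = pd.DataFrame(index=a.columns, columns=b.columns, dtype=object)
    for ci in a.columns:
        for li in b.columns:
            rv = float(np.corrcoef(a[ci], b[li])[0, 1])
            r.loc[ci, li] = rv
            stars.loc[ci, li] = _stars(_corr_p(rv, n))
    return r, stars


def ortholog_cluster_correlation(
    profiles_a: pd.DataFrame,
    profiles_b: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    hvg_n: int = 2000,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Cross-dataset cluster correlation over one-to-one orthologs.

    ``ortholog_map`` has two columns (gene in A, gene in B); duplicated
    genes on either side are dropped with a warning so the map is
    one-to-one. Genes are restricted to the intersection of each side's
    top-``hvg_n`` most variable genes (variance across that side's
    cluster columns); Pearson r is computed per cluster pair, and rows/
    columns are ordered by Ward hierarchical clustering on 1 - r.
    Returns (r matrix, row order, column order).
    """
    if len(ortholog_map) == 0:
        raise ValidationError("empty ortholog map")
    om = ortholog_map.iloc[:, :2].copy()
    om.columns = ["a", "b"]
    dup = om["a"].duplicated(keep=False) | om["b"].duplicated(keep=False)
    if dup.any():
        logger.warning("dropping %d non-one-to-one ortholog pairs", int(dup.sum()))
        om = om.loc[~dup]

    def top_hvgs(profiles: pd.DataFrame) -> set[str]:
        var = profiles.var(axis=1, ddof=1)
        order = np.argsort(-var.to_numpy(), kind="stable")
        return set(profiles.index[order[: min(hvg_n, len(var))]])

    hvg_a, hvg_b = top_hvgs(profiles_a), top_hvgs(profiles_b)
    om = om[
        om["a"].isin(hvg_a & set(profiles_a.index))
        & om["b"].isin(hvg_b & set(profiles_b.index))
    ]
    if len(om) < 20:
        raise ValidationError(
            f"only {len(om)} shared ortholog genes after HVG restriction (need >= 20)"
        )
    A = profiles_a.loc[om["a"]].to_numpy(float)
    B = profiles_b.loc[om["b"]].to_numpy(float)
    r = pd.DataFrame(
        np.corrcoef(A.T, B.T)[: A.shape[1], A.shape[1]:],
        index=profiles_a.columns,
        columns=profiles_b.columns,
    )

    def ward_order(mat: np.ndarray, names) -> list[str]:
        if mat.shape[0] < 3:
            return list(names)
        d = squareform(
            np.maximum(1.0 - np.corrcoef(mat), 0.0), checks=False
        )
        return [names[i] for i in leaves_list(ward(d))]

    row_order = ward_order(A.T, list(r.index))
    col_order = ward_order(B.T, list(r.columns))
    return r.loc[row_order, col_order], row_order, col_order
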