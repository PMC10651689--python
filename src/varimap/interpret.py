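"""Automated factor interpretation.

Three complementary screens assign meaning to rotated factors:

* **cluster matching** — Pearson correlation between each cluster's mean
  expression profile and each factor's loadings, restricted to the
  cluster's top differentially expressed genes (robust across top-10/
  20/30/50 DE gene choices);
* **covariate association** — a random-forest classifier predicts the
  covariate (strain) label of each cell from its factor scores; the
  per-factor mean decrease in Gini impurity ranks factors by how much
  covariate signal they carry;
* **technical screen** — correlation of factor scores with library size,
  expressed-gene count and mitochondrial fraction flags factors that
  merely track data quality.

Differential expression uses the two-sided Wilcoxon rank-sum test per
gene (exact when both groups have <= 10 cells and no ties, tie-corrected
normal approximation otherwise) with Benjamini-Hochberg correction, and
genes are ranked by the ``-log10(p) * logFC`` score (natural-log fold
change of means with a 1e-9 pseudocount).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .containers import NormalizedMatrix, ValidationError
from .factor import FactorModel

__all__ = [
    "ClusterProfile",
    "FactorMatch",
    "ImportanceReport",
    "cluster_mean_profiles",
    "de_wilcoxon",
    "rank_de_genes",
    "factor_cluster_correlation",
    "covariate_factor_importance",
    "technical_covariate_check",
    "LOGFC_EPS",
    "P_FLOOR",
]

logger = logging.getLogger("varimap")

LOGFC_EPS = 1e-9  # pseudocount on group means in the natural-log fold change
P_FLOOR = 1e-300  # floor before -log10 in the DE ranking score


@dataclass
class ClusterProfile:
    """Per-cluster mean expression, cluster sizes, optional top-DE lists."""

    means: pd.DataFrame  # genes x clusters
    sizes: pd.Series
    top_de: dict[str, list[str]] = field(default_factory=dict)
    small_clusters: list[str] = field(default_factory=list)


@dataclass
class FactorMatch:
    """Cluster-factor correlation screen.

    ``correlation`` is clusters x factors (Pearson r over the row
    cluster's top-DE genes); ``best_factor`` the arg-max-|r| factor per
    cluster; ``robustness`` maps top_n -> best-factor series.
    """

    correlation: pd.DataFrame
    best_factor: pd.Series
    robustness: dict[int, pd.Series] = field(default_factory=dict)


@dataclass
class ImportanceReport:
    """Random-forest covariate association of factors."""

    importance: pd.Series  # per-factor mean decrease in Gini impurity
    accuracy: float
    sensitivity: float
    specificity: float
    positive_class: str
    split_ratio: float
    seed: int

    def ranked_factors(self) -> list[str]:
        return list(self.importance.sort_values(ascending=False).index)


def cluster_mean_profiles(norm: NormalizedMatrix, labels) -> ClusterProfile:
    """Arithmetic mean of normalized expression per cluster.

    Clusters with fewer than 3 cells are flagged in ``small_clusters``.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=norm.cell_ids)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])
        raise ValidationError(f"unlabeled cells: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    clusters = sorted(map(str, labels.unique()))
    labels = labels.astype(str)
    means = {}
    sizes = {}
    for c in clusters:
        mask = (labels == c).to_numpy()
        means[c] = norm.values[:, mask].mean(axis=1)
        sizes[c] = int(mask.sum())
    small = [c for c, s in sizes.items() if s < 3]
    if small:
        logger.warning("clusters with < 3 cells: %s", small)
    return ClusterProfile(
        means=pd.DataFrame(means, index=norm.gene_ids),
        sizes=pd.Series(sizes),
        small_clusters=small,
    )


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for small tie-free groups, else normal approx."""
    if len(x) <= 10 and len(y) <= 10 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y):
        return float(scipy.stats.mannwhitneyu(x, y, method="exact").pvalue)
    return float(scipy.stats.mannwhitneyu(x, y, method="asymptotic").pvalue)


def _ranksum_vectorized(values: np.ndarray, in_mask: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p per gene (row): tie-corrected normal approximation.

    Shares one rank computation across genes; applies the continuity
    correction, matching :func:`scipy.stats.mannwhitneyu`'s asymptotic
    method. Constant genes get p = 1.
    """
    n_in = int(in_mask.sum())
    n_out = values.shape[1] - n_in
    N = n_in + n_out
    ranks = scipy.stats.rankdata(values, axis=1)
    r_in = ranks[:, in_mask].sum(axis=1)
    u = r_in - n_in * (n_in + 1) / 2.0
    mu = n_in * n_out / 2.0
    # tie correction: sum over tied groups of t^3 - t, per gene
    s = np.sort(values, axis=1)
    tie_sum = np.empty(values.shape[0])
    for g in range(values.shape[0]):
        _, counts = np.unique(s[g], return_counts=True)
        tie_sum[g] = np.sum(counts**3 - counts)
    sigma2 = n_in * n_out / 12.0 * ((N + 1) - tie_sum / (N * (N - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(u - mu) - 0.5) / np.where(sigma > 0, sigma, 1.0)
    p = np.where(sigma > 0, 2.0 * scipy.stats.norm.sf(np.maximum(z, 0.0)), 1.0)
    return np.minimum(p, 1.0)


def de_wilcoxon(norm: NormalizedMatrix, labels, cluster: str) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression of one cluster vs the rest.

    No fold-change or detection-fraction pre-filtering is applied: every
    gene is tested. Returns a DataFrame with columns ``gene, p, p_adj,
    logFC, pct_in, pct_out, cluster`` sorted by the input gene order.
    """
    labels = pd.Series(np.asarray(labels, dtype=object), index=norm.cell_ids).astype(str)
    in_mask = (labels == str(cluster)).to_numpy()
    if not in_mask.any():
        raise ValidationError(f"cluster {cluster!r} has no cells")
    if in_mask.all():
        raise ValidationError(f"cluster {cluster!r} contains every cell (no out-group)")
    Xin = norm.values[:, in_mask]
    Xout = norm.values[:, ~in_mask]
    n_in, n_out = Xin.shape[1], Xout.shape[1]

    if n_in <= 10 and n_out <= 10:
        pvals = np.array([_ranksum_p(Xin[g], Xout[g]) for g in range(norm.n_genes)])
    else:
        pvals = _ranksum_vectorized(norm.values, in_mask)

    mean_in = Xin.mean(axis=1)
    mean_out = Xout.mean(axis=1)
    logfc = np.log((mean_in + LOGFC_EPS) / (mean_out + LOGFC_EPS))
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": norm.gene_ids,
            "p": pvals,
            "p_adj": np.maximum(p_adj, pvals),
            "logFC": logfc,
            "pct_in": (Xin > 0).mean(axis=1),
            "pct_out": (Xout > 0).mean(axis=1),
            "cluster": str(cluster),
        }
    )


def rank_de_genes(results: pd.DataFrame) -> pd.DataFrame:
    """Order genes by the decreasing ``-log10(p) * logFC`` score.

    Accepts any table with ``gene``, ``p`` and ``logFC`` columns (so
    externally computed mixed-model DE output can be ranked the same
    way). p values are floored at 1e-300.
    """
    if len(results) == 0:
        raise ValidationError("empty DE results")
    out = results.copy()
    out["score"] = -np.log10(np.maximum(out["p"].to_numpy(float), P_FLOOR)) * out[
        "logFC"
    ].to_numpy(float)
    return out.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def factor_cluster_correlation(
    profiles: ClusterProfile,
    model: FactorModel,
    top_n: int = 10,
    robustness_ns: tuple[int, ...] = (10, 20, 30, 50),
) -> FactorMatch:
    """Match clusters to factors by correlation over top-DE genes.

    For each cluster, Pearson r between the cluster's mean expression and
    each factor's loadings, restricted to that cluster's top ``top_n`` DE
    genes; the best factor per cluster maximizes |r|. The same matching
    is repeated for each n in ``robustness_ns`` into the robustness table.
    """
    if top_n < 3:
        raise ValidationError("top_n must be >= 3")
    if not profiles.top_de:
        raise ValidationError("cluster profiles carry no top-DE gene lists")
    gene_pos = {g: i for i, g in enumerate(model.gene_ids)}
    fac_names = model.factor_names()

    def corr_at(n: int) -> pd.DataFrame:
        rows = {}
        for cluster, de_genes in profiles.top_de.items():
            genes = [g for g in de_genes[:n] if g in gene_pos]
            dropped = len(de_genes[:n]) - len(genes)
            if dropped:
                logger.warning(
                    "cluster %s: %d top-DE genes absent from loading universe", cluster, dropped
                )
            if len(genes) < 3:
                rows[cluster] = [np.nan] * model.n_factors
                continue
            idx = [gene_pos[g] for g in genes]
            prof = profiles.means.loc[genes, cluster].to_numpy(float)
            rows[cluster] = [
                _pearson(prof, model.loadings[idx, k]) for k in range(model.n_factors)
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=fac_names)

    corr = corr_at(top_n)
    best = corr.abs().idxmax(axis=1, skipna=True)
    robustness = {n: corr_at(n).abs().idxmax(axis=1, skipna=True) for n in robustness_ns}
    return FactorMatch(correlation=corr, best_factor=best, robustness=robustness)


def covariate_factor_importance(
    model: FactorModel,
    labels,
    split_ratio: float = 0.75,
    seed: int = 0,
    n_trees: int = 500,
) -> ImportanceReport:
    """Random-forest covariate association of factor scores.

    Trains a ``n_trees``-tree forest (sqrt(K) features per split) on a
    stratified train/test split (train fraction ``split_ratio``, the 3:1
    convention by default) to predict the covariate label from factor
    scores, and reports per-factor mean decrease in Gini impurity plus
    held-out accuracy, sensitivity and specificity (positive class =
    first label in sorted order).
    """
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValidationError("need at least two covariate classes")
    if not np.all(np.isfinite(model.scores)):
        raise ValidationError("factor scores contain non-finite values")
    if not (0 < split_ratio < 1):
        raise ValidationError("split_ratio must be in (0, 1)")

    try:
        Xtr, Xte, ytr, yte = train_test_split(
            model.scores, y, train_size=split_ratio, stratify=y, random_state=seed
        )
    except ValueError as exc:
        raise ValidationError(
            f"stratified split failed ({exc}); check class sizes or change the seed"
        ) from exc
    if set(ytr) != set(classes) or set(yte) != set(classes):
        raise ValidationError(
            "a covariate class is missing from the train or test split; "
            "use stratification or a different seed"
        )
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
    )
    rf.fit(Xtr, ytr)
    pred = rf.predict(Xte)
    pos = classes[0]
    tp = np.sum((pred == pos) & (yte == pos))
    fn = np.sum((pred != pos) & (yte == pos))
    tn = np.sum((pred != pos) & (yte != pos))
    fp = np.sum((pred == pos) & (yte != pos))
    importance = pd.Series(rf.feature_importances_, index=model.factor_names())
    return ImportanceReport(
        importance=importance,
        accuracy=float((pred == yte).mean()),
        sensitivity=float(tp / (tp + fn)) if tp + fn else float("nan"),
        specificity=float(tn / (tn + fp)) if tn + fp else float("nan"),
        positive_class=pos,
        split_ratio=split_ratio,
        seed=seed,
    )


def technical_covariate_check(
    model: FactorModel, meta: pd.DataFrame, flag_threshold: float = 0.5
) -> pd.DataFrame:
    """Correlate factor scores with technical covariates.

    Pearson r of every factor's scores against ``library_size``,
    ``n_genes_expressed`` and ``mito_fraction``; factors whose largest
    |r| exceeds ``flag_threshold`` are flagged technical. A constant
    covariate gets r = 0 with a note.
    """
    covs = ["library_size", "n_genes_expressed", "mito_fraction"]
    for c in covs:
        if c not in meta.columns:
            raise ValidationError(f"cell metadata lacks column {c!r}")
    meta = meta.loc[model.cell_ids]
    rows = {}
    for c in covs:
        v = meta[c].to_numpy(float)
        if np.std(v) == 0:
            logger.warning("technical covariate %s is constant; correlation set to 0", c)
            rows[c] = np.zeros(model.n_factors)
        else:
            rows[c] = np.array(
                [_pearson(v, model.scores[:, k]) for k in range(model.n_factors)]
            )
    table = pd.DataFrame(rows, index=model.factor_names())
    table["max_abs_r"] = table[covs].abs().max(axis=1)
    table["technical_flag"] = table["max_abs_r"] > flag_threshold
    return table
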