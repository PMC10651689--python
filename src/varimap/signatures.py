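"""Portable factor gene signatures and rank-based per-cell scoring.

A factor is turned into a signature by taking its top-n positively and
negatively loaded genes (n = 10 by default). Cells of an independent
dataset are then scored with a Mann-Whitney-U-derived rank statistic
(UCell-style): genes are ranked within each cell by decreasing
expression with average ties, ranks above ``r_max`` are capped, and the
score is ``1 - U' / (n_s * r_max)`` in [0, 1] — invariant to any
strictly increasing per-cell transform of expression, hence portable
across normalizations and platforms. The bipolar score combines the two
poles of a directional factor as ``(score_pos - score_neg + 1) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import NormalizedMatrix, ValidationError
from .factor import FactorModel, top_loaded_genes

__all__ = [
    "GeneSignature",
    "extract_signature",
    "rank_signature_score",
    "bipolar_score",
    "compare_groups",
    "write_gmt",
    "R_MAX_DEFAULT",
]

logger = logging.getLogger("varimap")

R_MAX_DEFAULT = 1500  # rank cap: genes ranked beyond this count as r_max + 1


@dataclass
class GeneSignature:
    """Two-pole gene signature derived from a factor's loadings."""

    name: str
    source_factor: str
    positive_genes: list[str]
    negative_genes: list[str]
    positive_loadings: list[float]
    negative_loadings: list[float]

    def __post_init__(self) -> None:
        if not self.positive_genes and not self.negative_genes:
            raise ValidationError("signature has no genes")
        if set(self.positive_genes) & set(self.negative_genes):
            raise ValidationError("signature poles overlap")


def extract_signature(model: FactorModel, factor: int, n: int = 10) -> GeneSignature:
    """Top-n positively and negatively loaded genes of an (oriented) factor."""
    pos = top_loaded_genes(model, factor, n, "positive")
    neg = top_loaded_genes(model, factor, n, "negative")
    name = model.factor_names()[factor]
    return GeneSignature(
        name=f"{name}_signature",
        source_factor=name,
        positive_genes=list(pos["gene"]),
        negative_genes=list(neg["gene"]),
        positive_loadings=[float(v) for v in pos["loading"]],
        negative_loadings=[float(v) for v in neg["loading"]],
    )


def rank_signature_score(
    norm: NormalizedMatrix, genes: list[str], r_max: int = R_MAX_DEFAULT
) -> pd.Series:
    """Per-cell rank-based signature score in [0, 1].

    Within each cell, all genes are ranked by decreasing expression with
    average ties; ranks above ``r_max`` are capped at ``r_max + 1``. With
    signature ranks summing minus the minimal possible sum,
    ``U' = sum(ranks) - n_s (n_s + 1) / 2``, the score is
    ``1 - U' / (n_s * r_max)`` clamped to [0, 1].
    """
    present = [g for g in genes if g in set(norm.gene_ids)]
    if not present:
        raise ValidationError("no signature gene present in the matrix")
    if r_max <= len(present):
        raise ValidationError("r_max must exceed the signature size")
    if len(present) < len(genes):
        logger.warning(
            "%d of %d signature genes absent; scoring over the %d present",
            len(genes) - len(present),
            len(genes),
            len(present),
        )
    ranks = scipy.stats.rankdata(-norm.values, axis=0, method="average")
    ranks = np.minimum(ranks, r_max + 1)
    pos = {g: i for i, g in enumerate(norm.gene_ids)}
    idx = [pos[g] for g in present]
    n_s = len(idx)
    u = ranks[idx, :].sum(axis=0) - n_s * (n_s + 1) / 2.0
    score = 1.0 - u / (n_s * r_max)
    return pd.Series(np.clip(score, 0.0, 1.0), index=norm.cell_ids)


def bipolar_score(
    norm: NormalizedMatrix, signature: GeneSignature, r_max: int = R_MAX_DEFAULT
) -> pd.Series:
    """Directional score combining both poles: ``(pos - neg + 1) / 2``.

    Cells high on the positive pole and low on the negative pole
    approach 1; identical pole scores give 0.5.
    """
    if not signature.positive_genes or not signature.negative_genes:
        raise ValidationError("bipolar score needs both signature poles")
    s_pos = rank_signature_score(norm, signature.positive_genes, r_max)
    s_neg = rank_signature_score(norm, signature.negative_genes, r_max)
    return (s_pos - s_neg + 1.0) / 2.0


def compare_groups(
    scores: pd.Series,
    groups,
    within: pd.Series | None = None,
    restrict_to=None,
) -> dict:
    """Two-group comparison of per-cell scores.

    Two-sided Wilcoxon rank-sum p (exact for tie-free groups of <= 10,
    normal approximation otherwise), rank-biserial effect size and group
    medians; optionally restricted to cells of one cluster (``within`` =
    cluster labels aligned to scores, ``restrict_to`` = cluster name).
    """
    groups = pd.Series(np.asarray(groups, dtype=object), index=scores.index).astype(str)
    mask = np.ones(len(scores), dtype=bool)
    if restrict_to is not None:
        if within is None:
            raise ValidationError("restrict_to given without cluster labels")
        within = pd.Series(np.asarray(within, dtype=object), index=scores.index).astype(str)
        mask = (within == str(restrict_to)).to_numpy()
    s = scores.to_numpy(float)[mask]
    g = groups.to_numpy()[mask]
    names = sorted(set(g))
    if len(names) != 2:
        raise ValidationError(f"expected exactly two groups, found {names}")
    a = s[g == names[0]]
    b = s[g == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 cells after restriction")
    if len(a) <= 10 and len(b) <= 10 and len(np.unique(s)) == len(s):
        res = scipy.stats.mannwhitneyu(a, b, method="exact")
    else:
        res = scipy.stats.mannwhitneyu(a, b, method="asymptotic")
    u = float(res.statistic)  # U for the first group
    rank_biserial = 2.0 * u / (len(a) * len(b)) - 1.0
    return {
        "groups": names,
        "n": [int(len(a)), int(len(b))],
        "p_value": float(res.pvalue),
        "rank_biserial": rank_biserial,
        "medians": [float(np.median(a)), float(np.median(b))],
        "restricted_to": None if restrict_to is None else str(restrict_to),
    }


def write_gmt(signature: GeneSignature, path) -> None:
    """Write the two poles as a GMT-style file (one line per pole)."""
    with open(path, "w") as fh:
        fh.write(
            "\t".join([f"{signature.name}_pos", signature.source_factor]
                      + signature.positive_genes) + "\n"
        )
        fh.write(
            "\t".join([f"{signature.name}_neg", signature.source_factor]
                      + signature.negative_genes) + "\n"
        )
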