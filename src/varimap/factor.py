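"""PCA and varimax rotation: the matrix-factorization engine.

The expression matrix (genes x cells, gene-centered and scaled) is
decomposed into a loading matrix (genes x K; the gene-factor
relationship) and a score matrix (cells x K; the cell-factor
relationship). A varimax rotation is then applied to the loadings:
an orthogonal K x K matrix R chosen to maximize the variance of the
squared loadings within each factor, which concentrates each factor on
few genes and makes it interpretable. Scores are rotated by the same R,
so the reconstruction ``scores @ loadings.T`` is invariant.

The rotation is the classical cyclic pairwise (Kaiser) algorithm: for
each pair of factors the planar angle with the largest criterion gain
has a closed form; sweeps repeat until the gain falls below ``tol``.
Optionally loadings rows are Kaiser-normalized to unit length while
optimizing. Factor signs are fixed deterministically so the gene with
the largest absolute loading in each factor loads positively.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg

from .containers import NormalizedMatrix, ValidationError

__all__ = [
    "FactorModel",
    "fit_pca",
    "varimax_criterion",
    "varimax_rotate",
    "orient_factors",
    "top_loaded_genes",
    "save_factor_model",
    "load_factor_model",
    "export_rnk",
]

logger = logging.getLogger("varimap")


@dataclass
class FactorModel:
    """A (possibly rotated) PCA factorization.

    ``loadings`` is genes x K, ``scores`` cells x K, ``rotation`` the
    orthogonal K x K matrix relating the current basis to the unrotated
    PCA basis (identity when unrotated). ``variance_explained`` holds the
    sample variance of each factor's scores.
    """

    loadings: np.ndarray
    scores: np.ndarray
    rotation: np.ndarray
    variance_explained: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    rotated: bool = False
    converged: bool = True
    criterion_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        self.scores = np.asarray(self.scores, float)
        self.rotation = np.asarray(self.rotation, float)
        self.variance_explained = np.asarray(self.variance_explained, float)
        K = self.n_factors
        if K < 1:
            raise ValidationError("factor model needs K >= 1")
        if self.scores.shape[1] != K or self.rotation.shape != (K, K):
            raise ValidationError("loadings/scores/rotation dimensions disagree")
        if not np.all(np.isfinite(self.loadings)):
            raise ValidationError("loadings contain non-finite values")
        if np.abs(self.rotation.T @ self.rotation - np.eye(K)).max() > 1e-8:
            raise ValidationError("rotation matrix is not orthogonal")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def factor_names(self) -> list[str]:
        prefix = "varimax" if self.rotated else "PC"
        return [f"{prefix}{k + 1}" for k in range(self.n_factors)]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.loadings, index=self.gene_ids, columns=self.factor_names())

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.cell_ids, columns=self.factor_names())


def fit_pca(scaled: NormalizedMatrix, K: int) -> FactorModel:
    """Top-K principal components of a gene-centered matrix.

    Loadings are the orthonormal right-singular structure over genes;
    scores are the cell projections (mean zero, with sample variance
    equal to the variance explained by the component). Deterministic:
    computed by symmetric eigendecomposition of the smaller Gram matrix,
    signs fixed by :func:`orient_factors`.
    """
    X = scaled.values  # genes x cells
    G, n = X.shape
    if not (1 <= K <= min(G, n)):
        raise ValidationError(f"K={K} must be in [1, min(genes, cells)={min(G, n)}]")
    gene_means = X.mean(axis=1)
    if np.abs(gene_means).max() > 1e-6:
        warnings.warn("fit_pca input does not look gene-centered", stacklevel=2)

    if G <= n:
        C = X @ X.T  # genes x genes
        evals, evecs = scipy.linalg.eigh(C, subset_by_index=(G - K, G - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        loadings = evecs
        scores = X.T @ loadings
    else:
        C = X.T @ X  # cells x cells
        evals, evecs = scipy.linalg.eigh(C, subset_by_index=(n - K, n - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        s = np.sqrt(np.maximum(evals, 0))
        scores = evecs * s[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = (X @ evecs) / np.where(s > 0, s, 1.0)[None, :]

    var_explained = np.maximum(evals, 0) / max(n - 1, 1)
    model = FactorModel(
        loadings=loadings,
        scores=scores,
        rotation=np.eye(K),
        variance_explained=var_explained,
        gene_ids=list(scaled.gene_ids),
        cell_ids=list(scaled.cell_ids),
        rotated=False,
    )
    return orient_factors(model)


def varimax_criterion(loadings: np.ndarray) -> float:
    """Sum over factors of the population variance of squared loadings."""
    L2 = np.asarray(loadings, float) ** 2
    return float(np.sum(L2.var(axis=0)))  # ddof=0: divisor = number of genes


def _pairwise_angle(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form optimal planar rotation angle for one factor pair."""
    G = x.shape[0]
    u = x * x - y * y
    v = 2.0 * x * y
    A = u.sum()
    B = v.sum()
    num = 2.0 * (u * v).sum() - 2.0 * A * B / G
    den = (u * u - v * v).sum() - (A * A - B * B) / G
    return 0.25 * np.arctan2(num, den)


def varimax_rotate(
    model: FactorModel,
    kaiser: bool = True,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> FactorModel:
    """Varimax-rotate a factor model (cyclic pairwise planar rotations).

    Returns a new model with loadings ``L @ R`` and scores ``S @ R`` for
    an orthogonal R; the varimax criterion of the (Kaiser-normalized, if
    ``kaiser``) loadings is non-decreasing across sweeps, recorded in
    ``criterion_trace``. K = 1 returns an identity rotation. Factors are
    reordered by decreasing rotated score variance and re-oriented.
    """
    K = model.n_factors
    if K == 1:
        out = replace(
            model,
            rotation=model.rotation.copy(),
            rotated=True,
            converged=True,
            criterion_trace=[varimax_criterion(model.loadings)],
        )
        return orient_factors(out)

    L0 = model.loadings
    if kaiser:
        h = np.linalg.norm(L0, axis=1)
        h = np.where(h > 0, h, 1.0)
        A = L0 / h[:, None]
    else:
        A = L0.copy()

    R = np.eye(K)
    trace = [varimax_criterion(A)]
    converged = False
    for _ in range(max_iter):
        for p in range(K - 1):
            for q in range(p + 1, K):
                phi = _pairwise_angle(A[:, p], A[:, q])
                if abs(phi) < 1e-12:
                    continue
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([[c, -s], [s, c]])
                A[:, [p, q]] = A[:, [p, q]] @ rot
                R[:, [p, q]] = R[:, [p, q]] @ rot
        trace.append(varimax_criterion(A))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"varimax did not converge in {max_iter} sweeps "
            f"(last gain {trace[-1] - trace[-2]:.3g})",
            stacklevel=2,
        )

    loadings = L0 @ R
    scores = model.scores @ R
    # order rotated factors by the variance they carry
    var = scores.var(axis=0, ddof=1) if scores.shape[0] > 1 else scores.var(axis=0)
    order = np.argsort(-var, kind="stable")
    out = FactorModel(
        loadings=loadings[:, order],
        scores=scores[:, order],
        rotation=(model.rotation @ R)[:, order],
        variance_explained=var[order],
        gene_ids=list(model.gene_ids),
        cell_ids=list(model.cell_ids),
        rotated=True,
        converged=converged,
        criterion_trace=trace,
    )
    return orient_factors(out)


def orient_factors(model: FactorModel) -> FactorModel:
    """Fix factor signs: the largest-|loading| gene loads positively.

    Scores (and the rotation bookkeeping) are flipped consistently, so
    the reconstruction is unchanged. Idempotent.
    """
    flips = np.ones(model.n_factors)
    for k in range(model.n_factors):
        col = model.loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            flips[k] = -1.0
    if np.all(flips == 1.0):
        return model
    return replace(
        model,
        loadings=model.loadings * flips[None, :],
        scores=model.scores * flips[None, :],
        rotation=model.rotation * flips[None, :],
        variance_explained=model.variance_explained.copy(),
    )


def top_loaded_genes(
    model: FactorModel, factor: int, n: int, pole: str = "positive"
) -> pd.DataFrame:
    """The n most positively (or negatively) loaded genes of a factor.

    Returns a DataFrame with columns ``gene`` and ``loading``, ordered by
    decreasing contribution to the requested pole. The absolute loading
    indicates each gene's contribution to the factor.
    """
    if not (0 <= factor < model.n_factors):
        raise ValidationError(f"factor index {factor} out of range")
    if pole not in ("positive", "negative"):
        raise ValidationError("pole must be 'positive' or 'negative'")
    col = model.loadings[:, factor]
    if n > len(col):
        warnings.warn(
            f"requested {n} genes but factor has {len(col)}; truncating", stacklevel=2
        )
        n = len(col)
    order = np.argsort(-col, kind="stable") if pole == "positive" else np.argsort(col, kind="stable")
    idx = order[:n]
    return pd.DataFrame(
        {"gene": [model.gene_ids[i] for i in idx], "loading": col[idx]}
    )


# ---------------------------------------------------------------------------
# serialization


def save_factor_model(model: FactorModel, directory: str | Path) -> None:
    """Write a tabular bundle: loadings.tsv, scores.tsv, rotation.tsv, meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.loadings_frame().to_csv(directory / "loadings.tsv", sep="\t")
    model.scores_frame().to_csv(directory / "scores.tsv", sep="\t")
    pd.DataFrame(model.rotation).to_csv(directory / "rotation.tsv", sep="\t", index=False)
    meta = {
        "rotated": model.rotated,
        "converged": model.converged,
        "variance_explained": model.variance_explained.tolist(),
        "criterion_trace": list(model.criterion_trace),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_factor_model(directory: str | Path) -> FactorModel:
    directory = Path(directory)
    loadings = pd.read_csv(directory / "loadings.tsv", sep="\t", index_col=0)
    scores = pd.read_csv(directory / "scores.tsv", sep="\t", index_col=0)
    rotation = pd.read_csv(directory / "rotation.tsv", sep="\t").to_numpy()
    meta = json.loads((directory / "meta.json").read_text())
    return FactorModel(
        loadings=loadings.to_numpy(),
        scores=scores.to_numpy(),
        rotation=rotation,
        variance_explained=np.asarray(meta["variance_explained"]),
        gene_ids=[str(g) for g in loadings.index],
        cell_ids=[str(c) for c in scores.index],
        rotated=bool(meta["rotated"]),
        converged=bool(meta["converged"]),
        criterion_trace=list(meta.get("criterion_trace", [])),
    )


def export_rnk(model: FactorModel, factor: int, path: str | Path) -> None:
    """Write a GSEA .rnk file (gene TAB loading, sorted decreasing)."""
    col = model.loadings[:, factor]
    order = np.argsort(-col, kind="stable")
    with open(path, "w") as fh:
        for i in order:
            fh.write(f"{model.gene_ids[i]}\t{col[i]:.6g}\n")
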