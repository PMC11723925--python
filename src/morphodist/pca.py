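"""Mixed-data principal component analysis and Mahalanobis-type distances.

Encoding follows the factor-analysis-of-mixed-data convention: continuous
variables are z-scored; ordinal variables enter as z-scored integer level
ranks; each nominal category becomes a centred indicator weighted by
1/sqrt(category frequency), so rare categories are not swamped and every
category remains an interpretable arrow in the correlation circle.  The PCs
are the eigenvectors of the covariance of this encoded matrix; distances are
Euclidean over variance-standardised PC scores, i.e. the Mahalanobis
distance in encoded space restricted to the retained components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .schema_io import FlakeTable, Schema

logger = logging.getLogger(__name__)

__all__ = [
    "PCModel",
    "encode_mixed",
    "mixed_pca",
    "variance_explained",
    "mahalanobis_distances",
    "correlation_circle",
]


@dataclass
class PCModel:
    """A fitted mixed-data PCA."""

    columns: list[str]        # encoded column names
    column_vars: list[str]    # parent schema variable per encoded column
    encoded: np.ndarray       # (n, p) centred encoded matrix
    loadings: np.ndarray      # (p, k) orthonormal eigenvectors
    eigenvalues: np.ndarray   # (k,) nonincreasing, nonnegative
    scores: np.ndarray        # (n, k) = encoded @ loadings

    @property
    def n(self) -> int:
        return self.encoded.shape[0]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def encode_mixed(table: FlakeTable, schema: Schema | None = None):
    """Numeric encoding of a complete mixed-scale table.

    Returns ``(Z, names, parents)``.  Zero-variance columns (constant
    variables, unobserved categories) are dropped with a log notice.
    """
    schema = schema or table.schema
    if table.data.isna().any().any():
        raise ValueError("encode_mixed requires a complete table (impute first)")
    blocks: list[np.ndarray] = []
    names: list[str] = []
    parents: list[str] = []
    n = table.n
    for var in schema.variables:
        s = table.data[var.name]
        if var.scale in ("continuous", "ordinal"):
            if var.scale == "continuous":
                x = s.to_numpy(dtype=float)
            else:
                x = s.cat.codes.to_numpy().astype(float)
            sd = x.std(ddof=1)
            if sd == 0:
                logger.info("encode_mixed: dropping constant column %s", var.name)
                continue
            blocks.append(((x - x.mean()) / sd)[:, None])
            names.append(var.name)
            parents.append(var.name)
        else:
            codes = s.cat.codes.to_numpy()
            for k, lev in enumerate(var.levels):  # type: ignore[arg-type]
                pk = float((codes == k).mean())
                if pk == 0.0 or pk == 1.0:
                    logger.info("encode_mixed: dropping degenerate category %s=%s", var.name, lev)
                    continue
                ind = (codes == k).astype(float)
                blocks.append(((ind - pk) / np.sqrt(pk))[:, None])
                lab = var.level_labels[k] if var.level_labels else lev
                names.append(f"{var.name}.{lab}")
                parents.append(var.name)
    if not blocks:
        raise ValueError("no usable columns after encoding")
    Z = np.hstack(blocks)
    return Z, names, parents


def mixed_pca(table: FlakeTable, schema: Schema | None = None) -> PCModel:
    """Eigen-decomposition of the encoded, centred mixed table."""
    if table.n < 2:
        raise ValueError("mixed_pca requires at least 2 records")
    Z, names, parents = encode_mixed(table, schema)
    n = Z.shape[0]
    S = Z.T @ Z / (n - 1)
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    # deterministic sign: largest-magnitude loading of each PC is positive
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    scores = Z @ V
    return PCModel(
        columns=names, column_vars=parents, encoded=Z,
        loadings=V, eigenvalues=w, scores=scores,
    )


def variance_explained(model: PCModel) -> np.ndarray:
    """Percent variance per PC (sums to 100)."""
    tot = model.eigenvalues.sum()
    if tot <= 0:
        raise ValueError("degenerate model: zero total variance")
    return 100.0 * model.eigenvalues / tot


def retained_components(model: PCModel, min_rel_eig: float = 1e-8,
                        n_components: int | None = None) -> np.ndarray:
    """Indices of PCs used for distances (all non-degenerate by default)."""
    if n_components is not None:
        return np.arange(min(n_components, model.n_components))
    lam = model.eigenvalues
    keep = lam > min_rel_eig * lam[0]
    dropped = int((~keep).sum())
    if dropped:
        logger.info("mahalanobis_distances: dropping %d near-zero component(s)", dropped)
    return np.flatnonzero(keep)


def standardized_scores(model: PCModel, min_rel_eig: float = 1e-8,
                        n_components: int | None = None) -> np.ndarray:
    """Scores whitened to unit variance on the retained components."""
    idx = retained_components(model, min_rel_eig, n_components)
    return model.scores[:, idx] / np.sqrt(model.eigenvalues[idx])


def mahalanobis_distances(model: PCModel, min_rel_eig: float = 1e-8,
                          n_components: int | None = None) -> np.ndarray:
    """Object-by-object Mahalanobis-type distance matrix from a fitted model."""
    U = standardized_scores(model, min_rel_eig, n_components)
    return squareform(pdist(U))


def correlation_circle(model: PCModel, pcs: tuple[int, int] = (0, 1)):
    """Correlation of each encoded column with two PCs (biplot arrows).

    Returns ``(arrows, names, parents)`` where ``arrows`` is (p, 2) with
    row norms <= 1.  Zero-variance score axes yield zero correlation.
    """
    import pandas as pd

    Z = model.encoded
    out = np.zeros((Z.shape[1], 2))
    for c, j in enumerate(pcs):
        s = model.scores[:, j]
        ssd = s.std(ddof=1)
        if ssd == 0:
            continue
        zc = Z - Z.mean(axis=0)
        out[:, c] = (zc * (s - s.mean())[:, None]).sum(axis=0) / (
            (Z.shape[0] - 1) * Z.std(axis=0, ddof=1) * ssd
        )
    return pd.DataFrame(
        {
            "column": model.columns,
            "variable": model.column_vars,
            "pc1_corr": out[:, 0],
            "pc2_corr": out[:, 1],
        }
    )
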