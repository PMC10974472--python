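"""Standardization and principal component analysis of the feature table.

The 11 GI variables mix seconds, metres, metres per second and newtons, so
the analysis operates on z-scored columns (correlation-matrix PCA).  The
eigendecomposition is obtained from the SVD of the centred standardized
matrix, which is stable also when there are fewer participants than
variables; the loadings carry a deterministic sign convention (the
largest-magnitude coefficient of each component is positive) so results are
reproducible across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import FEATURES


def feature_matrix(table: pd.DataFrame,
                   columns: tuple[str, ...] = FEATURES) -> np.ndarray:
    """Extract the (n, p) numeric feature block, validating the registry."""
    missing = [c for c in columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature table is missing columns {missing}")
    X = table.loc[:, list(columns)].to_numpy(float)
    if np.isnan(X).any():
        bad = [columns[j] for j in np.unique(np.argwhere(np.isnan(X))[:, 1])]
        raise ValueError(f"missing values in columns {bad}")
    return X


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns: returns ``(Z, column_means, column_sds)``.

    Sample SDs use ``ddof=1``.  Zero-variance columns are rejected by name
    (index if no registry applies).
    """
    X = np.asarray(X, float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [FEATURES[j] if j < len(FEATURES) else str(j) for j in zero]
        raise ValueError(f"zero-variance column(s): {names}")
    return (X - mu) / sd, mu, sd


@dataclass
class PCAModel:
    """Fitted correlation-matrix PCA.

    ``loadings`` is the full p x p orthonormal matrix (columns are the
    components, ordered by decreasing eigenvalue); ``eigenvalues`` are the
    variances of the scores along each component; ``explained_fraction``
    sums to one.
    """

    column_means: np.ndarray
    column_sds: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_fraction: np.ndarray
    feature_names: tuple[str, ...] = FEATURES

    def n_components_for(self, var_threshold: float) -> int:
        """Smallest k whose cumulative explained fraction reaches the
        threshold."""
        cum = np.cumsum(self.explained_fraction)
        return int(np.searchsorted(cum, var_threshold - 1e-12) + 1)

    # serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": list(self.feature_names),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "explained_fraction": self.explained_fraction.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            column_means=np.array(doc["column_means"]),
            column_sds=np.array(doc["column_sds"]),
            loadings=np.array(doc["loadings"]),
            eigenvalues=np.array(doc["eigenvalues"]),
            explained_fraction=np.array(doc["explained_fraction"]),
            feature_names=tuple(doc["feature_names"]),
        )


def fit_pca(table: pd.DataFrame | np.ndarray,
            feature_names: tuple[str, ...] = FEATURES) -> PCAModel:
    """Fit correlation-matrix PCA on a feature table (or raw matrix).

    The components are the right singular vectors of the centred z-scored
    matrix; eigenvalues are ``s^2 / (n - 1)`` (the variances of the scores),
    equal to the eigenvalues of the sample correlation matrix.
    """
    if isinstance(table, pd.DataFrame):
        X = feature_matrix(table, feature_names)
    else:
        X = np.asarray(table, float)
        feature_names = tuple(
            feature_names[: X.shape[1]]
            if X.shape[1] == len(feature_names)
            else tuple(f"x{j}" for j in range(X.shape[1]))
        )
    n, p = X.shape
    if n < 2:
        raise ValueError(f"need at least 2 rows, got {n}")
    Z, mu, sd = standardize(X)
    # Z is centred by construction; SVD gives the eigenvectors of Z'Z/(n-1)
    _, s, Vt = np.linalg.svd(Z, full_matrices=True)
    eigvals = np.zeros(p)
    k = min(n, p)
    eigvals[:k] = s[:k] ** 2 / (n - 1)
    loadings = Vt.T
    # deterministic sign: largest-magnitude coefficient of each PC positive
    for j in range(p):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
    return PCAModel(
        column_means=mu,
        column_sds=sd,
        loadings=loadings,
        eigenvalues=eigvals,
        explained_fraction=eigvals / eigvals.sum(),
        feature_names=feature_names,
    )


def project(model: PCAModel, table: pd.DataFrame | np.ndarray,
            k: int | None = None) -> np.ndarray:
    """Score a table in the model's PC basis: ``Z @ loadings[:, :k]``.

    The table is standardized with the *model's* means and SDs, so new
    observations are scored consistently with the training table.
    """
    p = model.loadings.shape[0]
    if k is None:
        k = p
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    if isinstance(table, pd.DataFrame):
        X = feature_matrix(table, model.feature_names)
    else:
        X = np.asarray(table, float)
        if X.shape[1] != p:
            raise ValueError(
                f"table has {X.shape[1]} columns, model expects {p} "
                f"({list(model.feature_names)})")
    Z = (X - model.column_means) / model.column_sds
    return Z @ model.loadings[:, :k]
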