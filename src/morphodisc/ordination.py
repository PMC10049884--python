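"""Principal component analysis with cumulative-variance truncation.

PCA is run independently for every size treatment of every measurement
scheme. The eigendecomposition is of the sample covariance (n-1 denominator)
of the centred — never correlation-standardized — feature table; an economy
SVD is used internally, which is mathematically identical and handles the
p >> n landmark tables. New specimens (the unidentified ones) are projected
into a fitted space without refitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureTable

__all__ = ["PCAModel", "pca", "retain_for_threshold", "project"]

_EIGVAL_TOL = 1e-12  # relative to the largest eigenvalue


@dataclass
class PCAModel:
    mean: np.ndarray  # (m,)
    eigenvalues: np.ndarray  # (K,), descending
    loadings: np.ndarray  # (m, K), orthonormal columns
    scores: np.ndarray  # (n, K)
    feature_names: list[str]
    source: str
    treatment: str

    @property
    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def n_retained_95(self) -> int:
        return retain_for_threshold(self, 0.95)


def pca(table: FeatureTable) -> PCAModel:
    """Principal components of a feature table.

    Components with eigenvalues below ``1e-12`` of the leading eigenvalue are
    discarded as numerically null. Sign convention: the largest-magnitude
    loading of each component is positive.
    """
    if table.n_specimens < 3:
        raise ValueError("PCA needs at least 3 specimens")
    if table.n_features < 2:
        raise ValueError("PCA needs at least 2 features")
    mean = table.values.mean(axis=0)
    centred = table.values - mean
    # economy SVD: centred = U S Vt, eigenvalues of cov are S^2/(n-1)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    eigenvalues = s**2 / (table.n_specimens - 1)
    if eigenvalues[0] <= 0:
        raise ValueError("feature table has zero total variance")
    keep = eigenvalues > _EIGVAL_TOL * eigenvalues[0]
    eigenvalues = eigenvalues[keep]
    loadings = vt[keep].T
    # deterministic signs: largest |loading| of each PC made positive
    for k in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, k])))
        if loadings[j, k] < 0:
            loadings[:, k] = -loadings[:, k]
    scores = centred @ loadings
    return PCAModel(
        mean=mean,
        eigenvalues=eigenvalues,
        loadings=loadings,
        scores=scores,
        feature_names=list(table.feature_names),
        source=table.source,
        treatment=table.treatment,
    )


def retain_for_threshold(model: PCAModel, threshold: float) -> int:
    """Smallest k whose cumulative variance fraction reaches ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cumulative = np.cumsum(model.variance_fractions)
    return int(np.searchsorted(cumulative, threshold - 1e-12) + 1)


def project(model: PCAModel, new_table: FeatureTable | np.ndarray) -> np.ndarray:
    """Project new specimens into an existing PC space (no refitting)."""
    if isinstance(new_table, FeatureTable):
        if new_table.feature_names != model.feature_names:
            raise ValueError(
                f"feature mismatch: model has {len(model.feature_names)} features "
                f"({model.source}/{model.treatment}), table has {new_table.n_features}"
            )
        values = new_table.values
    else:
        values = np.atleast_2d(np.asarray(new_table, dtype=float))
        if values.shape[1] != model.mean.shape[0]:
            raise ValueError("feature mismatch: wrong number of columns")
    return (values - model.mean) @ model.loadings
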