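"""Feature tables: linear distances, log-shape ratios, flattened shape coordinates.

A :class:`FeatureTable` is the common currency of the pipeline — an
``n_specimens x n_features`` matrix tagged with its size treatment:

``raw``
    Linear distances (caliper analog) or partial-Procrustes coordinates
    (form = shape plus size).
``isometry_free``
    Mosimann log-shape ratios ``log10(x / geometric mean)`` for linear data,
    or full-Procrustes (unit centroid size) coordinates for landmark data.
``allometry_free``
    Residuals of the isometry-free variables after regression on log size
    (see :mod:`morphodisc.allometry`).

The per-specimen size proxy travels with the table: the geometric mean (GM)
of the measurements for linear protocols, centroid size (CS) for landmark
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import LandmarkDataset, MeasurementProtocol
from .procrustes import AlignedDataset

__all__ = [
    "FeatureTable",
    "extract_distances",
    "geometric_mean",
    "log_shape_ratios",
    "gmm_feature_table",
]

TREATMENTS = ("raw", "isometry_free", "allometry_free")

GMM_SOURCE = "GMM"


@dataclass
class FeatureTable:
    values: np.ndarray
    feature_names: list[str]
    treatment: str
    size_vector: np.ndarray
    source: str
    specimen_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_vector = np.asarray(self.size_vector, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite entries")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.size_vector.shape != (self.values.shape[0],):
            raise ValueError("size_vector must have one entry per specimen")
        if np.any(self.size_vector <= 0):
            raise ValueError("size_vector entries must be positive")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one feature name required per column")
        if not self.specimen_ids:
            self.specimen_ids = [f"spec{i}" for i in range(self.values.shape[0])]
        if not self.groups:
            self.groups = ["unknown"] * self.values.shape[0]

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.specimen_ids, columns=self.feature_names)
        df.insert(0, "group", self.groups)
        df.insert(1, "size", self.size_vector)
        df.to_csv(path, index_label="specimen", float_format="%.12g")


def extract_distances(
    dataset: LandmarkDataset, protocol: MeasurementProtocol
) -> FeatureTable:
    """Extract a protocol's linear distances from landmark coordinates.

    Distances are Euclidean point-to-point lengths measured on the original
    (unaligned) coordinates — rigid-motion invariance of distances makes
    alignment irrelevant here. Where a measurement declares a mirror pair,
    the left and right distances are averaged. The table's size vector is the
    per-specimen geometric mean of all measurements.
    """
    protocol.validate_for(dataset.n_landmarks)
    coords = dataset.coords
    cols = []
    for m in protocol.measurements:
        d = np.linalg.norm(coords[:, m.a] - coords[:, m.b], axis=1)
        if m.mirror is not None:
            d2 = np.linalg.norm(coords[:, m.mirror[0]] - coords[:, m.mirror[1]], axis=1)
            d = 0.5 * (d + d2)
        if np.any(d == 0):
            warnings.warn(
                f"measurement {m.label!r}: zero distance (coincident landmarks) "
                "for at least one specimen; value kept",
                stacklevel=2,
            )
        cols.append(d)
    values = np.column_stack(cols)
    return FeatureTable(
        values=values,
        feature_names=protocol.labels,
        treatment="raw",
        size_vector=geometric_mean(values),
        source=protocol.name,
        specimen_ids=list(dataset.specimen_ids),
        groups=list(dataset.groups),
    )


def geometric_mean(values: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean, computed in log space for stability."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if np.any(values <= 0):
        i, j = np.argwhere(values <= 0)[0]
        raise ValueError(f"nonpositive entry at row {i}, feature column {j}")
    return np.exp(np.mean(np.log(values), axis=1))


def log_shape_ratios(table: FeatureTable) -> FeatureTable:
    """Mosimann log-shape ratios: ``log10(measurement / geometric mean)``.

    Removes isometric size from a raw linear table; every row of the result
    sums to zero and the result is invariant to per-specimen uniform scaling.
    The geometric mean itself is retained as the size vector.
    """
    if table.treatment != "raw":
        raise ValueError("log-shape ratios are computed from a raw table")
    gm = geometric_mean(table.values)
    values = np.log10(table.values / gm[:, None])
    return replace(table, values=values, treatment="isometry_free", size_vector=gm)


def gmm_feature_table(aligned: AlignedDataset) -> FeatureTable:
    """Flatten an aligned landmark sample into a feature table.

    Partial-superimposition coordinates (``scaled=False``) give the raw GMM
    table (form: shape plus size); full-superimposition coordinates give the
    isometry-free table. Centroid size is the size vector in both cases.
    """
    p = aligned.consensus.shape[0]
    names = [f"L{j:03d}_{ax}" for j in range(p) for ax in "xyz"]
    return FeatureTable(
        values=aligned.flat(),
        feature_names=names,
        treatment="isometry_free" if aligned.scaled else "raw",
        size_vector=aligned.centroid_sizes,
        source=GMM_SOURCE,
        specimen_ids=list(aligned.specimen_ids),
        groups=list(aligned.groups),
    )
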