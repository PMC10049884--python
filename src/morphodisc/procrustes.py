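"""Ordinary and generalized Procrustes superimposition.

Two variants are exposed through ``gpa(..., scale=...)``:

* ``scale=True`` — full superimposition: every configuration is centred,
  rescaled to unit centroid size, then rotated to the consensus. The aligned
  coordinates are "isometry-free" shape variables.
* ``scale=False`` — partial superimposition: translation and rotation only,
  so the aligned coordinates retain size ("form", here called raw).

Scaling is fixed unit-size pre-scaling: no scale factor is re-optimised
inside the rotation step, which is the dominant convention in the geometric
morphometrics ecosystem. Reflections are never allowed (crania have fixed
chirality). The aligned sample is finally rotated into the principal axes of
the consensus with a deterministic sign convention, which makes the output
invariant to specimen order and to arbitrary rigid motion of the input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import LandmarkDataset

__all__ = ["AlignedDataset", "centroid_size", "opa_align", "gpa", "align_new_to_consensus"]


class DegenerateConfigurationError(ValueError):
    pass


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the centroid.

    Rotation- and translation-invariant; scales linearly under uniform
    scaling. A configuration of identical points has centroid size 0.
    """
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centred**2)))


def _centroid_sizes(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=1, keepdims=True)
    return np.sqrt(np.sum(centred**2, axis=(1, 2)))


def opa_align(
    mobile: np.ndarray,
    target: np.ndarray,
    allow_scale: bool = False,
    label: str = "configuration",
) -> np.ndarray:
    """Ordinary Procrustes alignment of ``mobile`` onto ``target``.

    Finds the translation + proper rotation (+ scale if ``allow_scale``)
    minimising the summed squared coordinate differences. The rotation is
    restricted to determinant +1 by sign-correcting the smallest singular
    value, so reflections are never matched.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("mobile and target must have the same shape")
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    if np.linalg.matrix_rank(mc) < 2:
        raise DegenerateConfigurationError(
            f"{label}: rank-deficient (collinear or coincident) landmark configuration"
        )
    u, s, vt = np.linalg.svd(mc.T @ tc)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(3)
    flip[-1] = d
    rot = (u * flip) @ vt
    aligned = mc @ rot
    if allow_scale:
        # optimal scale for fixed rotation: <aligned, tc> / ||mc||^2
        beta = float(np.sum(aligned * tc) / np.sum(mc**2))
        aligned = beta * aligned
    return aligned + target.mean(axis=0)


@dataclass
class AlignedDataset:
    """Result of a generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, p, 3)
    centroid_sizes: np.ndarray  # from the original, pre-scaling configurations
    consensus: np.ndarray  # (p, 3)
    scaled: bool
    procrustes_ss: float
    n_iterations: int
    converged: bool
    specimen_ids: list[str]
    groups: list[str]
    ss_history: list[float] | None = None  # per-iteration SS against the mean

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to an (n, 3p) matrix."""
        return self.aligned.reshape(self.n_specimens, -1)


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation taking ``consensus`` into principal-axes orientation.

    Axes are ordered by decreasing variance of the consensus landmarks. Signs
    of the first two axes are chosen so the landmark loadings along each have
    positive skewness (tie-break: first loading with magnitude > 1e-12 made
    positive); the third axis is their cross product, which keeps the map a
    proper rotation.
    """
    centred = consensus - consensus.mean(axis=0)
    cov = centred.T @ centred
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    axes = eigvec[:, order]
    for k in range(2):
        loadings = centred @ axes[:, k]
        skew = np.mean(loadings**3)
        if abs(skew) > 1e-12:
            if skew < 0:
                axes[:, k] = -axes[:, k]
        else:
            nz = loadings[np.abs(loadings) > 1e-12]
            if nz.size and nz[0] < 0:
                axes[:, k] = -axes[:, k]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return axes


def _procrustes_ss(aligned: np.ndarray, consensus: np.ndarray) -> float:
    return float(np.sum((aligned - consensus) ** 2))


def gpa(
    dataset: LandmarkDataset,
    scale: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of all configurations.

    Iteratively aligns every (centred, and unit-sized if ``scale``)
    configuration to the running consensus until the relative decrease of the
    Procrustes sum of squares falls below ``tol``. Centroid sizes are recorded
    from the original configurations. The total SS is non-increasing across
    iterations by construction.
    """
    if dataset.n_specimens < 2:
        raise ValueError("GPA needs at least two specimens")
    coords = dataset.coords.astype(float)
    cs = _centroid_sizes(coords)
    if np.any(cs <= 0):
        bad = dataset.specimen_ids[int(np.argmax(cs <= 0))]
        raise DegenerateConfigurationError(f"specimen {bad!r}: zero centroid size")
    working = coords - coords.mean(axis=1, keepdims=True)
    if scale:
        working = working / cs[:, None, None]

    consensus = working[0].copy()
    if scale:
        consensus = consensus / centroid_size(consensus)
    # convergence is monitored on the SS against the (un-normalized) mean,
    # which is non-increasing from the first full pass onwards: the rotation
    # step can only improve the fit to the previous mean (the consensus is a
    # positive multiple of it) and the new mean minimizes the SS
    prev_ss = np.inf
    ss_history: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        for i in range(working.shape[0]):
            working[i] = opa_align(
                working[i], consensus, allow_scale=False, label=dataset.specimen_ids[i]
            )
        mean_shape = working.mean(axis=0)
        consensus = mean_shape
        if scale:
            consensus = mean_shape / centroid_size(mean_shape)
        ss = _procrustes_ss(working, mean_shape)
        if ss > prev_ss + 1e-9 * (1.0 + prev_ss):  # pragma: no cover
            raise RuntimeError("Procrustes SS increased during GPA iteration")
        ss_history.append(ss)
        if prev_ss - ss <= tol * ss + 1e-24:
            converged = True
            break
        prev_ss = ss
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (SS={ss:.3e})", stacklevel=2
        )

    rot = _principal_axis_rotation(consensus)
    consensus = (consensus - consensus.mean(axis=0)) @ rot
    working = working @ rot
    # SS is reported against the mean shape (the quantity the iteration
    # minimizes); the stored consensus is its unit-size version when scaled
    return AlignedDataset(
        aligned=working,
        centroid_sizes=cs,
        consensus=consensus,
        scaled=scale,
        procrustes_ss=_procrustes_ss(working, working.mean(axis=0)),
        n_iterations=iteration,
        converged=converged,
        specimen_ids=list(dataset.specimen_ids),
        groups=list(dataset.groups),
        ss_history=ss_history,
    )


def align_new_to_consensus(
    dataset: LandmarkDataset, reference: AlignedDataset
) -> AlignedDataset:
    """Superimpose new specimens onto an existing consensus without refitting.

    Each configuration is centred (and unit-scaled if the reference was
    scaled) and rotated onto the frozen consensus — the training shape space
    is not re-estimated, as required when projecting unidentified specimens
    into a trained ordination.
    """
    coords = dataset.coords.astype(float)
    cs = _centroid_sizes(coords)
    working = coords - coords.mean(axis=1, keepdims=True)
    if reference.scaled:
        working = working / cs[:, None, None]
    for i in range(working.shape[0]):
        working[i] = opa_align(
            working[i], reference.consensus, allow_scale=False,
            label=dataset.specimen_ids[i],
        )
    return AlignedDataset(
        aligned=working,
        centroid_sizes=cs,
        consensus=reference.consensus.copy(),
        scaled=reference.scaled,
        procrustes_ss=_procrustes_ss(working, reference.consensus),
        n_iterations=0,
        converged=True,
        specimen_ids=list(dataset.specimen_ids),
        groups=list(dataset.groups),
    )
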