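"""Multivariate allometric regression with permutation-tested Goodall's F.

Allometry — shape change disproportionate to size — is quantified as the
multivariate ordinary-least-squares regression of the isometry-free shape
variables on the natural logarithm of the size proxy (centroid size for
landmark data, geometric mean for linear data). Effect size is

    R^2 = SS_model / SS_total

with sums of squares pooled over all shape variables, and significance uses
Goodall's F,

    F = (SS_model / 1) / (SS_residual / (n - 2)),

assessed by residual randomization: with an intercept-only reduced model,
randomizing reduced-model residuals is exactly a row permutation of the
centred response against the covariate, which is how it is implemented. The
permutation p-value uses the add-one convention p = (1 + #{F* >= F}) /
(1 + n_perm), so it is never exactly zero and its floor at 1000 permutations
is 1/1001 ~ 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .features import FeatureTable

__all__ = ["AllometryFit", "fit_allometry", "allometry_free", "permutation_null_check"]


@dataclass
class AllometryFit:
    """Multivariate regression of shape variables on log size."""

    slopes: np.ndarray  # (m,)
    intercepts: np.ndarray  # (m,)
    r_squared: float
    f_statistic: float
    p_value: float
    n_permutations: int
    residuals: np.ndarray  # (n, m)
    log_size: np.ndarray  # (n,)
    seed: int
    table: FeatureTable

    @property
    def n_specimens(self) -> int:
        return self.residuals.shape[0]

    def summary_row(self) -> dict[str, float | int | str]:
        return {
            "source": self.table.source,
            "R2": self.r_squared,
            "F": self.f_statistic,
            "p": self.p_value,
            "n": self.n_specimens,
            "n_perm": self.n_permutations,
            "seed": self.seed,
        }


def _sums_of_squares(y_centred: np.ndarray, x_centred: np.ndarray, sxx: float):
    """Pooled SS_model for a single centred covariate, per feature then summed."""
    sxy = x_centred @ y_centred  # (m,)
    return float(np.sum(sxy**2) / sxx)


def fit_allometry(table: FeatureTable, n_perm: int = 1000, seed: int = 0) -> AllometryFit:
    """Regress a shape table on the natural log of its size vector.

    ``table`` must be isometry-free (Procrustes shape coordinates or
    log-shape ratios); the permutation test is reproducible from ``seed``.
    """
    if table.treatment != "isometry_free":
        raise ValueError(
            f"allometry is fitted on an isometry-free table, got {table.treatment!r}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = table.n_specimens
    if n < 3:
        raise ValueError("allometric regression needs at least 3 specimens")
    x = np.log(table.size_vector)
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 1e-300 * n:
        raise ValueError("size vector is constant: no allometry estimable")

    y = table.values
    ybar = y.mean(axis=0)
    yc = y - ybar
    ss_total = float(np.sum(yc**2))
    if ss_total == 0:
        raise ValueError("shape table has zero total variance")

    slopes = (xc @ yc) / sxx
    intercepts = ybar - slopes * x.mean()
    fitted = np.outer(xc, slopes)
    residuals = yc - fitted
    ss_model = _sums_of_squares(yc, xc, sxx)
    ss_residual = max(ss_total - ss_model, 0.0)
    r_squared = ss_model / ss_total
    df_r = n - 2
    # a perfect fit has zero residual SS: F is infinite by convention
    f_obs = np.inf if ss_residual == 0 else (ss_model / 1.0) / (ss_residual / df_r)

    # RRPP with intercept-only reduced model == row permutation; permuting the
    # covariate against fixed rows is the same exchange, vectorized here.
    rng = np.random.default_rng(seed)
    perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    xp = xc[perm_idx]  # (n_perm, n)
    sxy_p = xp @ yc  # (n_perm, m)
    ss_model_p = np.sum(sxy_p**2, axis=1) / sxx
    ss_resid_p = ss_total - ss_model_p
    f_perm = ss_model_p / (ss_resid_p / df_r)
    p_value = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)

    return AllometryFit(
        slopes=slopes,
        intercepts=intercepts,
        r_squared=r_squared,
        f_statistic=f_obs,
        p_value=p_value,
        n_permutations=n_perm,
        residuals=residuals,
        log_size=x,
        seed=seed,
        table=table,
    )


def allometry_free(fit: AllometryFit, add_consensus: bool = True) -> FeatureTable:
    """Allometry-free shape table: the residuals of the allometric regression.

    With ``add_consensus`` the per-feature means are added back so the values
    stay interpretable as shapes near the consensus; this shifts columns by
    constants and changes nothing downstream (PCA centres them again).
    """
    values = fit.residuals
    if add_consensus:
        values = values + fit.table.values.mean(axis=0)
    return replace(fit.table, values=values, treatment="allometry_free")


def permutation_null_check(
    table: FeatureTable,
    n_perm: int = 199,
    n_reps: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Type-I-error calibration of the permutation test on null data.

    Each replicate destroys any size-shape association by independently
    permuting the size covariate (an exact null when the table was generated
    with zero allometry), refits, and records the permutation p-value. Returns
    the rejection rate at ``alpha`` together with the 99% binomial band it
    should fall in for a well-calibrated test.
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_reps)
    for r in range(n_reps):
        shuffled = replace(
            table, size_vector=rng.permutation(table.size_vector)
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        pvals[r] = fit_allometry(shuffled, n_perm=n_perm, seed=sub_seed).p_value
    rejections = int(np.count_nonzero(pvals <= alpha))
    rate = rejections / n_reps
    k_lo, k_hi = stats.binom.interval(0.99, n_reps, alpha)
    lo, hi = k_lo / n_reps, k_hi / n_reps
    return {
        "n_reps": n_reps,
        "n_perm": n_perm,
        "alpha": alpha,
        "rejection_rate": rate,
        "band_99": (lo, hi),
        "within_band": lo <= rate <= hi,
        "p_values": pvals,
        "seed": seed,
    }
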