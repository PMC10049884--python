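"""Equal-prior LDA, leave-one-out posteriors and membership-based performance.

The classifier is the classical Gaussian linear discriminant: class means
with a pooled within-class covariance (divisor n - K, the convention of the
R MASS/klaR toolchain this mirrors), posteriors from Bayes' rule,

    m_k(x) ∝ π_k · exp(-1/2 (x - μ_k)' Σ⁻¹ (x - μ_k)).

Honest memberships come from leave-one-out cross validation: the LDA is
refit n times with one specimen held out, while the PC feature space stays
fixed (computed once on the full sample — the standard practice this
replicates; the resulting mild information leakage is deliberate and
documented).

Performance is summarized with membership-based measures in the style of
Garczarek & Weihs' unified classification performance measures, computed
from the n x K posterior-membership matrix ``m`` with true classes ``t`` and
assigned classes ``a = argmax``:

* correctness rate   CR = mean(a_i == t_i)
* accuracy           AC = 1 - K/(K-1) · mean ||m_i - e_{t_i}||²
* ability to separate AS = 1 - K/(K-1) · mean ||m_i - e_{a_i}||²
* confidence         CF = mean m_i[a_i]
* per-true-class confidence: mean of m_i[a_i] within each true class.

The K/(K-1) normalization makes a uniform-membership classifier score 0 and
a perfect one score 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LDAModel",
    "ClassificationReport",
    "fit_lda",
    "posterior_memberships",
    "loocv_memberships",
    "ucpm",
    "classify_unknowns",
]


@dataclass
class LDAModel:
    classes: list[str]
    priors: np.ndarray  # (K,), sums to 1
    means: np.ndarray  # (K, d)
    pooled_cov: np.ndarray  # (d, d)
    pooled_cov_inv: np.ndarray
    scalings: np.ndarray  # (d, n_axes) discriminant axes for plotting
    ridge_applied: bool

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class ClassificationReport:
    memberships: np.ndarray  # (n, K)
    classes: list[str]
    true_labels: list[str]
    assigned_labels: list[str]
    correctness_rate: float
    accuracy: float
    ability_to_separate: float
    confidence: float
    confidence_per_class: dict[str, float]
    confusion: np.ndarray  # (K, K): rows true, columns assigned

    def as_dict(self) -> dict[str, float]:
        out = {
            "CR": self.correctness_rate,
            "AC": self.accuracy,
            "AS": self.ability_to_separate,
            "CF": self.confidence,
        }
        for cls, v in self.confidence_per_class.items():
            out[f"CF_{cls}"] = v
        return out


def fit_lda(
    scores: np.ndarray,
    labels: list[str] | np.ndarray,
    priors: dict[str, float] | None = None,
) -> LDAModel:
    """Fit an LDA with specified (default equal) priors.

    Class order follows first appearance in ``labels``. A near-singular
    pooled covariance triggers a loudly-warned ridge of ``1e-8 · trace/d``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = [str(l) for l in labels]
    if scores.shape[0] != len(labels):
        raise ValueError("one label required per row of scores")
    classes = list(dict.fromkeys(labels))
    k, (n, d) = len(classes), scores.shape
    if k < 2:
        raise ValueError("LDA needs at least two classes")
    if n - k < d:
        warnings.warn(
            f"only {n - k} within-class degrees of freedom for {d} dimensions; "
            "pooled covariance estimate will be poor",
            stacklevel=2,
        )
    if priors is None:
        prior_vec = np.full(k, 1.0 / k)
    else:
        prior_vec = np.array([priors[c] for c in classes], dtype=float)
        if not np.isclose(prior_vec.sum(), 1.0):
            raise ValueError("priors must sum to 1")

    means = np.empty((k, d))
    pooled = np.zeros((d, d))
    label_arr = np.array(labels)
    for i, cls in enumerate(classes):
        x = scores[label_arr == cls]
        if x.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        means[i] = x.mean(axis=0)
        resid = x - means[i]
        pooled += resid.T @ resid
    pooled /= n - k

    ridge_applied = False
    try:
        cond = np.linalg.cond(pooled)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-8 * np.trace(pooled) / d
        pooled = pooled + ridge * np.eye(d)
        ridge_applied = True
        warnings.warn(
            f"singular pooled covariance: ridge {ridge:.3e} added", stacklevel=2
        )
    pooled_inv = np.linalg.inv(pooled)

    # discriminant axes: eigenvectors of Sigma^-1 B via the symmetric
    # whitened problem W^-1/2 B W^-1/2 (same subspace, stable numerics)
    grand = scores.mean(axis=0)
    between = np.zeros((d, d))
    for i, cls in enumerate(classes):
        n_c = int(np.count_nonzero(label_arr == cls))
        diff = (means[i] - grand)[:, None]
        between += n_c * (diff @ diff.T)
    between /= n
    eigval_w, eigvec_w = np.linalg.eigh(pooled)
    w_inv_half = eigvec_w @ np.diag(1.0 / np.sqrt(np.maximum(eigval_w, 1e-300))) @ eigvec_w.T
    sym = w_inv_half @ between @ w_inv_half
    eigval_b, eigvec_b = np.linalg.eigh(sym)
    order = np.argsort(eigval_b)[::-1][: k - 1]
    scalings = w_inv_half @ eigvec_b[:, order]

    return LDAModel(
        classes=classes,
        priors=prior_vec,
        means=means,
        pooled_cov=pooled,
        pooled_cov_inv=pooled_inv,
        scalings=scalings,
        ridge_applied=ridge_applied,
    )


def posterior_memberships(model: LDAModel, scores: np.ndarray) -> np.ndarray:
    """Posterior class memberships for each row of ``scores`` (rows sum to 1)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    log_post = np.empty((scores.shape[0], model.n_classes))
    for i in range(model.n_classes):
        diff = scores - model.means[i]
        maha = np.einsum("ij,jk,ik->i", diff, model.pooled_cov_inv, diff)
        log_post[:, i] = np.log(model.priors[i]) - 0.5 * maha
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    return post / post.sum(axis=1, keepdims=True)


def loocv_memberships(
    scores: np.ndarray,
    labels: list[str] | np.ndarray,
    priors: dict[str, float] | None = None,
) -> np.ndarray:
    """Leave-one-out posterior membership matrix.

    For each specimen the LDA is refit on all others and the posterior is
    evaluated at the held-out point. The feature (PC) space is not refit —
    only the discriminant. Class columns follow first appearance in the full
    label list. Deterministic: no randomness anywhere.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = [str(l) for l in labels]
    classes = list(dict.fromkeys(labels))
    n = scores.shape[0]
    memberships = np.zeros((n, len(classes)))
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        fold_labels = [labels[j] for j in idx[mask]]
        for cls in classes:
            if fold_labels.count(cls) < 2:
                raise ValueError(
                    f"leaving out specimen {i} leaves class {cls!r} with <2 members; "
                    "larger groups are required for LOOCV"
                )
        model = fit_lda(scores[mask], fold_labels, priors)
        post = posterior_memberships(model, scores[i : i + 1])[0]
        # fold class order may differ; map back to global order
        for j, cls in enumerate(model.classes):
            memberships[i, classes.index(cls)] = post[j]
    return memberships


def ucpm(
    memberships: np.ndarray,
    true_labels: list[str] | np.ndarray,
    classes: list[str] | None = None,
) -> ClassificationReport:
    """Membership-based classification performance report.

    Argmax ties are broken toward the lowest class index. True labels absent
    from ``classes`` are rejected; a class with no true members gets NaN
    per-class confidence.
    """
    memberships = np.atleast_2d(np.asarray(memberships, dtype=float))
    true_labels = [str(l) for l in true_labels]
    if classes is None:
        classes = list(dict.fromkeys(true_labels))
    n, k = memberships.shape
    if k != len(classes):
        raise ValueError("membership columns must match the class list")
    if len(true_labels) != n:
        raise ValueError("one true label per membership row")
    bad = set(true_labels) - set(classes)
    if bad:
        raise ValueError(f"true labels not in class list: {sorted(bad)}")
    row_sums = memberships.sum(axis=1)
    if np.any(np.abs(row_sums - 1) > 1e-6):
        raise ValueError("membership rows must sum to 1")

    assigned_idx = np.argmax(memberships, axis=1)  # ties -> lowest index
    true_idx = np.array([classes.index(t) for t in true_labels])

    eye = np.eye(k)
    correct = assigned_idx == true_idx
    cr = float(np.mean(correct))
    scale = k / (k - 1)
    ac = 1.0 - scale * float(np.mean(np.sum((memberships - eye[true_idx]) ** 2, axis=1)))
    as_ = 1.0 - scale * float(np.mean(np.sum((memberships - eye[assigned_idx]) ** 2, axis=1)))
    assigned_membership = memberships[np.arange(n), assigned_idx]
    cf = float(np.mean(assigned_membership))
    cf_per_class = {}
    for j, cls in enumerate(classes):
        in_class = true_idx == j
        cf_per_class[cls] = (
            float(np.mean(assigned_membership[in_class])) if in_class.any() else float("nan")
        )
    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (true_idx, assigned_idx), 1)

    return ClassificationReport(
        memberships=memberships,
        classes=list(classes),
        true_labels=true_labels,
        assigned_labels=[classes[j] for j in assigned_idx],
        correctness_rate=cr,
        accuracy=ac,
        ability_to_separate=as_,
        confidence=cf,
        confidence_per_class=cf_per_class,
        confusion=confusion,
    )


def classify_unknowns(
    pca_model,
    lda_model: LDAModel,
    unknown_table,
    n_retained: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Predict group identity of unidentified specimens.

    Projects the unknowns into the training PC space, truncates to the
    retained components the LDA was trained on, and returns equal-prior (or
    the model's) posterior memberships plus argmax labels.
    """
    from .ordination import project

    scores = project(pca_model, unknown_table)
    if n_retained is not None:
        scores = scores[:, :n_retained]
    if scores.shape[1] != lda_model.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: LDA trained on {lda_model.means.shape[1]} PCs, "
            f"projection gives {scores.shape[1]}"
        )
    post = posterior_memberships(lda_model, scores)
    labels = [lda_model.classes[int(j)] for j in np.argmax(post, axis=1)]
    return labels, post
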