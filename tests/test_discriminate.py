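import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from morphodisc import (
    fit_lda,
    loocv_memberships,
    posterior_memberships,
    ucpm,
)


def _two_clouds(rng, sep=10.0, n=20, d=3):
    a = rng.normal(size=(n, d))
    b = rng.normal(size=(n, d)) + sep
    return np.vstack([a, b]), ["a"] * n + ["b"] * n


def test_separated_clouds_confident_posteriors(rng):
    scores, labels = _two_clouds(rng)
    model = fit_lda(scores, labels)
    post = posterior_memberships(model, scores)
    own = post[np.arange(len(labels)), [model.classes.index(l) for l in labels]]
    assert np.all(own > 0.999)


def test_equidistant_point_splits_posterior():
    scores = np.array(
        [[-1.0, 0], [-1, 1], [-1, -1], [1.0, 0], [1, 1], [1, -1]]
    )
    labels = ["a", "a", "a", "b", "b", "b"]
    model = fit_lda(scores, labels)
    post = posterior_memberships(model, np.array([[0.0, 0.0]]))[0]
    np.testing.assert_allclose(post, [0.5, 0.5], atol=1e-12)


def test_two_class_posterior_matches_logistic_closed_form(rng):
    """1-D LDA posteriors equal the logistic of the linear discriminant score."""
    x_a = rng.normal(0.0, 1.0, size=15)
    x_b = rng.normal(3.0, 1.0, size=10)
    scores = np.concatenate([x_a, x_b])[:, None]
    labels = ["a"] * 15 + ["b"] * 10
    model = fit_lda(scores, labels)
    mu_a, mu_b = model.means[:, 0]
    sigma2 = model.pooled_cov[0, 0]
    query = np.linspace(-2, 5, 9)
    post = posterior_memberships(model, query[:, None])
    # equal priors: log odds = (mu_a - mu_b)/sigma2 * (x - (mu_a+mu_b)/2)
    log_odds = (mu_a - mu_b) / sigma2 * (query - (mu_a + mu_b) / 2)
    np.testing.assert_allclose(post[:, 0], 1 / (1 + np.exp(-log_odds)), atol=1e-10)


def test_agreement_with_sklearn_lda(rng):
    """Independent implementation check; covariance divisors (n-K vs n) differ
    negligibly at this sample size."""
    scores = np.vstack(
        [rng.normal(size=(40, 4)), rng.normal(size=(40, 4)) + 1.5,
         rng.normal(size=(40, 4)) - 1.5]
    )
    labels = ["a"] * 40 + ["b"] * 40 + ["c"] * 40
    model = fit_lda(scores, labels)
    post = posterior_memberships(model, scores)
    sk = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(scores, labels)
    sk_post = sk.predict_proba(scores)
    assert np.mean(np.argmax(post, 1) == np.argmax(sk_post, 1)) > 0.99
    np.testing.assert_allclose(post, sk_post, atol=0.03)


def test_priors_shift_posteriors(rng):
    scores, labels = _two_clouds(rng, sep=1.0)
    equal = fit_lda(scores, labels)
    skewed = fit_lda(scores, labels, priors={"a": 0.9, "b": 0.1})
    post_eq = posterior_memberships(equal, np.zeros((1, 3)))[0]
    post_sk = posterior_memberships(skewed, np.zeros((1, 3)))[0]
    assert post_sk[0] > post_eq[0]


def test_lda_validation(rng):
    with pytest.raises(ValueError, match="fewer than 2"):
        fit_lda(np.ones((3, 2)) + rng.normal(size=(3, 2)), ["a", "a", "b"])
    with pytest.raises(ValueError, match="two classes"):
        fit_lda(rng.normal(size=(4, 2)), ["a"] * 4)


def test_loocv_perfectly_separable_and_deterministic(rng):
    scores, labels = _two_clouds(rng, sep=20.0)
    m1 = loocv_memberships(scores, labels)
    m2 = loocv_memberships(scores, labels)
    assert np.array_equal(m1, m2)
    report = ucpm(m1, labels)
    assert report.correctness_rate == 1.0
    np.testing.assert_allclose(m1.sum(axis=1), 1.0, atol=1e-9)


def test_loocv_rejects_tiny_classes(rng):
    scores = rng.normal(size=(5, 2))
    with pytest.raises(ValueError, match="<2 members"):
        loocv_memberships(scores, ["a", "a", "a", "b", "b"])


def test_ucpm_perfect_and_uniform():
    eye = np.eye(3)
    truths = ["c0", "c1", "c2"]
    perfect = ucpm(eye, truths)
    assert perfect.correctness_rate == perfect.accuracy == 1.0
    assert perfect.ability_to_separate == perfect.confidence == 1.0

    uniform = ucpm(np.full((6, 3), 1 / 3), ["c0", "c1", "c2"] * 2, classes=truths)
    assert uniform.accuracy == pytest.approx(0.0, abs=1e-12)
    assert uniform.confidence == pytest.approx(1 / 3)
    assert uniform.ability_to_separate == pytest.approx(0.0, abs=1e-12)


def test_ucpm_hand_worked_example():
    """Three-specimen example checked by hand from the adopted formulas."""
    m = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1], [0.4, 0.5, 0.1]])
    truths = ["g1", "g2", "g1"]
    report = ucpm(m, truths, classes=["g1", "g2", "g3"])
    assert report.correctness_rate == pytest.approx(2 / 3, abs=1e-12)
    # AC: mean squared gap to truth indicators .14, .06, .62 -> 1 - 1.5*mean
    assert report.accuracy == pytest.approx(0.59, abs=1e-12)
    # AS: gaps to assigned indicators .14, .06, .42
    assert report.ability_to_separate == pytest.approx(0.69, abs=1e-12)
    assert report.confidence == pytest.approx(2 / 3, abs=1e-12)
    assert report.confidence_per_class["g1"] == pytest.approx(0.6, abs=1e-12)
    assert report.confidence_per_class["g2"] == pytest.approx(0.8, abs=1e-12)
    assert np.isnan(report.confidence_per_class["g3"])
    np.testing.assert_array_equal(
        report.confusion, [[1, 1, 0], [0, 1, 0], [0, 0, 0]]
    )


def test_cr_consistent_with_confusion(rng):
    m = rng.dirichlet(np.ones(3), size=30)
    truths = [f"c{i % 3}" for i in range(30)]
    report = ucpm(m, truths, classes=["c0", "c1", "c2"])
    assert report.correctness_rate == pytest.approx(
        np.trace(report.confusion) / 30
    )
    assert report.confusion.sum() == 30


def test_as_cf_invariant_to_true_label_relabeling(rng):
    """AS and CF depend on assignments only; CR and AC change under relabeling."""
    m = rng.dirichlet(np.ones(3), size=24)
    truths = [f"c{i % 3}" for i in range(24)]
    swapped = {"c0": "c1", "c1": "c0", "c2": "c2"}
    relabelled = [swapped[t] for t in truths]
    r1 = ucpm(m, truths, classes=["c0", "c1", "c2"])
    r2 = ucpm(m, relabelled, classes=["c0", "c1", "c2"])
    assert r2.ability_to_separate == pytest.approx(r1.ability_to_separate)
    assert r2.confidence == pytest.approx(r1.confidence)
    assert r2.correctness_rate != pytest.approx(r1.correctness_rate)


def test_ucpm_rejects_bad_rows():
    with pytest.raises(ValueError, match="sum to 1"):
        ucpm(np.array([[0.5, 0.2, 0.1]]), ["c0"], classes=["c0", "c1", "c2"])
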