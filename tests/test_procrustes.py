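import numpy as np
import pytest

from morphodisc import LandmarkDataset, centroid_size, gpa, opa_align
from morphodisc.procrustes import DegenerateConfigurationError, align_new_to_consensus
from morphodisc.synthetic import _random_rotation


def test_centroid_size_analytic_and_homogeneous(rng):
    cross = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], dtype=float)
    assert centroid_size(cross) == pytest.approx(2.0)
    config = rng.normal(size=(10, 3))
    assert centroid_size(3.7 * config) == pytest.approx(3.7 * centroid_size(config))
    # rotation/translation invariance
    rot = _random_rotation(rng)
    assert centroid_size(config @ rot.T + [5, -2, 9]) == pytest.approx(
        centroid_size(config)
    )


def test_centroid_size_matches_interpoint_brute_force(rng):
    """CS^2 equals the double-loop interpoint formula sum_ij ||xi-xj||^2 / (2p)."""
    config = rng.normal(size=(10, 3))
    acc = 0.0
    for i in range(10):
        for j in range(10):
            acc += np.sum((config[i] - config[j]) ** 2)
    assert centroid_size(config) ** 2 == pytest.approx(acc / (2 * 10), rel=1e-12)


def test_opa_exact_recovery_and_reflection_exclusion(rng):
    target = rng.normal(size=(8, 3))
    rot = _random_rotation(rng)
    mobile = target @ rot.T + np.array([1.0, -2.0, 0.5])
    aligned = opa_align(mobile, target)
    assert np.sum((aligned - target) ** 2) < 1e-18

    reflected = target.copy()
    reflected[:, 0] = -reflected[:, 0]
    aligned = opa_align(reflected, target)
    assert np.sum((aligned - target) ** 2) > 1e-3  # reflections are never matched


def test_opa_residual_is_global_minimum_over_sampled_rotations(rng):
    """OPA residual lower-bounds an exhaustive search over random rotations."""
    mobile = rng.normal(size=(6, 3))
    target = rng.normal(size=(6, 3))
    opa_res = np.sum((opa_align(mobile, target) - target) ** 2)
    mc = mobile - mobile.mean(axis=0)
    tc = target - target.mean(axis=0)
    n_samples = 200_000
    q, r = np.linalg.qr(rng.standard_normal((n_samples, 3, 3)))
    q *= np.sign(np.einsum("nii->ni", r))[:, None, :]
    det = np.linalg.det(q)
    q[det < 0, :, 0] *= -1
    residuals = np.sum((np.einsum("pj,nkj->npk", mc, q) - tc) ** 2, axis=(1, 2))
    assert opa_res <= residuals.min() + 1e-12


def test_opa_rejects_degenerate_configuration():
    line = np.outer(np.arange(4.0), [1.0, 0, 0])
    with pytest.raises(DegenerateConfigurationError):
        opa_align(line, np.random.default_rng(0).normal(size=(4, 3)))


def _rigidly_perturbed_copies(rng, base, n):
    coords = []
    for _ in range(n):
        coords.append(base @ _random_rotation(rng).T + rng.normal(size=3))
    return LandmarkDataset(
        coords=np.stack(coords), specimen_ids=[f"s{i}" for i in range(n)]
    )


def test_gpa_identical_configs_zero_variance(rng):
    base = rng.normal(size=(12, 3))
    ds = _rigidly_perturbed_copies(rng, base, 5)
    res = gpa(ds, scale=False)
    assert res.procrustes_ss < 1e-15
    for i in range(1, 5):
        np.testing.assert_allclose(res.aligned[i], res.aligned[0], atol=1e-9)


def test_gpa_scaled_copies(rng):
    base = rng.normal(size=(12, 3))
    factors = np.array([1.0, 2.5, 0.4, 3.3])
    ds = LandmarkDataset(
        coords=np.stack([f * base for f in factors]),
        specimen_ids=[f"s{i}" for i in range(4)],
    )
    res = gpa(ds, scale=True)
    assert res.procrustes_ss < 1e-15
    np.testing.assert_allclose(res.centroid_sizes, factors * centroid_size(base), rtol=1e-12)
    # full superimposition: every aligned configuration has unit centroid size
    np.testing.assert_allclose(
        np.sqrt(np.sum(res.aligned**2, axis=(1, 2))), 1.0, atol=1e-9
    )


def test_gpa_two_specimens_matches_pairwise_opa(rng):
    """n=2 GPA sum of squares equals half the pairwise OPA residual (closed form)."""
    a = rng.normal(size=(10, 3))
    b = rng.normal(size=(10, 3))
    ds = LandmarkDataset(coords=np.stack([a, b]), specimen_ids=["a", "b"])
    res = gpa(ds, scale=True)

    au = (a - a.mean(0)) / centroid_size(a)
    bu = (b - b.mean(0)) / centroid_size(b)
    pairwise = np.sum((opa_align(bu, au) - au) ** 2)
    assert res.procrustes_ss == pytest.approx(pairwise / 2, abs=1e-9)


def test_gpa_invariant_to_input_motion_and_order(rng, small_dataset):
    dataset, _ = small_dataset
    ref = gpa(dataset, scale=True)

    moved = dataset.coords.copy()
    for i in range(moved.shape[0]):
        moved[i] = moved[i] @ _random_rotation(rng).T + rng.normal(size=3)
    res_moved = gpa(
        LandmarkDataset(moved, list(dataset.specimen_ids), list(dataset.groups)),
        scale=True,
    )
    np.testing.assert_allclose(res_moved.aligned, ref.aligned, atol=1e-8)

    order = rng.permutation(dataset.n_specimens)
    res_perm = gpa(
        LandmarkDataset(
            dataset.coords[order],
            [dataset.specimen_ids[i] for i in order],
            [dataset.groups[i] for i in order],
        ),
        scale=True,
    )
    np.testing.assert_allclose(res_perm.aligned[np.argsort(order)], ref.aligned, atol=1e-8)


def test_partial_gpa_preserves_size(small_dataset):
    dataset, _ = small_dataset
    res = gpa(dataset, scale=False)
    aligned_cs = np.sqrt(np.sum(res.aligned**2, axis=(1, 2)))
    np.testing.assert_allclose(aligned_cs, res.centroid_sizes, rtol=1e-9)


def test_align_new_to_consensus_matches_training_alignment(small_dataset):
    """A training specimen re-aligned to the frozen consensus lands where GPA put it."""
    dataset, _ = small_dataset
    res = gpa(dataset, scale=True)
    sub = dataset.subset(np.arange(dataset.n_specimens) < 3)
    re_aligned = align_new_to_consensus(sub, res)
    np.testing.assert_allclose(re_aligned.aligned, res.aligned[:3], atol=1e-6)
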