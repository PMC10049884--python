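import numpy as np
import pytest

from morphodisc import (
    FeatureTable,
    LandmarkDataset,
    Measurement,
    MeasurementProtocol,
    extract_distances,
    geometric_mean,
    gmm_feature_table,
    gpa,
    log_shape_ratios,
)
from morphodisc.synthetic import _random_rotation


def test_extract_distances_analytic_and_mirror():
    coords = np.array(
        [[[0, 0, 0], [3, 4, 0], [0, 0, 4], [0, 0, -6], [1, 1, 1]]], dtype=float
    )
    ds = LandmarkDataset(coords, ["s0"])
    proto = MeasurementProtocol(
        "demo",
        [
            Measurement("hyp", 0, 1),  # |(3,4,0)| = 5
            Measurement("bilateral", 0, 2, mirror=(0, 3)),  # mean(4, 6) = 5
        ],
    )
    table = extract_distances(ds, proto)
    np.testing.assert_allclose(table.values[0], [5.0, 5.0])
    assert table.treatment == "raw"
    assert table.source == "demo"


def test_distances_invariant_to_rigid_motion(rng):
    coords = rng.normal(size=(4, 9, 3)) + 5
    ds = LandmarkDataset(coords, [f"s{i}" for i in range(4)])
    proto = MeasurementProtocol(
        "p", [Measurement(f"m{i}", i, i + 3) for i in range(4)]
    )
    base = extract_distances(ds, proto)
    moved = coords.copy()
    for i in range(4):
        moved[i] = moved[i] @ _random_rotation(rng).T + rng.normal(size=3)
    table = extract_distances(LandmarkDataset(moved, ds.specimen_ids), proto)
    np.testing.assert_allclose(table.values, base.values, atol=1e-10)
    # equivariance under uniform scaling
    scaled = extract_distances(LandmarkDataset(2.5 * coords, ds.specimen_ids), proto)
    np.testing.assert_allclose(scaled.values, 2.5 * base.values, rtol=1e-12)


def test_geometric_mean_analytic_and_naive_oracle(rng):
    assert geometric_mean(np.array([[1.0, 10.0, 100.0]]))[0] == pytest.approx(10.0)
    assert geometric_mean(np.full((1, 7), 4.2))[0] == pytest.approx(4.2)
    row = rng.uniform(0.1, 50.0, size=20)
    naive = np.prod(row) ** (1 / 20)
    assert geometric_mean(row[None, :])[0] == pytest.approx(naive, rel=1e-12)
    with pytest.raises(ValueError, match="nonpositive"):
        geometric_mean(np.array([[1.0, -2.0]]))


def test_log_shape_ratios_properties(rng):
    values = rng.uniform(1.0, 20.0, size=(6, 5))
    values[0, :3] = [1.0, 10.0, 100.0]
    table = FeatureTable(
        values=values,
        feature_names=[f"f{i}" for i in range(5)],
        treatment="raw",
        size_vector=geometric_mean(values),
        source="p",
    )
    iso = log_shape_ratios(table)
    assert iso.treatment == "isometry_free"
    gm0 = geometric_mean(values[:1])[0]
    np.testing.assert_allclose(
        iso.values[0, :3], np.log10(np.array([1.0, 10.0, 100.0]) / gm0)
    )
    # rows sum to zero (Mosimann property)
    np.testing.assert_allclose(iso.values.sum(axis=1), 0.0, atol=1e-9)
    # per-specimen scale invariance: specimen 2 measured 7x larger
    rescaled = values.copy()
    rescaled[2] *= 7.0
    table7 = FeatureTable(
        values=rescaled, feature_names=table.feature_names, treatment="raw",
        size_vector=geometric_mean(rescaled), source="p",
    )
    np.testing.assert_allclose(log_shape_ratios(table7).values[2], iso.values[2], atol=1e-12)


def test_log_shape_ratio_three_value_row():
    table = FeatureTable(
        values=np.array([[1.0, 10.0, 100.0]]),
        feature_names=["a", "b", "c"],
        treatment="raw",
        size_vector=np.array([10.0]),
        source="p",
    )
    np.testing.assert_allclose(log_shape_ratios(table).values[0], [-1.0, 0.0, 1.0], atol=1e-12)


def test_tetrahedron_log_shape_ratios_vanish(tetrahedron_dataset):
    """All edges of a regular tetrahedron are equal, so shape ratios are zero."""
    proto = MeasurementProtocol(
        "edges",
        [Measurement(f"e{a}{b}", a, b) for a in range(4) for b in range(a + 1, 4)],
    )
    table = extract_distances(tetrahedron_dataset, proto)
    # specimen 2 is a doubled copy: distances scale, ratios do not
    np.testing.assert_allclose(table.values[1], 2 * table.values[0], rtol=1e-12)
    iso = log_shape_ratios(table)
    np.testing.assert_allclose(iso.values, 0.0, atol=1e-12)


def test_gmm_feature_tables_from_gpa(small_dataset):
    dataset, _ = small_dataset
    raw = gmm_feature_table(gpa(dataset, scale=False))
    iso = gmm_feature_table(gpa(dataset, scale=True))
    assert raw.treatment == "raw" and iso.treatment == "isometry_free"
    assert raw.source == iso.source == "GMM"
    assert raw.n_features == 3 * dataset.n_landmarks
    np.testing.assert_allclose(raw.size_vector, iso.size_vector, rtol=1e-12)


def test_feature_table_validation(rng):
    with pytest.raises(ValueError, match="treatment"):
        FeatureTable(np.ones((2, 2)), ["a", "b"], "bogus", np.ones(2), "p")
    with pytest.raises(ValueError, match="positive"):
        FeatureTable(np.ones((2, 2)), ["a", "b"], "raw", np.array([1.0, -1.0]), "p")
    with pytest.raises(ValueError, match="non-finite"):
        FeatureTable(np.full((2, 2), np.inf), ["a", "b"], "raw", np.ones(2), "p")
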