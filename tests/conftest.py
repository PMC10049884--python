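import numpy as np
import pytest

from morphodisc import GroupSpec, LandmarkDataset, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Three well-separated groups, small landmark count: LDA is well-posed."""
    return SyntheticSpec(
        n_landmarks=20,
        groups=(
            GroupSpec("a", n=30, mean_log_size=3.0, sd_log_size=0.05,
                      shape_offset_scale=0.03),
            GroupSpec("b", n=25, mean_log_size=2.95, sd_log_size=0.05,
                      shape_offset_scale=0.03),
            GroupSpec("c", n=20, mean_log_size=2.9, sd_log_size=0.05,
                      shape_offset_scale=0.03),
        ),
        allometry_coefficient=0.4,
        noise_sd=0.003,
        rigid_motion=True,
        seed=7,
    )


@pytest.fixture
def small_dataset(small_spec):
    dataset, truth = generate(small_spec)
    return dataset, truth


@pytest.fixture
def tetrahedron_dataset():
    """Two copies of a regular tetrahedron (all six edges equal)."""
    t = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    return LandmarkDataset(
        coords=np.stack([t, 2.0 * t]),
        specimen_ids=["t1", "t2"],
        groups=["g", "g"],
    )
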