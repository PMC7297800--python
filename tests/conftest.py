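import numpy as np
import pytest

from periprog.network import NetworkModel
from periprog.phantom import PhantomParams, generate_cohort, generate_subject


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200616)


@pytest.fixture(scope="session")
def random_volume_8():
    """Seeded 8^3 intensity volume for oracle-equivalence checks."""
    return np.random.default_rng(8).random((8, 8, 8)) * 100.0


@pytest.fixture(scope="session")
def small_subject():
    """One strong-effect phantom subject on a reduced 32 mm grid."""
    params = PhantomParams(
        grid_shape=(32, 32, 32),
        core_radius_mm=5.0,
        progression_extent_mm=5.0,
        core_offset_mm=3.0,
        n_subjects=1,
        seed=42,
    )
    return generate_subject(params, 0)


@pytest.fixture(scope="session")
def small_cohort():
    """Four strong-effect subjects on the reduced grid."""
    params = PhantomParams(
        grid_shape=(32, 32, 32),
        core_radius_mm=5.0,
        progression_extent_mm=5.0,
        core_offset_mm=3.0,
        n_subjects=4,
        seed=77,
    )
    return generate_cohort(params)


@pytest.fixture(scope="session")
def labeled_tables(small_cohort):
    """Per-subject labeled feature tables, ~400 sampled voxels each."""
    from periprog.experiments import cohort_feature_tables

    return cohort_feature_tables(small_cohort, seed=77, max_voxels=400)


@pytest.fixture
def zero_model():
    """A 294-input network with all-zero weights (outputs 0.5 everywhere)."""
    sizes = (294, 10, 1)
    weights = [
        (np.zeros((a, b)), np.zeros(b)) for a, b in zip(sizes[:-1], sizes[1:])
    ]
    return NetworkModel(sizes, weights, np.zeros(294), np.ones(294))
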