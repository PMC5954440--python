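import numpy as np
import pytest

from scnmap import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort shared by read-only tests."""
    spec = CohortSpec(
        n_per_group=10,
        grid_shape=(10, 12, 10),
        rng_seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def null_spec(rng_seed: int, n: int = 40, grid=(12, 12, 12)) -> CohortSpec:
    """Single-group global-null cohort spec used for FWE calibration."""
    return CohortSpec(
        n_per_group=n,
        age_ranges=((18, 89),),
        group_labels=("all",),
        grid_shape=grid,
        voxel_size_mm=2.0,
        world_origin_mm=(-12.0, -32.0, -12.0),
        hippo_box=((-8.0, 8.0), (-27.0, -15.0), (-8.0, 8.0)),
        rng_seed=rng_seed,
    )
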