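import numpy as np
import pytest

from nhkit.preprocess import BoldRun, MotionTrace
from nhkit.synthetic import CohortSpec, RegionSpec, _box


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_run(data_2d: np.ndarray, grid=(4, 3, 2), tr_s: float = 2.5) -> BoldRun:
    """Wrap a (voxels x time) matrix into a BoldRun on a small grid."""
    v, t = data_2d.shape
    assert v == np.prod(grid)
    return BoldRun(np.asarray(data_2d, float).reshape(*grid, t), np.eye(4), tr_s)


@pytest.fixture
def flat_motion():
    return MotionTrace(np.zeros((20, 6)))


def tiny_cohort_spec(seed: int = 11, **overrides) -> CohortSpec:
    """A 2/2/2 cohort on a small grid with two coupled regions; fast enough
    for end-to-end smoke tests."""
    regions = [
        RegionSpec("reg_a", _box(1, 3, 1, 3, 1, 2),
                   {"control": 0.3, "melancholic": 0.6, "nonmelancholic": 0.3}),
        RegionSpec("reg_b", _box(6, 8, 5, 7, 3, 4),
                   {"control": 0.5, "melancholic": 0.5, "nonmelancholic": 0.5}),
    ]
    defaults = dict(
        group_sizes=(2, 2, 2),
        grid_shape=(10, 9, 6),
        n_volumes=60,
        regions=regions,
        nh_corr_region="reg_a",
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


# -- shared expensive fixture: one full default-cohort pipeline run ----------

@pytest.fixture(scope="session")
def default_pipeline_run():
    from nhkit.pipeline import RunConfig, run_pipeline

    cfg = RunConfig(seed=20240901)
    cfg.cohort.seed = 20240901
    return run_pipeline(cfg)
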