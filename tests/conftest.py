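import numpy as np
import pytest

import lesioncpm as lc
import lesioncpm.behavior as bhv


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study configuration used across integration tests."""
    return lc.SyntheticConfig(
        shape=(24, 28, 24),
        n_rois=20,
        network_size=6,
        n_shared=2,
        n_task_specific=1,
        n_subjects=(40, 30, 25),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return lc.make_phantom(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_phantom):
    return lc.simulate_cohort(small_cfg, phantom=small_phantom)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    return lc.write_cohort(small_cohort, d)


def standardized_scores(records, task):
    return bhv.standardize_scores(bhv.score_records(records, task).dropna())


def group_xy(cohort, phantom, group, atlas):
    task = "TMT" if group in ("group1", "group2") else "Stroop"
    vec = standardized_scores(cohort.behavior[group], task)
    mat = lc.disconnection_matrix(cohort.lesions[group], atlas)
    return mat.scores.loc[vec.subject_ids], vec.values


@pytest.fixture(scope="session")
def group_data(small_cohort, small_phantom):
    """(X, y) per group for the AC atlas, subjects aligned."""
    return {
        g: group_xy(small_cohort, small_phantom, g, small_phantom.atlas_ac)
        for g in ("group1", "group2", "group3")
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_volume(rng, shape=(6, 6, 6), voxel_mm=1.0):
    aff = np.eye(4) * voxel_mm
    aff[3, 3] = 1.0
    return lc.Volume3D(rng.standard_normal(shape), aff)


def random_binary_volume(rng, shape=(6, 6, 6), p=0.4, nonempty=False):
    data = (rng.random(shape) < p).astype(float)
    if nonempty and not data.any():
        data.flat[0] = 1.0
    return lc.Volume3D(data)
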