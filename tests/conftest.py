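"""Shared fixtures: small synthetic tracks, records and datasets."""

import numpy as np
import pytest

from liftload import pose_io, synthetic
from liftload.synthetic import SimConfig, make_profiles, simulate_lift_instance


def make_track(T=5, fps=30.0, video_id="v0", seed=0, conf=0.9):
    """A small random-but-valid PoseTrack."""
    rng = np.random.default_rng(seed)
    kpts = np.empty((T, pose_io.N_KEYPOINTS, 3))
    kpts[:, :, 0] = 900.0 + rng.normal(0, 50, (T, pose_io.N_KEYPOINTS))
    kpts[:, :, 1] = 500.0 + rng.normal(0, 80, (T, pose_io.N_KEYPOINTS))
    kpts[:, :, 2] = conf
    return pose_io.track_from_arrays(kpts, None, fps=fps, video_id=video_id)


@pytest.fixture
def small_track():
    return make_track(T=8, seed=1)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def profile(sim_config):
    return make_profiles(sim_config)[0]


@pytest.fixture(scope="session")
def lift_record(profile, sim_config):
    return simulate_lift_instance(profile, "knuckle", 8.2, "lift", sim_config, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced factorial study: 5 subjects, all postures/loads/tasks."""
    cfg = SimConfig(n_subjects=5, seed=3)
    return synthetic.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_instances(small_dataset):
    return synthetic.dataset_to_instances(small_dataset)
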