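import numpy as np
import pytest

from headmotion.geometry import BallModel, RigidTransform
from headmotion.synthetic import (ScenarioConfig, head_ball, make_face_cloud,
                                  occiput_anchor)


@pytest.fixture(scope="session")
def scenario():
    return ScenarioConfig(n_points=2000, seed=1)


@pytest.fixture(scope="session")
def reference(scenario):
    return make_face_cloud(scenario)


@pytest.fixture(scope="session")
def ball(reference):
    return head_ball(reference)


@pytest.fixture(scope="session")
def anchor(ball):
    return occiput_anchor(ball)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_transform(rng, max_translation_mm=2.0, max_angle_rad=0.035,
                     pivot=None):
    """Random rigid transform with bounded magnitude (seeded)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0, max_angle_rad)
    t = rng.uniform(-1, 1, 3)
    t *= rng.uniform(0, max_translation_mm) / max(np.linalg.norm(t), 1e-12)
    if pivot is not None:
        base = RigidTransform.rotation_about(axis * angle, pivot)
        return RigidTransform(base.rotation, base.translation + t)
    return RigidTransform.from_rotvec(axis * angle, t)
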