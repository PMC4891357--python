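import numpy as np
import pytest

from ucmreach import (
    ArmGeometry,
    VariabilityModel,
    minimum_jerk_path,
    prepare_reference,
    sample_ensemble,
    study_design,
)


@pytest.fixture(scope="session")
def geometry():
    return ArmGeometry()  # 300/250/80/70 mm, no rod


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def finger_reference():
    """Prepared reference movement of the index-finger, non-displaced
    condition (shared: inverse kinematics is the expensive step)."""
    return prepare_reference(study_design()[0])


@pytest.fixture(scope="session")
def small_ensemble(finger_reference):
    """One 25-trial ensemble at the default 2 deg / 0.5 deg noise."""
    return sample_ensemble(finger_reference, VariabilityModel(seed=11))


@pytest.fixture()
def clean_reach():
    """Noiseless 300 mm, 1 s minimum-jerk reach with hold phases, at 100 Hz."""
    start = np.array([215.0, 0.0, -300.0])
    target = start + np.array([300.0, 0.0, 0.0])
    return minimum_jerk_path(start, target, movement_time=1.0), start, target


def random_posture(rng, scale=0.6):
    """A generic, non-degenerate 9-joint posture away from full extension."""
    base = np.array([0.2, 0.8, -0.3, -1.2, 0.2, 0.1, -0.2, 0.05, 0.15])
    return base + scale * rng.uniform(-0.3, 0.3, size=9)
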