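import numpy as np
import pytest

from biomechfit.models import default_gait_skeleton
from biomechfit.skeleton import JointSpec, MarkerDef, SegmentSpec, Skeleton
from biomechfit.synthetic import GaitConfig, NoiseConfig, generate_trial, synthesize_markers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def gait_skel():
    return default_gait_skeleton()


@pytest.fixture
def single_box():
    """One free-floating 10 kg box."""
    return Skeleton(
        [SegmentSpec("box", (0.2, 0.3, 0.4), 1.0)],
        [JointSpec("root", "free6", "", "box")],
        [MarkerDef("M0", "box", (0.1, 0.0, 0.0))],
        total_mass=10.0,
    )


@pytest.fixture
def chain3():
    """Root box + two revolute links with markers on every segment."""
    segments = [
        SegmentSpec("base", (0.2, 0.2, 0.2), 0.5),
        SegmentSpec("link1", (0.1, 0.4, 0.1), 0.3, "cylinder", (0.0, -0.2, 0.0)),
        SegmentSpec("link2", (0.1, 0.3, 0.1), 0.2, "cylinder", (0.0, -0.15, 0.0)),
    ]
    joints = [
        JointSpec("root", "free6", "", "base"),
        JointSpec("j1", "ball3", "base", "link1", (0.05, -0.1, 0.0)),
        JointSpec("j2", "revolute1", "link1", "link2", (0.0, -0.4, 0.0),
                  axis_local=(0.0, 0.0, 1.0)),
    ]
    markers = [
        MarkerDef("B1", "base", (0.1, 0.1, 0.0), True),
        MarkerDef("B2", "base", (-0.1, 0.0, 0.1)),
        MarkerDef("B3", "base", (0.0, -0.1, -0.1)),
        MarkerDef("L1A", "link1", (0.05, -0.1, 0.0), True),
        MarkerDef("L1B", "link1", (-0.05, -0.3, 0.02)),
        MarkerDef("L2A", "link2", (0.04, -0.1, 0.0), True),
        MarkerDef("L2B", "link2", (0.0, -0.25, 0.04)),
    ]
    return Skeleton(segments, joints, markers, total_mass=20.0)


@pytest.fixture(scope="session")
def short_trial():
    """2 s noisy synthetic walking trial (seed 11), shared across tests."""
    return generate_trial(11, gait=GaitConfig(duration=2.0))


@pytest.fixture(scope="session")
def short_trial_clean(short_trial):
    """Noise-free markers for the same ground truth."""
    markers = synthesize_markers(short_trial.skeleton, short_trial.q,
                                 short_trial.frame_rate,
                                 NoiseConfig(marker_sigma=0.0), seed=99)
    return short_trial, markers
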