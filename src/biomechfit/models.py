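"""Default full-body gait skeleton (13 segments, 41 markers).

Geometry is a generic adult template: Y-up, X forward, Z to the subject's
right, pelvis at the root.  Nominal mass fractions follow standard
anthropometric tables (hands merged into forearms, trunk merged into a single
torso segment) and sum to one exactly.
"""

from __future__ import annotations

import numpy as np

from .skeleton import JointSpec, MarkerDef, SegmentSpec, Skeleton

# (name, dims xyz, mass fraction, inertia model, com offset)
_SEGMENTS = [
    ("pelvis", (0.25, 0.15, 0.30), 0.142, "box", (0.0, 0.0, 0.0)),
    ("torso", (0.25, 0.45, 0.30), 0.355, "box", (0.0, 0.22, 0.0)),
    ("head", (0.18, 0.24, 0.18), 0.081, "box", (0.0, 0.12, 0.0)),
    ("thigh_r", (0.14, 0.42, 0.14), 0.100, "cylinder", (0.0, -0.18, 0.0)),
    ("shank_r", (0.11, 0.43, 0.11), 0.0465, "cylinder", (0.0, -0.19, 0.0)),
    ("foot_r", (0.25, 0.08, 0.10), 0.0145, "box", (0.05, -0.05, 0.0)),
    ("thigh_l", (0.14, 0.42, 0.14), 0.100, "cylinder", (0.0, -0.18, 0.0)),
    ("shank_l", (0.11, 0.43, 0.11), 0.0465, "cylinder", (0.0, -0.19, 0.0)),
    ("foot_l", (0.25, 0.08, 0.10), 0.0145, "box", (0.05, -0.05, 0.0)),
    ("upper_arm_r", (0.09, 0.30, 0.09), 0.028, "cylinder", (0.0, -0.14, 0.0)),
    ("forearm_r", (0.08, 0.35, 0.08), 0.022, "cylinder", (0.0, -0.15, 0.0)),
    ("upper_arm_l", (0.09, 0.30, 0.09), 0.028, "cylinder", (0.0, -0.14, 0.0)),
    ("forearm_l", (0.08, 0.35, 0.08), 0.022, "cylinder", (0.0, -0.15, 0.0)),
]

_Z = (0.0, 0.0, 1.0)

# (name, type, parent, child, parent offset, axis)
_JOINTS = [
    ("ground_pelvis", "free6", "", "pelvis", (0, 0, 0), None),
    ("lumbar", "ball3", "pelvis", "torso", (0.0, 0.10, 0.0), None),
    ("neck", "ball3", "torso", "head", (0.0, 0.45, 0.0), None),
    ("hip_r", "ball3", "pelvis", "thigh_r", (0.0, -0.07, 0.09), None),
    ("knee_r", "revolute1", "thigh_r", "shank_r", (0.0, -0.42, 0.0), _Z),
    ("ankle_r", "revolute1", "shank_r", "foot_r", (0.0, -0.43, 0.0), _Z),
    ("hip_l", "ball3", "pelvis", "thigh_l", (0.0, -0.07, -0.09), None),
    ("knee_l", "revolute1", "thigh_l", "shank_l", (0.0, -0.42, 0.0), _Z),
    ("ankle_l", "revolute1", "shank_l", "foot_l", (0.0, -0.43, 0.0), _Z),
    ("shoulder_r", "ball3", "torso", "upper_arm_r", (0.0, 0.40, 0.19), None),
    ("elbow_r", "revolute1", "upper_arm_r", "forearm_r", (0.0, -0.30, 0.0), _Z),
    ("shoulder_l", "ball3", "torso", "upper_arm_l", (0.0, 0.40, -0.19), None),
    ("elbow_l", "revolute1", "upper_arm_l", "forearm_l", (0.0, -0.30, 0.0), _Z),
]

# (label, segment, offset, anatomical)
_RIGHT_MARKERS = [
    ("RKNE", "thigh_r", (0.0, -0.42, 0.07), True),
    ("RTH1", "thigh_r", (0.06, -0.15, 0.05), False),
    ("RTH2", "thigh_r", (0.02, -0.25, 0.07), False),
    ("RTH3", "thigh_r", (0.07, -0.32, 0.02), False),
    ("RANK", "shank_r", (0.0, -0.43, 0.055), True),
    ("RSH1", "shank_r", (0.05, -0.12, 0.04), False),
    ("RSH2", "shank_r", (0.01, -0.22, 0.06), False),
    ("RSH3", "shank_r", (0.04, -0.33, 0.03), False),
    ("RHEE", "foot_r", (-0.05, -0.04, 0.0), True),
    ("RTOE", "foot_r", (0.18, -0.06, -0.01), True),
    ("RMT5", "foot_r", (0.12, -0.05, 0.05), False),
    ("RSHO", "upper_arm_r", (0.0, 0.02, 0.05), True),
    ("RUPA", "upper_arm_r", (0.02, -0.18, 0.04), False),
    ("RUPB", "upper_arm_r", (-0.035, -0.22, -0.02), False),
    ("RELB", "forearm_r", (0.0, 0.0, 0.05), True),
    ("RFRM", "forearm_r", (-0.025, -0.12, -0.035), False),
    ("RWRA", "forearm_r", (0.01, -0.26, 0.03), True),
]

_AXIAL_MARKERS = [
    ("RASI", "pelvis", (0.12, 0.02, 0.12), True),
    ("LASI", "pelvis", (0.12, 0.02, -0.12), True),
    ("RPSI", "pelvis", (-0.12, 0.03, 0.05), True),
    ("LPSI", "pelvis", (-0.12, 0.03, -0.05), True),
    ("C7", "torso", (-0.07, 0.42, 0.0), True),
    ("CLAV", "torso", (0.07, 0.38, 0.0), True),
    ("T10", "torso", (-0.09, 0.20, 0.0), False),
    ("STRN", "torso", (0.09, 0.22, 0.0), False),
    ("RFHD", "head", (0.08, 0.10, 0.06), True),
    ("LFHD", "head", (0.08, 0.10, -0.06), False),
    ("RBHD", "head", (-0.08, 0.02, 0.05), False),
]


def _mirror(label: str) -> str:
    return "L" + label[1:]


def default_gait_skeleton(total_mass: float = 75.0) -> Skeleton:
    """Build the generic 13-segment skeleton with its default marker set."""
    segments = [
        SegmentSpec(n, np.array(d), f, model, np.array(c))
        for n, d, f, model, c in _SEGMENTS
    ]
    joints = [
        JointSpec(n, t, p, c, np.array(po), axis_local=np.array(a) if a else None)
        for n, t, p, c, po, a in _JOINTS
    ]
    markers = [MarkerDef(l, s, np.array(o), a) for l, s, o, a in _AXIAL_MARKERS]
    for label, seg, off, anat in _RIGHT_MARKERS:
        markers.append(MarkerDef(label, seg, np.array(off), anat))
        moff = np.array(off) * np.array([1.0, 1.0, -1.0])
        markers.append(MarkerDef(_mirror(label), seg.replace("_r", "_l"), moff, anat))
    return Skeleton(segments, joints, markers, total_mass=total_mass)


FOOT_SEGMENTS = ("foot_r", "foot_l")


def foot_sole_drop(skel: Skeleton, foot: str) -> float:
    """Vertical distance from the foot segment origin (ankle) down to the sole."""
    i = skel.segment_index(foot)
    return float(skel.scales[i, 1] * skel.segments[i].nominal_length[1])


def subject_height(skel: Skeleton) -> float:
    """Standing stature: sole to top of head at the zero pose."""
    up = standing_pelvis_height(skel)
    for jname in ("lumbar", "neck"):
        j = skel.joints[skel.joint_index(jname)]
        pi = skel.segment_index(j.parent_segment)
        up += skel.scales[pi, 1] * j.parent_offset_local[1]
    hi = skel.segment_index("head")
    up += skel.scales[hi, 1] * skel.segments[hi].nominal_length[1]
    return float(up)


def standing_pelvis_height(skel: Skeleton) -> float:
    """Pelvis origin height that puts the soles on the ground at the zero pose."""
    drop = 0.0
    for jname in ("hip_r", "knee_r", "ankle_r"):
        j = skel.joints[skel.joint_index(jname)]
        pi = skel.segment_index(j.parent_segment)
        drop += -(skel.scales[pi, 1] * j.parent_offset_local[1])
    return drop + foot_sole_drop(skel, "foot_r")
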