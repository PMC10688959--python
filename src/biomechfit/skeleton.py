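"""Minimal articulated rigid-body engine for marker-driven biomechanics.

A :class:`Skeleton` is a kinematic tree of scalable segments connected by
``free6`` (root), ``ball3`` (Euler XYZ) and ``revolute1`` joints, with optical
markers attached to segments by local offsets.  The engine provides forward
kinematics, analytic marker Jacobians with respect to joint coordinates ``q``,
per-segment scales ``s`` and marker offsets ``p``, the generalized mass
matrix, bias (Coriolis + gravity) forces, and inverse dynamics with external
wrenches.

Conventions: Y-up world, SI units, radians internally.  Ball and root
orientations use intrinsic Euler XYZ angles; keep the middle angle away from
+/-90 degrees (gimbal lock).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

SKELETON_FORMAT = "biomechfit-skeleton-v1"
DEFAULT_GRAVITY = np.array([0.0, -9.80665, 0.0])

JOINT_DOF = {"free6": 6, "ball3": 3, "revolute1": 1}

_EX = np.array([1.0, 0.0, 0.0])
_EY = np.array([0.0, 1.0, 0.0])
_EZ = np.array([0.0, 0.0, 1.0])


class SkeletonError(ValueError):
    """Raised on contract violations (bad tree, dimension mismatch, ...)."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class JointSpec:
    name: str
    type: str  # free6 | ball3 | revolute1
    parent_segment: str  # "" for the root joint
    child_segment: str
    parent_offset_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    child_offset_local: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_local: Optional[np.ndarray] = None  # revolute only

    def __post_init__(self):
        self.parent_offset_local = np.asarray(self.parent_offset_local, float)
        self.child_offset_local = np.asarray(self.child_offset_local, float)
        if self.type not in JOINT_DOF:
            raise SkeletonError(f"unknown joint type {self.type!r}")
        if self.type == "revolute1":
            if self.axis_local is None:
                raise SkeletonError(f"revolute joint {self.name!r} needs axis_local")
            a = np.asarray(self.axis_local, float)
            n = np.linalg.norm(a)
            if not np.isclose(n, 1.0, atol=1e-6):
                raise SkeletonError(f"axis_local of {self.name!r} must be unit norm")
            self.axis_local = a / n

    @property
    def dof(self) -> int:
        return JOINT_DOF[self.type]


@dataclass
class SegmentSpec:
    name: str
    nominal_length: np.ndarray  # per-axis dimensions, m
    nominal_mass_fraction: float
    inertia_model: str = "box"  # box | cylinder
    com_offset_local: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.nominal_length = np.asarray(self.nominal_length, float)
        self.com_offset_local = np.asarray(self.com_offset_local, float)
        if np.any(self.nominal_length <= 0):
            raise SkeletonError(f"segment {self.name!r} has non-positive dimensions")
        if self.inertia_model not in ("box", "cylinder"):
            raise SkeletonError(f"unknown inertia model {self.inertia_model!r}")


@dataclass
class MarkerDef:
    label: str
    segment: str
    offset_local: np.ndarray
    anatomical: bool = False

    def __post_init__(self):
        self.offset_local = np.asarray(self.offset_local, float)


@dataclass
class Pose:
    q: np.ndarray
    qdot: Optional[np.ndarray] = None
    qddot: Optional[np.ndarray] = None

    def __post_init__(self):
        self.q = np.asarray(self.q, float)
        if self.qdot is not None:
            self.qdot = np.asarray(self.qdot, float)
        if self.qddot is not None:
            self.qddot = np.asarray(self.qddot, float)


# ---------------------------------------------------------------------------
# Rotation helpers
# ---------------------------------------------------------------------------

def rot_x(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def rot_y(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def rot_z(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_xyz(angles: np.ndarray) -> np.ndarray:
    """Intrinsic XYZ Euler rotation: R = Rx(a) @ Ry(b) @ Rz(c)."""
    a, b, c = angles
    return rot_x(a) @ rot_y(b) @ rot_z(c)


def axis_angle(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    k = np.asarray(axis, float)
    K = skew(k)
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3-vector cross product without np.cross's axis-handling overhead."""
    return np.array([
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    ])


def skew(v: np.ndarray) -> np.ndarray:
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def euler_xyz_axes(angles: np.ndarray) -> np.ndarray:
    """Columns are the rotation axes of the XYZ Euler rates, expressed in the
    frame *before* the joint rotation.

    omega_pre = E(angles) @ [da, db, dc]
    """
    a, b, _ = angles
    Rx = rot_x(a)
    return np.column_stack([_EX, Rx @ _EY, Rx @ rot_y(b) @ _EZ])


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

class Skeleton:
    """Kinematic tree with scales, markers, and inertial properties."""

    def __init__(
        self,
        segments: Sequence[SegmentSpec],
        joints: Sequence[JointSpec],
        markers: Sequence[MarkerDef] = (),
        scales: Optional[np.ndarray] = None,
        segment_masses: Optional[np.ndarray] = None,
        total_mass: float = 75.0,
        gravity: np.ndarray = DEFAULT_GRAVITY,
    ):
        self.segments: List[SegmentSpec] = list(segments)
        self.markers: List[MarkerDef] = list(markers)
        self.gravity = np.asarray(gravity, float)

        self._seg_index: Dict[str, int] = {s.name: i for i, s in enumerate(self.segments)}
        if len(self._seg_index) != len(self.segments):
            raise SkeletonError("duplicate segment names")

        self.joints = self._order_joints(list(joints))
        self._validate_markers()

        nseg = len(self.segments)
        fr = np.array([s.nominal_mass_fraction for s in self.segments])
        if abs(fr.sum() - 1.0) > 1e-9:
            raise SkeletonError(f"mass fractions sum to {fr.sum()}, expected 1")
        self.scales = (
            np.ones((nseg, 3)) if scales is None else np.array(scales, float).reshape(nseg, 3)
        )
        if np.any(self.scales <= 0):
            raise SkeletonError("scales must be positive")
        if segment_masses is None:
            self.segment_masses = fr * float(total_mass)
        else:
            self.segment_masses = np.array(segment_masses, float).reshape(nseg)
        if self.segment_masses.sum() <= 0:
            raise SkeletonError("total mass must be positive")

        self._build_layout()

    # -- construction helpers -------------------------------------------------

    def _order_joints(self, joints: List[JointSpec]) -> List[JointSpec]:
        roots = [j for j in joints if j.parent_segment == ""]
        if len(roots) != 1 or roots[0].type != "free6":
            raise SkeletonError("joint graph must be rooted at exactly one free6 joint")
        by_parent: Dict[str, List[JointSpec]] = {}
        for j in joints:
            by_parent.setdefault(j.parent_segment, []).append(j)
        ordered: List[JointSpec] = []
        seen_child = set()
        stack = [roots[0]]
        while stack:
            j = stack.pop(0)
            if j.child_segment in seen_child:
                raise SkeletonError(f"segment {j.child_segment!r} has two parent joints")
            if j.child_segment not in self._seg_index:
                raise SkeletonError(f"joint {j.name!r} references unknown segment")
            seen_child.add(j.child_segment)
            ordered.append(j)
            stack.extend(by_parent.get(j.child_segment, []))
        if len(ordered) != len(joints):
            raise SkeletonError("joint graph is not a connected tree")
        if len(ordered) != len(self.segments):
            raise SkeletonError("every segment needs exactly one parent joint")
        return ordered

    def _validate_markers(self):
        labels = [m.label for m in self.markers]
        if len(set(labels)) != len(labels):
            raise SkeletonError("duplicate marker labels")
        for m in self.markers:
            if m.segment not in self._seg_index:
                raise SkeletonError(f"marker {m.label!r} on unknown segment {m.segment!r}")

    def _build_layout(self):
        self.nq = sum(j.dof for j in self.joints)
        self._joint_qslice: List[slice] = []
        off = 0
        for j in self.joints:
            self._joint_qslice.append(slice(off, off + j.dof))
            off += j.dof
        # joint index whose child is segment i
        self._parent_joint_of_seg = [-1] * len(self.segments)
        for ji, j in enumerate(self.joints):
            self._parent_joint_of_seg[self._seg_index[j.child_segment]] = ji
        # boolean (nseg, nq): dof k moves segment b
        mask = np.zeros((len(self.segments), self.nq), bool)
        for ji, j in enumerate(self.joints):
            si = self._seg_index[j.child_segment]
            sl = self._joint_qslice[ji]
            mask[si, sl] = True
            if j.parent_segment:
                mask[si] |= mask[self._seg_index[j.parent_segment]]
        self._dof_mask = mask
        self._marker_seg = np.array([self._seg_index[m.segment] for m in self.markers], int)
        self._marker_offsets = (
            np.array([m.offset_local for m in self.markers]).reshape(-1, 3)
            if self.markers
            else np.zeros((0, 3))
        )

    # -- basic accessors ------------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def total_mass(self) -> float:
        return float(self.segment_masses.sum())

    @property
    def marker_labels(self) -> List[str]:
        return [m.label for m in self.markers]

    @property
    def root_rot_slice(self) -> slice:
        return slice(3, 6)

    @property
    def root_trans_slice(self) -> slice:
        return slice(0, 3)

    def segment_index(self, name: str) -> int:
        return self._seg_index[name]

    def joint_index(self, name: str) -> int:
        for i, j in enumerate(self.joints):
            if j.name == name:
                return i
        raise KeyError(name)

    def joint_qslice(self, name_or_index) -> slice:
        if isinstance(name_or_index, str):
            name_or_index = self.joint_index(name_or_index)
        return self._joint_qslice[name_or_index]

    def coordinate_names(self) -> List[str]:
        names = []
        for j in self.joints:
            if j.type == "free6":
                names += [f"{j.name}_tx", f"{j.name}_ty", f"{j.name}_tz",
                          f"{j.name}_rx", f"{j.name}_ry", f"{j.name}_rz"]
            elif j.type == "ball3":
                names += [f"{j.name}_rx", f"{j.name}_ry", f"{j.name}_rz"]
            else:
                names.append(f"{j.name}_angle")
        return names

    def rotational_dofs(self) -> np.ndarray:
        """Indices of all rotational generalized coordinates (joint angles)."""
        idx = []
        for ji, j in enumerate(self.joints):
            sl = self._joint_qslice[ji]
            if j.type == "free6":
                idx.extend(range(sl.start + 3, sl.stop))
            else:
                idx.extend(range(sl.start, sl.stop))
        return np.array(idx, int)

    def with_scales(self, scales: np.ndarray) -> "Skeleton":
        """Independent copy with the given scales; shares no mutable spec
        objects with self (set_marker_offsets on the copy must not leak)."""
        skel = self.copy()
        skel.scales = np.array(scales, float).reshape(self.n_segments, 3)
        if np.any(skel.scales <= 0):
            raise SkeletonError("scales must be positive")
        return skel

    def copy(self) -> "Skeleton":
        skel = Skeleton(
            [replace(s) for s in self.segments],
            [replace(j) for j in self.joints],
            [replace(m) for m in self.markers],
            scales=self.scales.copy(),
            segment_masses=self.segment_masses.copy(),
            gravity=self.gravity.copy(),
        )
        return skel

    def set_marker_offsets(self, offsets: np.ndarray):
        offsets = np.asarray(offsets, float).reshape(self.n_markers, 3)
        for m, o in zip(self.markers, offsets):
            m.offset_local = o.copy()
        self._marker_offsets = offsets.copy()

    def marker_offsets(self) -> np.ndarray:
        return self._marker_offsets.copy()

    def check_pose(self, pose: Pose, need_derivatives: bool = False):
        if pose.q.shape != (self.nq,):
            raise SkeletonError(f"pose has dim {pose.q.shape}, skeleton needs ({self.nq},)")
        if need_derivatives and (pose.qdot is None or pose.qddot is None):
            raise SkeletonError("pose must carry qdot and qddot")

    # -- kinematics -----------------------------------------------------------

    def fk_state(self, q: np.ndarray) -> "KinState":
        """Forward kinematics: world transforms of all segments plus per-dof
        axis/point data used by the geometric Jacobians."""
        q = np.asarray(q, float)
        if q.shape != (self.nq,):
            raise SkeletonError(f"q has shape {q.shape}, expected ({self.nq},)")
        nseg, nq = self.n_segments, self.nq
        R = np.zeros((nseg, 3, 3))
        o = np.zeros((nseg, 3))
        jpos = np.zeros((len(self.joints), 3))
        dof_axis = np.zeros((nq, 3))
        dof_point = np.zeros((nq, 3))
        dof_is_rot = np.zeros(nq, bool)

        for ji, j in enumerate(self.joints):
            sl = self._joint_qslice[ji]
            ci = self._seg_index[j.child_segment]
            qj = q[sl]
            if j.type == "free6":
                pj = qj[:3]
                R_pre = np.eye(3)
                Rj = euler_xyz(qj[3:6])
                E = euler_xyz_axes(qj[3:6])
                dof_axis[sl.start:sl.start + 3] = np.eye(3)
                dof_is_rot[sl.start:sl.start + 3] = False
                rot_sl = slice(sl.start + 3, sl.stop)
                dof_axis[rot_sl] = (R_pre @ E).T
                dof_point[rot_sl] = pj
                dof_is_rot[rot_sl] = True
            else:
                pi = self._seg_index[j.parent_segment]
                R_pre = R[pi]
                pj = o[pi] + R_pre @ (self.scales[pi] * j.parent_offset_local)
                if j.type == "ball3":
                    Rj = euler_xyz(qj)
                    E = euler_xyz_axes(qj)
                    dof_axis[sl] = (R_pre @ E).T
                else:  # revolute1
                    Rj = axis_angle(j.axis_local, qj[0])
                    dof_axis[sl] = R_pre @ j.axis_local
                dof_point[sl] = pj
                dof_is_rot[sl] = True
            Rc = R_pre @ Rj
            R[ci] = Rc
            o[ci] = pj - Rc @ (self.scales[ci] * j.child_offset_local)
            jpos[ji] = pj

        return KinState(self, q, R, o, jpos, dof_axis, dof_point, dof_is_rot)

    # -- serialization --------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": SKELETON_FORMAT,
            "gravity": self.gravity.tolist(),
            "segments": [
                {
                    "name": s.name,
                    "nominal_length": s.nominal_length.tolist(),
                    "nominal_mass_fraction": s.nominal_mass_fraction,
                    "inertia_model": s.inertia_model,
                    "com_offset_local": s.com_offset_local.tolist(),
                }
                for s in self.segments
            ],
            "joints": [
                {
                    "name": j.name,
                    "type": j.type,
                    "parent_segment": j.parent_segment,
                    "child_segment": j.child_segment,
                    "parent_offset_local": j.parent_offset_local.tolist(),
                    "child_offset_local": j.child_offset_local.tolist(),
                    **({"axis_local": j.axis_local.tolist()} if j.axis_local is not None else {}),
                }
                for j in self.joints
            ],
            "markers": [
                {
                    "label": m.label,
                    "segment": m.segment,
                    "offset_local": m.offset_local.tolist(),
                    "anatomical": m.anatomical,
                }
                for m in self.markers
            ],
            "scales": {s.name: self.scales[i].tolist() for i, s in enumerate(self.segments)},
            "segment_masses": {
                s.name: float(self.segment_masses[i]) for i, s in enumerate(self.segments)
            },
        }

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "Skeleton":
        if d.get("format") != SKELETON_FORMAT:
            raise SkeletonError(f"unsupported skeleton format {d.get('format')!r}")
        segments = [
            SegmentSpec(
                name=s["name"],
                nominal_length=s["nominal_length"],
                nominal_mass_fraction=s["nominal_mass_fraction"],
                inertia_model=s.get("inertia_model", "box"),
                com_offset_local=s.get("com_offset_local", np.zeros(3)),
            )
            for s in d["segments"]
        ]
        joints = [
            JointSpec(
                name=j["name"],
                type=j["type"],
                parent_segment=j["parent_segment"],
                child_segment=j["child_segment"],
                parent_offset_local=j.get("parent_offset_local", np.zeros(3)),
                child_offset_local=j.get("child_offset_local", np.zeros(3)),
                axis_local=j.get("axis_local"),
            )
            for j in d["joints"]
        ]
        markers = [
            MarkerDef(m["label"], m["segment"], m["offset_local"], m.get("anatomical", False))
            for m in d.get("markers", [])
        ]
        skel = cls(segments, joints, markers, gravity=np.asarray(d.get("gravity", DEFAULT_GRAVITY)))
        if "scales" in d:
            skel.scales = np.array([d["scales"][s.name] for s in segments], float)
        if "segment_masses" in d:
            skel.segment_masses = np.array([d["segment_masses"][s.name] for s in segments], float)
        return skel

    @classmethod
    def load(cls, path) -> "Skeleton":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Kinematic state + Jacobians
# ---------------------------------------------------------------------------

@dataclass
class KinState:
    skel: Skeleton
    q: np.ndarray
    R: np.ndarray       # (nseg, 3, 3) world rotations
    o: np.ndarray       # (nseg, 3) world segment origins
    joint_pos: np.ndarray   # (njoint, 3) world joint positions
    dof_axis: np.ndarray    # (nq, 3)
    dof_point: np.ndarray   # (nq, 3)
    dof_is_rot: np.ndarray  # (nq,)

    def marker_positions(self) -> np.ndarray:
        sk = self.skel
        if sk.n_markers == 0:
            return np.zeros((0, 3))
        seg = sk._marker_seg
        off = sk.scales[seg] * sk._marker_offsets
        return self.o[seg] + np.einsum("mij,mj->mi", self.R[seg], off)

    def point_jacobian_q(self, points: np.ndarray, seg_indices: np.ndarray) -> np.ndarray:
        """Geometric Jacobian of world points attached to segments: (P, 3, nq)."""
        sk = self.skel
        points = np.atleast_2d(points)
        seg_indices = np.atleast_1d(seg_indices)
        mask = sk._dof_mask[seg_indices]  # (P, nq)
        diff = points[:, None, :] - self.dof_point[None, :, :]       # (P, nq, 3)
        C = np.cross(self.dof_axis[None, :, :], diff)                # (P, nq, 3)
        C[:, ~self.dof_is_rot, :] = self.dof_axis[~self.dof_is_rot]
        C *= mask[:, :, None]
        return C.transpose(0, 2, 1)

    def angular_jacobian(self, seg_indices: np.ndarray) -> np.ndarray:
        """Maps qdot to world angular velocity of segments: (P, 3, nq)."""
        sk = self.skel
        seg_indices = np.atleast_1d(seg_indices)
        mask = sk._dof_mask[seg_indices] & self.dof_is_rot[None, :]
        J = self.dof_axis.T[None, :, :] * mask[:, None, :]
        return J


def forward_kinematics(skel: Skeleton, pose: Pose) -> Dict[str, np.ndarray]:
    """World position of every marker at the given pose."""
    skel.check_pose(pose)
    st = skel.fk_state(pose.q)
    X = st.marker_positions()
    return {m.label: X[i] for i, m in enumerate(skel.markers)}


def marker_world_positions(skel: Skeleton, q: np.ndarray) -> np.ndarray:
    return skel.fk_state(q).marker_positions()


def _scale_chain_contribs(skel: Skeleton, st: KinState) -> List[List[Tuple[int, np.ndarray]]]:
    """Per segment: list of (segment index, 3x3) terms giving the sensitivity
    of any point carried by that segment to upstream segment scales."""
    nseg = skel.n_segments
    contrib: List[List[Tuple[int, np.ndarray]]] = [[] for _ in range(nseg)]
    for j in skel.joints:
        ci = skel._seg_index[j.child_segment]
        terms: List[Tuple[int, np.ndarray]] = []
        if j.parent_segment:
            pi = skel._seg_index[j.parent_segment]
            terms = list(contrib[pi])
            terms.append((pi, st.R[pi] * j.parent_offset_local[np.newaxis, :]))
        if np.any(j.child_offset_local):
            terms = terms + [(ci, -(st.R[ci] * j.child_offset_local[np.newaxis, :]))]
        contrib[ci] = terms
    return contrib


def attached_point_jacobians(
    skel: Skeleton,
    st: KinState,
    seg_indices: np.ndarray,
    local_offsets: np.ndarray,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """World positions and analytic partials of points attached to segments.

    Returns (X, Jq, Js) with shapes (P,3), (P,3,nq), (P,3,3*nseg); the local
    offsets are scaled elementwise by their segment's scale before transform.
    """
    seg_indices = np.atleast_1d(np.asarray(seg_indices, int))
    local_offsets = np.atleast_2d(np.asarray(local_offsets, float))
    off = skel.scales[seg_indices] * local_offsets
    X = st.o[seg_indices] + np.einsum("pij,pj->pi", st.R[seg_indices], off)
    Jq = st.point_jacobian_q(X, seg_indices)
    contrib = _scale_chain_contribs(skel, st)
    P = len(seg_indices)
    Js = np.zeros((P, 3, skel.n_segments * 3))
    for pi_ in range(P):
        b = seg_indices[pi_]
        for si, mat in contrib[b]:
            Js[pi_, :, si * 3:si * 3 + 3] += mat
        Js[pi_, :, b * 3:b * 3 + 3] += st.R[b] * local_offsets[pi_][np.newaxis, :]
    return X, Jq, Js


def _scale_jacobian(skel: Skeleton, st: KinState) -> np.ndarray:
    """(M, 3, nseg*3) partials of marker world positions w.r.t. scales."""
    _, _, Js = attached_point_jacobians(skel, st, skel._marker_seg, skel._marker_offsets)
    return Js


def marker_jacobians(skel: Skeleton, pose: Pose) -> np.ndarray:
    """Dense (3M) x (nq + 3*nseg + 3M) Jacobian of all marker world positions
    with respect to (q, s, p)."""
    skel.check_pose(pose)
    st = skel.fk_state(pose.q)
    X = st.marker_positions()
    M = skel.n_markers
    Jq = st.point_jacobian_q(X, skel._marker_seg)            # (M,3,nq)
    Js = _scale_jacobian(skel, st)                            # (M,3,3S)
    J = np.zeros((3 * M, skel.nq + 3 * skel.n_segments + 3 * M))
    J[:, :skel.nq] = Jq.reshape(3 * M, skel.nq)
    J[:, skel.nq:skel.nq + 3 * skel.n_segments] = Js.reshape(3 * M, -1)
    off = skel.nq + 3 * skel.n_segments
    for mi in range(M):
        b = skel._marker_seg[mi]
        J[3 * mi:3 * mi + 3, off + 3 * mi:off + 3 * mi + 3] = st.R[b] * skel.scales[b][np.newaxis, :]
    return J


def com_position(skel: Skeleton, pose: Pose) -> np.ndarray:
    """Mass-weighted world center of mass."""
    skel.check_pose(pose)
    st = skel.fk_state(pose.q)
    return _com_from_state(skel, st)


def _com_from_state(skel: Skeleton, st: KinState) -> np.ndarray:
    offs = skel.scales * np.array([s.com_offset_local for s in skel.segments])
    pts = st.o + np.einsum("bij,bj->bi", st.R, offs)
    return skel.segment_masses @ pts / skel.total_mass


def com_positions_trajectory(skel: Skeleton, q_traj: np.ndarray) -> np.ndarray:
    return np.array([_com_from_state(skel, skel.fk_state(q)) for q in q_traj])


def segment_com_points(skel: Skeleton, st: KinState) -> np.ndarray:
    offs = skel.scales * np.array([s.com_offset_local for s in skel.segments])
    return st.o + np.einsum("bij,bj->bi", st.R, offs)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _local_inertia(seg: SegmentSpec, scale: np.ndarray, mass: float) -> np.ndarray:
    """Principal inertia about the segment COM, in the segment frame."""
    d = scale * seg.nominal_length
    if seg.inertia_model == "box":
        return np.diag(mass / 12.0 * np.array([
            d[1] ** 2 + d[2] ** 2,
            d[0] ** 2 + d[2] ** 2,
            d[0] ** 2 + d[1] ** 2,
        ]))
    # cylinder with long axis Y
    r = 0.25 * (d[0] + d[2])
    h = d[1]
    it = mass * (3 * r ** 2 + h ** 2) / 12.0
    return np.diag([it, 0.5 * mass * r ** 2, it])


def _world_inertias(skel: Skeleton, st: KinState, masses: Optional[np.ndarray] = None) -> np.ndarray:
    masses = skel.segment_masses if masses is None else masses
    out = np.zeros((skel.n_segments, 3, 3))
    for b, seg in enumerate(skel.segments):
        Il = _local_inertia(seg, skel.scales[b], masses[b])
        out[b] = st.R[b] @ Il @ st.R[b].T
    return out


def mass_matrix(skel: Skeleton, pose: Pose) -> np.ndarray:
    """Generalized mass matrix assembled as sum of J^T (spatial inertia) J."""
    skel.check_pose(pose)
    st = skel.fk_state(pose.q)
    return _mass_matrix_from_state(skel, st)


def _mass_matrix_from_state(skel: Skeleton, st: KinState,
                            masses: Optional[np.ndarray] = None) -> np.ndarray:
    masses = skel.segment_masses if masses is None else masses
    coms = segment_com_points(skel, st)
    seg_idx = np.arange(skel.n_segments)
    Jv = st.point_jacobian_q(coms, seg_idx)       # (B,3,nq)
    Jw = st.angular_jacobian(seg_idx)             # (B,3,nq)
    Iw = _world_inertias(skel, st, masses)
    M = np.zeros((skel.nq, skel.nq))
    for b in range(skel.n_segments):
        M += masses[b] * Jv[b].T @ Jv[b]
        M += Jw[b].T @ Iw[b] @ Jw[b]
    return 0.5 * (M + M.T)


@dataclass
class VelState:
    """Per-segment velocity/acceleration quantities from the recursion."""
    omega: np.ndarray      # (B,3)
    omega_dot: np.ndarray  # (B,3)
    a_com: np.ndarray      # (B,3) COM linear accelerations
    v_com: np.ndarray      # (B,3)


def _vel_acc_recursion(skel: Skeleton, st: KinState, qdot: np.ndarray,
                       qddot: np.ndarray) -> VelState:
    nseg = skel.n_segments
    omega = np.zeros((nseg, 3))
    omega_dot = np.zeros((nseg, 3))
    v_o = np.zeros((nseg, 3))
    a_o = np.zeros((nseg, 3))
    for ji, j in enumerate(skel.joints):
        sl = skel._joint_qslice[ji]
        ci = skel._seg_index[j.child_segment]
        if j.type == "free6":
            w_p = np.zeros(3)
            wd_p = np.zeros(3)
            v_j = qdot[sl.start:sl.start + 3].copy()
            a_j = qddot[sl.start:sl.start + 3].copy()
            rot_start = sl.start + 3
            ndof_rot = 3
        else:
            pi = skel._seg_index[j.parent_segment]
            w_p = omega[pi]
            wd_p = omega_dot[pi]
            r = st.R[pi] @ (skel.scales[pi] * j.parent_offset_local)
            v_j = v_o[pi] + _cross3(w_p, r)
            a_j = a_o[pi] + _cross3(wd_p, r) + _cross3(w_p, _cross3(w_p, r))
            rot_start = sl.start
            ndof_rot = j.dof
        w_c = w_p.copy()
        wd_c = wd_p.copy()
        w_pre = w_p.copy()
        for k in range(rot_start, rot_start + ndof_rot):
            axis = st.dof_axis[k]
            axis_dot = _cross3(w_pre, axis)
            w_c = w_c + axis * qdot[k]
            wd_c = wd_c + axis_dot * qdot[k] + axis * qddot[k]
            w_pre = w_pre + axis * qdot[k]
        rc = st.R[ci] @ (skel.scales[ci] * j.child_offset_local)
        omega[ci] = w_c
        omega_dot[ci] = wd_c
        v_o[ci] = v_j - _cross3(w_c, rc)
        a_o[ci] = a_j - _cross3(wd_c, rc) - _cross3(w_c, _cross3(w_c, rc))
    # COM kinematics
    offs = skel.scales * np.array([s.com_offset_local for s in skel.segments])
    rcm = np.einsum("bij,bj->bi", st.R, offs)
    v_com = v_o + np.cross(omega, rcm)
    a_com = a_o + np.cross(omega_dot, rcm) + np.cross(omega, np.cross(omega, rcm))
    return VelState(omega, omega_dot, a_com, v_com)


def bias_force(skel: Skeleton, q: np.ndarray, qdot: np.ndarray,
               masses: Optional[np.ndarray] = None) -> np.ndarray:
    """Coriolis/centrifugal plus gravity generalized forces (qddot = 0)."""
    st = skel.fk_state(q)
    return _bias_from_state(skel, st, qdot, masses)


def _bias_from_state(skel: Skeleton, st: KinState, qdot: np.ndarray,
                     masses: Optional[np.ndarray] = None) -> np.ndarray:
    masses = skel.segment_masses if masses is None else masses
    vs = _vel_acc_recursion(skel, st, qdot, np.zeros(skel.nq))
    coms = segment_com_points(skel, st)
    seg_idx = np.arange(skel.n_segments)
    Jv = st.point_jacobian_q(coms, seg_idx)
    Jw = st.angular_jacobian(seg_idx)
    Iw = _world_inertias(skel, st, masses)
    tau = np.zeros(skel.nq)
    g = skel.gravity
    for b in range(skel.n_segments):
        F = masses[b] * (vs.a_com[b] - g)
        T = Iw[b] @ vs.omega_dot[b] + np.cross(vs.omega[b], Iw[b] @ vs.omega[b])
        tau += Jv[b].T @ F + Jw[b].T @ T
    return tau


@dataclass
class ExternalWrench:
    """Force + free couple applied to a segment at a world point."""
    segment: str
    force: np.ndarray
    torque: np.ndarray = field(default_factory=lambda: np.zeros(3))
    point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.force = np.asarray(self.force, float)
        self.torque = np.asarray(self.torque, float)
        self.point = np.asarray(self.point, float)


def external_generalized_forces(skel: Skeleton, st: KinState,
                                wrenches: Sequence[ExternalWrench]) -> np.ndarray:
    tau = np.zeros(skel.nq)
    for w in wrenches:
        b = skel.segment_index(w.segment)
        Jp = st.point_jacobian_q(w.point[np.newaxis], np.array([b]))[0]
        Jw = st.angular_jacobian(np.array([b]))[0]
        tau += Jp.T @ w.force + Jw.T @ w.torque
    return tau


def inverse_dynamics(skel: Skeleton, pose: Pose,
                     external_wrenches: Sequence[ExternalWrench] = (),
                     masses: Optional[np.ndarray] = None) -> np.ndarray:
    """Generalized forces tau with M qddot + bias = tau + J^T f_ext.

    The six entries for the root free joint are the residual wrench; the
    remaining entries are net joint torques.
    """
    skel.check_pose(pose, need_derivatives=True)
    st = skel.fk_state(pose.q)
    M = _mass_matrix_from_state(skel, st, masses)
    b = _bias_from_state(skel, st, pose.qdot, masses)
    tau = M @ pose.qddot + b
    if external_wrenches:
        tau -= external_generalized_forces(skel, st, external_wrenches)
    return tau


def forward_dynamics(skel: Skeleton, q: np.ndarray, qdot: np.ndarray,
                     tau: np.ndarray,
                     external_wrenches: Sequence[ExternalWrench] = (),
                     masses: Optional[np.ndarray] = None) -> np.ndarray:
    """qddot = M^-1 (tau + J^T f_ext - bias); inverse of inverse_dynamics."""
    st = skel.fk_state(q)
    M = _mass_matrix_from_state(skel, st, masses)
    rhs = tau - _bias_from_state(skel, st, qdot, masses)
    if external_wrenches:
        rhs = rhs + external_generalized_forces(skel, st, external_wrenches)
    return np.linalg.solve(M, rhs)


def root_dynamics(skel: Skeleton, st: KinState, qdot: np.ndarray,
                  qddot: np.ndarray,
                  external_wrenches: Sequence[ExternalWrench] = (),
                  masses: Optional[np.ndarray] = None
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fast path for the root rows of inverse dynamics.

    Returns (tau6, M66, E): the first six generalized forces (the residual
    wrench), the 6x6 root block of the mass matrix, and the 3x3 matrix whose
    columns are the world axes of the root Euler rates.  Equivalent to the
    corresponding pieces of inverse_dynamics/mass_matrix but assembled by
    direct Newton-Euler sums, O(bodies) instead of O(bodies x nq^2).
    """
    masses = skel.segment_masses if masses is None else masses
    vs = _vel_acc_recursion(skel, st, qdot, qddot)
    Iw = _world_inertias(skel, st, masses)
    coms = segment_com_points(skel, st)
    o_root = st.dof_point[3]  # root rotation axes pass through the root origin
    E = st.dof_axis[3:6].T
    g = skel.gravity

    F = masses[:, None] * (vs.a_com - g)
    T3 = np.einsum("bij,bj->bi", Iw, vs.omega_dot) + np.cross(
        vs.omega, np.einsum("bij,bj->bi", Iw, vs.omega))
    F_tot = F.sum(axis=0)
    moment = (np.cross(coms - o_root, F) + T3).sum(axis=0)
    for w in external_wrenches:
        F_tot -= w.force
        moment -= _cross3(w.point - o_root, w.force) + w.torque
    tau6 = np.concatenate([F_tot, E.T @ moment])

    M66 = np.zeros((6, 6))
    r = coms - o_root
    # Jv6 per body: [I | w_k x (c - o_root)]; Jw6 = [0 | E] for every body
    A_all = np.cross(E.T[None, :, :], r[:, None, :]).transpose(0, 2, 1)
    M66[:3, :3] = masses.sum() * np.eye(3)
    M66[:3, 3:] = np.einsum("b,bij->ij", masses, A_all)
    M66[3:, :3] = M66[:3, 3:].T
    M66[3:, 3:] = (np.einsum("b,bki,bkj->ij", masses, A_all, A_all)
                   + E.T @ Iw.sum(axis=0) @ E)
    return tau6, 0.5 * (M66 + M66.T), E


def root_wrench_world(skel: Skeleton, st: KinState, tau_root6: np.ndarray
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Convert the root rows of a generalized force vector into a world-frame
    (force, moment-about-root-origin) pair."""
    force = tau_root6[:3]
    E = st.dof_axis[3:6].T  # columns are world axes of the root Euler rates
    moment = np.linalg.solve(E.T, tau_root6[3:6])
    return force, moment


def kinetic_energy(skel: Skeleton, pose: Pose) -> float:
    """0.5 qdot^T M qdot; cross-checkable against per-body energies."""
    skel.check_pose(pose)
    if pose.qdot is None:
        raise SkeletonError("pose must carry qdot")
    M = mass_matrix(skel, pose)
    return 0.5 * float(pose.qdot @ M @ pose.qdot)


def potential_energy(skel: Skeleton, pose: Pose) -> float:
    c = com_position(skel, pose)
    return -skel.total_mass * float(skel.gravity @ c)


def skeleton_height(skel: Skeleton, q: Optional[np.ndarray] = None) -> float:
    """Standing height estimate: vertical extent of the marker cloud plus the
    scaled foot sole drop, at the given (default zero) pose."""
    if q is None:
        q = np.zeros(skel.nq)
    st = skel.fk_state(q)
    X = st.marker_positions()
    pts = np.vstack([X, st.o]) if len(X) else st.o
    return float(pts[:, 1].max() - pts[:, 1].min())
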