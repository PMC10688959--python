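"""Synthetic walking-trial generator with exact ground truth.

Produces dynamically consistent marker + ground-reaction-force data from a
known scaled skeleton: joint trajectories are smooth periodic profiles; the
pelvis height is slaved to foot-ground contact; and the external wrench
required to make the motion dynamically consistent is computed per frame by
inverse dynamics and assigned to the stance foot (split smoothly between feet
in double support, with center of pressure under the foot and the remaining
couple recorded as plate free torque).  The root residual wrench of the
generated trial evaluated at the ground truth is therefore zero up to
round-off, mirroring a simulated motion whose residuals vanish.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import models
from .io import FootAssignment, ForcePlate, GrfTrial, MarkerTrial, write_grf_mot, write_trc
from .dynamics_fit import finite_difference_derivatives, residual_metrics
from .skeleton import (
    ExternalWrench,
    Pose,
    Skeleton,
    external_generalized_forces,
    inverse_dynamics,
    root_wrench_world,
)

CONSISTENCY_LIMIT_PCT = 0.1  # generated trials must beat this normalized residual


@dataclass
class NoiseConfig:
    marker_sigma: float = 0.0015       # i.i.d. Gaussian, meters
    anatomical_perturbation: float = 0.005  # placement error bound, meters
    tracking_perturbation: float = 0.02
    occlusion_rate: float = 0.0
    soft_tissue_amplitude: float = 0.0  # sinusoidal artifact on leg tracking markers
    soft_tissue_frequency: float = 4.0  # Hz


@dataclass
class GaitConfig:
    duration: float = 5.0
    cadence: float = 1.8          # steps per second
    frame_rate: float = 100.0
    hip_flexion_amp: float = 0.30
    knee_amp: float = 0.45
    ankle_amp: float = 0.12
    arm_swing_amp: float = 0.15
    pelvis_sway: float = 0.02
    contact_softness: float = 0.01  # softmin width for pelvis height, m
    weight_window: float = 0.03     # clearance range sharing load, m


@dataclass
class SyntheticTrial:
    skeleton: Skeleton            # ground-truth scaled/registered skeleton
    q: np.ndarray                 # (T, nq) ground-truth coordinates
    markers: MarkerTrial
    grf: GrfTrial
    assignment: FootAssignment
    joint_torques: np.ndarray     # (T, nq) generalized forces at truth
    seed: int
    noise: NoiseConfig
    gait: GaitConfig
    residual_force_pct: float
    residual_torque_pct: float

    @property
    def frame_rate(self) -> float:
        return self.gait.frame_rate

    def save(self, outdir):
        import os
        os.makedirs(outdir, exist_ok=True)
        self.skeleton.save(os.path.join(outdir, "skeleton_truth.json"))
        write_trc(self.markers, os.path.join(outdir, "markers.trc"))
        write_grf_mot(self.grf, os.path.join(outdir, "grf.mot"))
        truth = {
            "seed": self.seed,
            "q": self.q.tolist(),
            "joint_torques": self.joint_torques.tolist(),
            "frame_rate": self.gait.frame_rate,
            "residual_force_pct": self.residual_force_pct,
            "residual_torque_pct": self.residual_torque_pct,
            "noise": asdict(self.noise),
            "gait": asdict(self.gait),
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh)


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def generate_subject(
    seed: int,
    scale_spread: float = 0.1,
    mass_spread: float = 0.1,
    axis_scale_jitter: float = 0.01,
    noise: Optional[NoiseConfig] = None,
    base_mass: float = 75.0,
) -> Skeleton:
    """Draw a ground-truth subject: scales around 1 with the given spread
    (mostly uniform per segment with small per-axis jitter), masses from the
    nominal fractions times a drawn total mass, and marker offsets perturbed
    within the anatomical/tracking placement bounds."""
    rng = np.random.default_rng(seed)
    noise = noise or NoiseConfig()
    skel = models.default_gait_skeleton(total_mass=base_mass)
    nseg = skel.n_segments
    uni = np.clip(1.0 + scale_spread * rng.standard_normal(nseg), 0.7, 1.4)
    jitter = 1.0 + axis_scale_jitter * rng.standard_normal((nseg, 3))
    skel.scales = uni[:, None] * np.clip(jitter, 0.9, 1.1)
    total = base_mass * float(np.clip(1.0 + mass_spread * rng.standard_normal(), 0.6, 1.5))
    skel.segment_masses = np.array(
        [s.nominal_mass_fraction for s in skel.segments]) * total
    offs = skel.marker_offsets()
    for i, m in enumerate(skel.markers):
        bound = (noise.anatomical_perturbation if m.anatomical
                 else noise.tracking_perturbation)
        d = rng.standard_normal(3)
        d *= rng.uniform(0, bound) / max(np.linalg.norm(d), 1e-12)
        offs[i] = offs[i] + d
    skel.set_marker_offsets(offs)
    return skel


# ---------------------------------------------------------------------------
# Gait generation
# ---------------------------------------------------------------------------

def _leg_profile(phase: np.ndarray, cfg: GaitConfig) -> Dict[str, np.ndarray]:
    """Smooth periodic joint-angle profiles for one leg; phase in radians."""
    hip_z = cfg.hip_flexion_amp * np.sin(phase)
    hip_x = 0.04 * np.sin(phase + 0.5)
    hip_y = 0.03 * np.sin(phase + 1.0)
    # knee flexes (negative, see axis convention) mostly during swing
    knee = -cfg.knee_amp * (0.5 - 0.5 * np.cos(phase - 0.7)) ** 2 - 0.03
    ankle = cfg.ankle_amp * np.sin(phase + 2.2) * 0.5
    return {"hip_x": hip_x, "hip_y": hip_y, "hip_z": hip_z,
            "knee": knee, "ankle": ankle}


def _foot_clearances(skel: Skeleton, q: np.ndarray) -> np.ndarray:
    """(T, 2) sole heights of (foot_r, foot_l) above the ground plane y=0."""
    idx = [skel.segment_index(f) for f in models.FOOT_SEGMENTS]
    drops = [models.foot_sole_drop(skel, f) for f in models.FOOT_SEGMENTS]
    out = np.zeros((len(q), 2))
    for t in range(len(q)):
        st = skel.fk_state(q[t])
        out[t] = [st.o[idx[k], 1] - drops[k] for k in range(2)]
    return out


def generate_gait(
    skel: Skeleton,
    gait: Optional[GaitConfig] = None,
) -> Tuple[np.ndarray, GrfTrial, FootAssignment, np.ndarray]:
    """Generate a walking-in-place trial: ground-truth coordinates, the
    dynamically consistent GRF assigned to the feet, the true plate-to-foot
    assignment, and the ground-truth generalized forces (joint torques)."""
    cfg = gait or GaitConfig()
    fr = cfg.frame_rate
    dt = 1.0 / fr
    T = int(round(cfg.duration * fr))
    t = np.arange(T) * dt
    stride = cfg.cadence / 2.0  # full gait cycles per second
    phase_r = 2 * np.pi * stride * t
    phase_l = phase_r + np.pi

    q = np.zeros((T, skel.nq))
    right = _leg_profile(phase_r, cfg)
    left = _leg_profile(phase_l, cfg)
    for side, prof in (("r", right), ("l", left)):
        hip = skel.joint_qslice(f"hip_{side}")
        q[:, hip.start + 0] = prof["hip_x"] * (1 if side == "r" else -1)
        q[:, hip.start + 1] = prof["hip_y"] * (1 if side == "r" else -1)
        q[:, hip.start + 2] = prof["hip_z"]
        q[:, skel.joint_qslice(f"knee_{side}").start] = prof["knee"]
        q[:, skel.joint_qslice(f"ankle_{side}").start] = prof["ankle"]
        sh = skel.joint_qslice(f"shoulder_{side}")
        swing = -cfg.arm_swing_amp * np.sin(phase_r if side == "l" else phase_l)
        q[:, sh.start + 2] = swing
        q[:, skel.joint_qslice(f"elbow_{side}").start] = -0.35 + 0.1 * swing
    lum = skel.joint_qslice("lumbar")
    q[:, lum.start + 1] = 0.05 * np.sin(phase_r)   # counter-rotation
    q[:, lum.start + 2] = -0.05 + 0.02 * np.sin(2 * phase_r)
    neck = skel.joint_qslice("neck")
    q[:, neck.start + 0] = 0.04 * np.sin(phase_r + 0.9)
    q[:, neck.start + 1] = -0.06 * np.sin(phase_r)   # gaze stabilization
    q[:, neck.start + 2] = 0.03 + 0.03 * np.sin(2 * phase_r + 0.4)
    # root pose: lateral sway toward the stance side, small yaw/roll
    q[:, 0] = 0.015 * np.sin(2 * phase_r + 1.0)
    q[:, 2] = cfg.pelvis_sway * np.sin(phase_r + np.pi / 2)
    q[:, 3] = 0.02 * np.sin(phase_r)
    q[:, 4] = 0.04 * np.sin(phase_r + 0.3)
    q[:, 5] = -0.03 + 0.015 * np.sin(2 * phase_r)

    # pelvis height: keep the lower foot in soft contact with the ground
    q[:, 1] = models.standing_pelvis_height(skel)
    clear = _foot_clearances(skel, q)
    sigma = cfg.contact_softness
    softmin = -sigma * np.log(np.sum(np.exp(-clear / sigma), axis=1))
    q[:, 1] -= softmin

    clear = _foot_clearances(skel, q)
    w_raw = np.maximum(0.0, 1.0 - clear / cfg.weight_window) ** 2
    denom = w_raw.sum(axis=1)
    if np.any(denom <= 0):
        raise RuntimeError("generated gait lost ground contact; adjust GaitConfig")
    w = w_raw / denom[:, None]

    # required external wrench per frame from inverse dynamics (no externals)
    qd, qdd = finite_difference_derivatives(q, dt)
    foot_idx = [skel.segment_index(f) for f in models.FOOT_SEGMENTS]
    forces = np.zeros((T, 2, 3))
    cops = np.zeros((T, 2, 3))
    couples = np.zeros((T, 2, 3))
    torques = np.zeros((T, skel.nq))
    for ti in range(T):
        st = skel.fk_state(q[ti])
        tau = inverse_dynamics(skel, Pose(q[ti], qd[ti], qdd[ti]))
        F_w, M_root = root_wrench_world(skel, st, tau[:6])
        o_root = q[ti, 0:3]
        # never emit a per-plate force below the assignment threshold: shift
        # marginal weight to the other foot so the thresholded assignment
        # still accounts for the full external wrench
        w_t = w[ti].copy()
        fmag = np.linalg.norm(F_w)
        for k in range(2):
            if 0 < w_t[k] * fmag < 12.0:
                w_t[1 - k] += w_t[k]
                w_t[k] = 0.0
        for k in range(2):
            wk = w_t[k]
            ankle = st.o[foot_idx[k]]
            cop = np.array([ankle[0] + 0.03, 0.0, ankle[2]])
            forces[ti, k] = wk * F_w
            cops[ti, k] = cop
            couples[ti, k] = wk * M_root - np.cross(cop - o_root, wk * F_w)
        wrenches = [
            ExternalWrench(models.FOOT_SEGMENTS[k], forces[ti, k],
                           couples[ti, k], cops[ti, k])
            for k in range(2) if np.linalg.norm(forces[ti, k]) > 0
        ]
        torques[ti] = tau - external_generalized_forces(skel, st, wrenches)

    plates = []
    for k, (zlo, zhi) in enumerate(((0.01, 0.8), (-0.8, -0.01))):
        corners = np.array([[-1.0, 0.0, zlo], [1.0, 0.0, zlo],
                            [1.0, 0.0, zhi], [-1.0, 0.0, zhi]])
        plates.append(ForcePlate(forces[:, k], cops[:, k], couples[:, k], corners))
    grf = GrfTrial(plates, fr)
    assignment = FootAssignment([
        [models.FOOT_SEGMENTS[k] if np.linalg.norm(forces[ti, k]) > 10.0 else None
         for k in range(2)]
        for ti in range(T)
    ])
    return q, grf, assignment, torques


# ---------------------------------------------------------------------------
# Marker synthesis
# ---------------------------------------------------------------------------

def synthesize_markers(
    skel: Skeleton,
    q_traj: np.ndarray,
    frame_rate: float,
    noise: Optional[NoiseConfig] = None,
    seed: int = 0,
) -> MarkerTrial:
    """Forward-kinematics marker positions plus Gaussian noise, optional
    sinusoidal soft-tissue artifact on thigh/shank tracking markers, and
    Bernoulli occlusions."""
    noise = noise or NoiseConfig()
    rng = np.random.default_rng(seed)
    T = len(q_traj)
    M = skel.n_markers
    pos = np.zeros((T, M, 3))
    for t in range(T):
        pos[t] = skel.fk_state(q_traj[t]).marker_positions()
    if noise.marker_sigma > 0:
        pos += noise.marker_sigma * rng.standard_normal(pos.shape)
    if noise.soft_tissue_amplitude > 0:
        tt = np.arange(T) / frame_rate
        for mi, m in enumerate(skel.markers):
            if m.anatomical or not m.segment.startswith(("thigh", "shank")):
                continue
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            phase = rng.uniform(0, 2 * np.pi)
            wav = noise.soft_tissue_amplitude * np.sin(
                2 * np.pi * noise.soft_tissue_frequency * tt + phase)
            pos[:, mi] += wav[:, None] * direction[None, :]
    visible = np.ones((T, M), bool)
    if noise.occlusion_rate > 0:
        visible = rng.random((T, M)) >= noise.occlusion_rate
        # never lose a full frame
        for t in range(T):
            if visible[t].sum() < 3:
                visible[t] = True
    out = pos.copy()
    out[~visible] = np.nan
    return MarkerTrial([m.label for m in skel.markers], out, visible, frame_rate)


# ---------------------------------------------------------------------------
# Full trial
# ---------------------------------------------------------------------------

def generate_trial(
    seed: int,
    noise: Optional[NoiseConfig] = None,
    gait: Optional[GaitConfig] = None,
    scale_spread: float = 0.1,
    mass_spread: float = 0.1,
    check_consistency: bool = True,
) -> SyntheticTrial:
    """Generate a complete seeded synthetic walking trial with ground truth.

    Asserts the dynamic-consistency invariant: the normalized residual force
    and torque at the ground truth stay below 0.1%.
    """
    noise = noise or NoiseConfig()
    gait_cfg = gait or GaitConfig()
    skel = generate_subject(seed, scale_spread=scale_spread,
                            mass_spread=mass_spread, noise=noise)
    q, grf, assignment, torques = generate_gait(skel, gait_cfg)
    markers = synthesize_markers(skel, q, gait_cfg.frame_rate, noise, seed=seed + 7919)
    res = residual_metrics(skel, q, grf, assignment, 1.0 / gait_cfg.frame_rate)
    if check_consistency and (
            res.force_normalized_pct > CONSISTENCY_LIMIT_PCT
            or res.torque_normalized_pct > CONSISTENCY_LIMIT_PCT):
        raise RuntimeError(
            f"generated trial violates dynamic consistency: "
            f"{res.force_normalized_pct:.3g}% force, "
            f"{res.torque_normalized_pct:.3g}% torque")
    return SyntheticTrial(skel, q, markers, grf, assignment, torques, seed,
                          noise, gait_cfg, res.force_normalized_pct,
                          res.torque_normalized_pct)
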