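"""Initial guesses for the kinematic fit: functional joint centers and axes,
scale initialization, and plain per-frame inverse kinematics.

The closed-form center-of-rotation estimate follows the Gamage-Lasenby
linear least-squares construction in a parent-anchored frame; the sphere and
axis refinements then operate directly on world-frame marker clouds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .io import MarkerTrial
from .skeleton import KinState, Pose, Skeleton, attached_point_jacobians

MIN_COMMON_FRAMES = 10


# ---------------------------------------------------------------------------
# Rigid alignment
# ---------------------------------------------------------------------------

def rigid_align(A: np.ndarray, B: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Kabsch: rotation R and translation t minimizing ||R A + t - B||."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, cb - R @ ca


# ---------------------------------------------------------------------------
# Fit containers
# ---------------------------------------------------------------------------

@dataclass
class JointCenterFit:
    joint: str
    centers: np.ndarray            # (T, 3) world
    radii: np.ndarray              # per child-cluster marker
    rms_residual: float
    degenerate: bool = False
    frames: Optional[np.ndarray] = None       # frame indices used
    parent_rot: Optional[np.ndarray] = None   # (T, 3, 3) world pose of the
    parent_trans: Optional[np.ndarray] = None  # parent marker cluster


@dataclass
class JointAxisFit:
    joint: str
    centers: np.ndarray   # (T, 3)
    axes: np.ndarray      # (T, 3) unit
    u: np.ndarray
    v: np.ndarray
    rms_residual: float
    succeeded: bool = False
    frames: Optional[np.ndarray] = None


@dataclass
class JointConstraint:
    joint: str
    kind: str                      # "axis" | "point"
    centers: np.ndarray            # (T, 3)
    axes: Optional[np.ndarray] = None  # (T, 3) when kind == "axis"
    frames: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# Closed-form center of rotation
# ---------------------------------------------------------------------------

def closed_form_joint_center(
    parent_markers: np.ndarray,
    child_markers: np.ndarray,
    joint: str = "",
) -> JointCenterFit:
    """Linear least-squares center-of-rotation estimate.

    ``parent_markers``/``child_markers``: (T, Mp, 3) and (T, Mc, 3) world
    trajectories of the marker clusters on the two adjacent segments, with
    NaN rows excluded beforehand.  The child cluster is expressed in a
    parent-anchored frame via per-frame rigid alignment; the fixed pivot is
    solved there and mapped back to world per frame.
    """
    T = parent_markers.shape[0]
    if T < MIN_COMMON_FRAMES:
        raise ValueError(f"need >= {MIN_COMMON_FRAMES} mutually visible frames, got {T}")
    if parent_markers.shape[1] + child_markers.shape[1] < 3:
        raise ValueError("need >= 3 markers on the two adjacent segments")
    ref = parent_markers[0]
    Rts = np.zeros((T, 3, 3))
    tts = np.zeros((T, 3))
    local = np.zeros_like(child_markers)
    for t in range(T):
        # world -> parent-anchored frame (frame 0 of the parent cluster)
        R, tr = rigid_align(parent_markers[t], ref)
        Rts[t] = R
        tts[t] = tr
        local[t] = child_markers[t] @ R.T + tr

    # Gamage-Lasenby: sum_i [Cov_i] c = sum_i b_i
    A = np.zeros((3, 3))
    b = np.zeros(3)
    for i in range(local.shape[1]):
        x = local[:, i, :]
        mx = x.mean(axis=0)
        A += 2.0 * ((x.T @ x) / T - np.outer(mx, mx))
        n2 = np.einsum("tj,tj->t", x, x)
        b += (n2[:, None] * x).mean(axis=0) - n2.mean() * mx
    # degeneracy test: A carries the relative-rotation information; no
    # rotation at all (static/pure translation) leaves A ~ 0 relative to the
    # cluster spread.  A hinge gives a rank-2 A — not degenerate, the
    # min-norm solution picks a point on the (ambiguous) axis.
    spread2 = max(np.mean(np.var(local.reshape(-1, 3), axis=0)), 1e-30)
    eigs = np.linalg.eigvalsh(A)
    degenerate = bool(eigs.max() < 1e-6 * spread2 or not np.all(np.isfinite(eigs)))
    c_local = np.linalg.lstsq(A, b, rcond=1e-3)[0]

    # back to world per frame: x_local = R x_world + t  =>  x_world = R^T (x_local - t)
    centers = np.einsum("tij,tj->ti", Rts.transpose(0, 2, 1), c_local[None, :] - tts)
    radii = np.linalg.norm(local - c_local, axis=2).mean(axis=0)
    res = np.linalg.norm(local - c_local, axis=2) - radii[None, :]
    return JointCenterFit(joint, centers, radii, float(np.sqrt(np.mean(res ** 2))),
                          degenerate=degenerate, parent_rot=Rts, parent_trans=tts)


# ---------------------------------------------------------------------------
# Sphere fit (moving center, constant radii)
# ---------------------------------------------------------------------------

def _sphere_objective(markers: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> float:
    d = np.linalg.norm(markers - centers[:, None, :], axis=2) - radii[None, :]
    return float(np.sum(d ** 2))


def sphere_fit(markers: np.ndarray, init: JointCenterFit,
               max_outer: int = 40, tol: float = 1e-12) -> JointCenterFit:
    """Refine a moving-sphere fit: per-marker constant radius to a per-frame
    center, by alternating exact radius updates with per-frame Gauss-Newton
    center updates.  Monotone in the objective."""
    markers = np.asarray(markers, float)
    T, M, _ = markers.shape
    if T < 2:
        return JointCenterFit(init.joint, init.centers.copy(), init.radii.copy(),
                              init.rms_residual, degenerate=True,
                              parent_rot=init.parent_rot, parent_trans=init.parent_trans)
    c = init.centers.copy()
    r = np.linalg.norm(markers - c[:, None, :], axis=2).mean(axis=0)
    prev = _sphere_objective(markers, c, r)
    init_obj = prev
    for _ in range(max_outer):
        # per-frame center update (Gauss-Newton step on 3 vars)
        for t in range(T):
            diff = markers[t] - c[t]
            dist = np.linalg.norm(diff, axis=1)
            dist[dist < 1e-12] = 1e-12
            res = dist - r
            J = -diff / dist[:, None]
            step, *_ = np.linalg.lstsq(J, -res, rcond=None)
            c_new = c[t] + step
            if _sphere_objective(markers[t:t + 1], c_new[None], r) <= \
               _sphere_objective(markers[t:t + 1], c[t][None], r):
                c[t] = c_new
        r = np.linalg.norm(markers - c[:, None, :], axis=2).mean(axis=0)
        obj = _sphere_objective(markers, c, r)
        if prev - obj < tol * max(1.0, prev):
            prev = obj
            break
        prev = obj
    if prev > init_obj + 1e-12:
        warnings.warn("sphere fit failed to improve; returning initialization")
        return init
    rms = float(np.sqrt(prev / (T * M)))
    return JointCenterFit(init.joint, c, r, rms, degenerate=init.degenerate,
                          parent_rot=init.parent_rot, parent_trans=init.parent_trans)


# ---------------------------------------------------------------------------
# Axis fit
# ---------------------------------------------------------------------------

def _axis_residuals(markers_t: np.ndarray, c: np.ndarray, a_raw: np.ndarray,
                    u: np.ndarray, v: np.ndarray) -> np.ndarray:
    a = a_raw / np.linalg.norm(a_raw)
    d = markers_t - c
    par = d @ a
    perp = np.linalg.norm(d - par[:, None] * a[None, :], axis=1)
    return np.concatenate([par - u, perp - v])


def _axis_residuals_jac(markers_t: np.ndarray, c: np.ndarray, a_raw: np.ndarray,
                        u: np.ndarray, v: np.ndarray
                        ) -> Tuple[np.ndarray, np.ndarray]:
    """Residuals and analytic Jacobian w.r.t. the 6-vector (c, a_raw)."""
    na = np.linalg.norm(a_raw)
    a = a_raw / na
    d = markers_t - c
    par = d @ a
    perp_vec = d - par[:, None] * a[None, :]
    perp = np.linalg.norm(perp_vec, axis=1)
    perp_safe = np.maximum(perp, 1e-12)
    phat = perp_vec / perp_safe[:, None]
    M = len(d)
    r = np.concatenate([par - u, perp - v])
    J = np.zeros((2 * M, 6))
    P = (np.eye(3) - np.outer(a, a)) / na  # d a_hat / d a_raw
    J[:M, 0:3] = -a[None, :]
    J[:M, 3:6] = d @ P.T
    J[M:, 0:3] = -phat
    J[M:, 3:6] = -(par[:, None] * phat) @ P.T
    return r, J


def _estimate_axes_from_rotation(parent_rot: np.ndarray, markers: np.ndarray,
                                 parent_trans: Optional[np.ndarray] = None
                                 ) -> np.ndarray:
    """Initial axis guess: dominant relative-rotation axis of the moving
    (child) cluster in the parent-anchored frame, mapped to world per frame.

    Markers that barely move in the parent frame (the parent's own cluster)
    are excluded automatically; they carry no rotation information."""
    T = markers.shape[0]
    allloc = np.einsum("tij,tkj->tki", parent_rot, markers)
    if parent_trans is not None:
        allloc = allloc + parent_trans[:, None, :]
    var = np.var(allloc, axis=0).sum(axis=1)
    moving = var > max(1e-10, 0.05 * var.max())
    if moving.sum() < 3:
        moving = np.ones(markers.shape[1], bool)
    local = allloc[:, moving, :]
    ref = local[0] - local[0].mean(axis=0)
    axes_local = []
    for t in range(1, T):
        R, _ = rigid_align(ref, local[t] - local[t].mean(axis=0))
        w, V = np.linalg.eig(R)
        k = np.argmin(np.abs(w - 1.0))
        ax = np.real(V[:, k])
        tr = np.clip((np.trace(R) - 1) / 2, -1, 1)
        if np.arccos(tr) > 0.02:
            axes_local.append(ax)
    if not axes_local:
        mean_local = np.array([0.0, 0.0, 1.0])
    else:
        axes_local = np.array(axes_local)
        ref_ax = axes_local[np.argmax(np.abs(axes_local).sum(axis=1))]
        axes_local *= np.sign(axes_local @ ref_ax)[:, None]
        mean_local = axes_local.mean(axis=0)
        mean_local /= np.linalg.norm(mean_local)
    world = np.einsum("tji,j->ti", parent_rot, mean_local)
    return world / np.linalg.norm(world, axis=1, keepdims=True)


def axis_fit(markers: np.ndarray, init: JointCenterFit,
             max_outer: int = 40,
             rms_ratio_threshold: float = 1.5,
             rms_abs_threshold: float = 3e-3,
             angle_threshold_deg: float = 10.0) -> JointAxisFit:
    """Fit a per-frame joint axis and center with per-marker constant
    along-axis and perpendicular distances; success means the fit is nearly
    as good as the sphere fit and the axes are mutually consistent."""
    markers = np.asarray(markers, float)
    T, M, _ = markers.shape
    c = init.centers.copy()
    if init.parent_rot is not None:
        a = _estimate_axes_from_rotation(init.parent_rot, markers, init.parent_trans)
    else:
        a = np.tile(np.array([0.0, 0.0, 1.0]), (T, 1))
    u = np.zeros(M)
    v = np.zeros(M)
    for _ in range(max_outer):
        # canonicalize the along-axis gauge: centers may slide freely along a
        # hinge axis, which would corrupt the cross-frame means
        d = markers - c[:, None, :]
        par = np.einsum("tmi,ti->tm", d, a)
        shift_t = par.mean(axis=1) - par.mean()
        c = c + shift_t[:, None] * a
        d = markers - c[:, None, :]
        par = np.einsum("tmi,ti->tm", d, a)
        perp = np.linalg.norm(d - par[..., None] * a[:, None, :], axis=2)
        u_new, v_new = par.mean(axis=0), perp.mean(axis=0)
        shift = np.abs(u_new - u).max() + np.abs(v_new - v).max()
        u, v = u_new, v_new
        for t in range(T):
            x = np.concatenate([c[t], a[t]])
            lam = 1e-8
            r, J = _axis_residuals_jac(markers[t], x[:3], x[3:], u, v)
            obj = float(r @ r)
            for _ in range(20):
                H = J.T @ J
                step = np.linalg.solve(H + lam * np.eye(6), -(J.T @ r))
                x_new = x + step
                r_new, J_new = _axis_residuals_jac(markers[t], x_new[:3],
                                                   x_new[3:], u, v)
                obj_new = float(r_new @ r_new)
                if obj_new < obj:
                    improve = obj - obj_new
                    x, r, J, obj = x_new, r_new, J_new, obj_new
                    lam = max(lam * 0.3, 1e-10)
                    if improve < 1e-14 + 1e-8 * obj:
                        break
                else:
                    lam *= 10.0
                    if lam > 1e6:
                        break
            c[t] = x[:3]
            a[t] = x[3:] / np.linalg.norm(x[3:])
        if shift < 1e-10:
            break
    res = np.concatenate([_axis_residuals(markers[t], c[t], a[t], u, v) for t in range(T)])
    rms = float(np.sqrt(np.mean(res ** 2)))

    # success rule: competitive with the sphere fit AND consistent axes in the
    # parent-anchored frame
    sphere_rms = max(init.rms_residual, 1e-6)
    if init.parent_rot is not None:
        a_local = np.einsum("tij,tj->ti", init.parent_rot, a)
    else:
        a_local = a
    a_local = a_local * np.sign(a_local @ a_local[0])[:, None]
    mean_ax = a_local.mean(axis=0)
    mean_ax /= np.linalg.norm(mean_ax)
    angles = np.degrees(np.arccos(np.clip(a_local @ mean_ax, -1, 1)))
    succeeded = bool(rms < max(rms_ratio_threshold * sphere_rms, rms_abs_threshold)
                     and float(angles.mean()) < angle_threshold_deg)
    return JointAxisFit(init.joint, c, a, u, v, rms, succeeded=succeeded)


def select_joint_constraint(sphere: JointCenterFit, axis: JointAxisFit) -> JointConstraint:
    """Axis constraint when the (strictly harder) axis fit succeeded,
    otherwise the sphere-fit joint center."""
    if axis.succeeded:
        return JointConstraint(sphere.joint, "axis", axis.centers, axes=axis.axes,
                               frames=sphere.frames)
    return JointConstraint(sphere.joint, "point", sphere.centers, frames=sphere.frames)


# ---------------------------------------------------------------------------
# Per-joint driver
# ---------------------------------------------------------------------------

def fit_joint_constraints(
    skel: Skeleton,
    trial: MarkerTrial,
    max_frames: int = 120,
    min_markers: int = 3,
) -> Dict[str, JointConstraint]:
    """Run closed-form + sphere + axis fitting for every internal joint with
    enough adjacent markers, returning the selected constraint per joint."""
    label_index = {l: i for i, l in enumerate(trial.labels)}
    out: Dict[str, JointConstraint] = {}
    for j in skel.joints:
        if j.type == "free6":
            continue
        par_idx = [label_index[m.label] for m in skel.markers
                   if m.segment == j.parent_segment and m.label in label_index]
        chi_idx = [label_index[m.label] for m in skel.markers
                   if m.segment == j.child_segment and m.label in label_index]
        if len(par_idx) < 3 or len(par_idx) + len(chi_idx) < min_markers or not chi_idx:
            continue
        vis = trial.visible[:, par_idx + chi_idx].all(axis=1)
        frames = np.flatnonzero(vis)
        if len(frames) < MIN_COMMON_FRAMES:
            continue
        if len(frames) > max_frames:
            frames = frames[np.linspace(0, len(frames) - 1, max_frames).astype(int)]
        parent = trial.positions[np.ix_(frames, par_idx)]
        child = trial.positions[np.ix_(frames, chi_idx)]
        try:
            cf = closed_form_joint_center(parent, child, joint=j.name)
        except ValueError:
            continue
        if cf.degenerate:
            continue
        cf.frames = frames
        both = np.concatenate([parent, child], axis=1)
        sph = sphere_fit(both, JointCenterFit(j.name, cf.centers, np.zeros(both.shape[1]),
                                              cf.rms_residual, parent_rot=cf.parent_rot,
                                              parent_trans=cf.parent_trans))
        sph.frames = frames
        ax = axis_fit(both, sph)
        ax.frames = frames
        out[j.name] = select_joint_constraint(sph, ax)
    return out


# ---------------------------------------------------------------------------
# Root pose from Procrustes
# ---------------------------------------------------------------------------

def root_pose_from_markers(skel: Skeleton, trial: MarkerTrial, t: int) -> np.ndarray:
    """Rough root pose for frame t from rigid alignment of the root-segment
    markers at the zero pose onto the measured cloud."""
    root_seg = skel.joints[0].child_segment
    label_index = {l: i for i, l in enumerate(trial.labels)}
    idx_model = [i for i, m in enumerate(skel.markers)
                 if m.segment == root_seg and m.label in label_index]
    q = np.zeros(skel.nq)
    if len(idx_model) < 3:
        return q
    st = skel.fk_state(q)
    X0 = st.marker_positions()[idx_model]
    meas_idx = [label_index[skel.markers[i].label] for i in idx_model]
    vis = trial.visible[t, meas_idx]
    if vis.sum() < 3:
        return q
    R, tr = rigid_align(X0[vis], trial.positions[t, np.array(meas_idx)[vis]])
    # R = Rx(a) Ry(b) Rz(c): recover intrinsic XYZ angles
    b = np.arcsin(np.clip(R[0, 2], -1, 1))
    a = np.arctan2(-R[1, 2], R[2, 2])
    cang = np.arctan2(-R[0, 1], R[0, 0])
    q[3:6] = [a, b, cang]
    q[0:3] = tr
    return q


# ---------------------------------------------------------------------------
# Scale initialization (marker + joint-constraint fit)
# ---------------------------------------------------------------------------

def initialize_scales(
    skel: Skeleton,
    trial: MarkerTrial,
    constraints: Dict[str, JointConstraint],
    n_frames: int = 20,
    joint_weight: float = 0.25,
    scale_bounds: Tuple[float, float] = (0.5, 2.0),
) -> np.ndarray:
    """Initialize per-segment scales by jointly fitting uniform segment
    scales, sampled-frame poses, and per-axis offsets alpha to the marker data
    and the functional joint centers/axes.  Returns an (nseg, 3) scale array
    (uniform per segment at this stage)."""
    nseg, nq = skel.n_segments, skel.nq
    T = trial.n_frames
    sample = np.linspace(0, T - 1, min(n_frames, T)).astype(int)

    # joint constraint lookup: joint name -> (kind, center at frame, axis at frame)
    con_data = []
    for j_i, j in enumerate(skel.joints):
        if j.name in constraints:
            con = constraints[j.name]
            interp_c = _interp_frames(con.centers, con.frames, T)
            interp_a = (_interp_frames(con.axes, con.frames, T, normalize=True)
                        if con.kind == "axis" else None)
            con_data.append((j_i, con.kind, interp_c, interp_a))
    n_axis = sum(1 for _, kind, _, _ in con_data if kind == "axis")

    q0 = np.vstack([root_pose_from_markers(skel, trial, t) for t in sample])
    x0 = np.concatenate([np.ones(nseg), np.zeros(n_axis), q0.ravel()])
    lo = np.concatenate([np.full(nseg, scale_bounds[0]), np.full(n_axis, -0.3),
                         np.full(q0.size, -np.inf)])
    hi = np.concatenate([np.full(nseg, scale_bounds[1]), np.full(n_axis, 0.3),
                         np.full(q0.size, np.inf)])

    vis = trial.visible[sample]
    meas = trial.positions[sample]
    label_order = [m.label for m in skel.markers]
    tr_idx = [trial.labels.index(l) if l in trial.labels else -1 for l in label_order]

    def unpack(x):
        s = x[:nseg]
        alpha = x[nseg:nseg + n_axis]
        qs = x[nseg + n_axis:].reshape(len(sample), nq)
        return s, alpha, qs

    def residuals_and_jac(x, want_jac):
        s_uni, alpha, qs = unpack(x)
        work = skel.with_scales(np.repeat(s_uni[:, None], 3, axis=1))
        res_blocks, jac_blocks = [], []
        for fi, t in enumerate(sample):
            st = work.fk_state(qs[fi])
            X, Jq, Js = attached_point_jacobians(work, st, work._marker_seg,
                                                 work._marker_offsets)
            rows = []
            for mi, ti in enumerate(tr_idx):
                if ti >= 0 and vis[fi, trial.labels.index(label_order[mi])]:
                    rows.append(mi)
            rows = np.array(rows, int)
            meas_rows = np.array([trial.labels.index(label_order[mi]) for mi in rows])
            r_m = (X[rows] - meas[fi, meas_rows]).ravel()
            res_blocks.append(r_m)

            # joint-constraint residuals
            jposes, jJq, jJs, jrefs = [], [], [], []
            ai = 0
            for (j_i, kind, cen, axs) in con_data:
                jspec = work.joints[j_i]
                pi = work.segment_index(jspec.parent_segment)
                Xj, Jqj, Jsj = attached_point_jacobians(
                    work, st, np.array([pi]), jspec.parent_offset_local[None])
                target = cen[t]
                if kind == "axis":
                    target = target + alpha[ai] * axs[t]
                r_j = joint_weight * (Xj[0] - target)
                res_blocks.append(r_j)
                jposes.append((kind, ai if kind == "axis" else -1, axs[t] if kind == "axis" else None))
                jJq.append(Jqj[0])
                jJs.append(Jsj[0])
                if kind == "axis":
                    ai += 1

            if want_jac:
                nres_m = len(rows) * 3
                ncols = nseg + n_axis + len(sample) * nq
                Jblock = np.zeros((nres_m + 3 * len(con_data), ncols))
                # markers
                Js_uni = Js[rows].reshape(nres_m, nseg, 3).sum(axis=2)
                Jblock[:nres_m, :nseg] = Js_uni
                qcol = nseg + n_axis + fi * nq
                Jblock[:nres_m, qcol:qcol + nq] = Jq[rows].reshape(nres_m, nq)
                # joints
                for k, ((kind, ai_k, ax), Jqj, Jsj) in enumerate(zip(jposes, jJq, jJs)):
                    r0 = nres_m + 3 * k
                    Jblock[r0:r0 + 3, :nseg] = joint_weight * \
                        Jsj.reshape(3, nseg, 3).sum(axis=2)
                    Jblock[r0:r0 + 3, qcol:qcol + nq] = joint_weight * Jqj
                    if kind == "axis":
                        Jblock[r0:r0 + 3, nseg + ai_k] = -joint_weight * ax
                jac_blocks.append(Jblock)
        r = np.concatenate(res_blocks)
        if want_jac:
            return r, np.vstack(jac_blocks)
        return r

    sol = least_squares(
        lambda x: residuals_and_jac(x, False),
        x0,
        jac=lambda x: residuals_and_jac(x, True)[1],
        bounds=(lo, hi), method="trf", max_nfev=60, x_scale="jac",
    )
    s_uni = np.clip(sol.x[:nseg], *scale_bounds)
    return np.repeat(s_uni[:, None], 3, axis=1)


def _interp_frames(values: np.ndarray, frames: Optional[np.ndarray], T: int,
                   normalize: bool = False) -> np.ndarray:
    """Expand per-fitted-frame quantities to all T frames by interpolation."""
    if frames is None:
        frames = np.arange(len(values))
    out = np.column_stack([
        np.interp(np.arange(T), frames, values[:, k]) for k in range(values.shape[1])
    ])
    if normalize:
        out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------

def _ik_frame(skel: Skeleton, meas: np.ndarray, vis_rows: np.ndarray,
              tr_rows: np.ndarray, q0: np.ndarray,
              max_iter: int = 25, tol: float = 1e-8) -> Tuple[np.ndarray, float]:
    """Damped Gauss-Newton IK for one frame over visible markers."""
    q = q0.copy()
    lam = 1e-6

    def cost(qv):
        X = skel.fk_state(qv).marker_positions()
        return X[vis_rows] - meas[tr_rows]

    r = cost(q)
    obj = float(np.sum(r ** 2))
    for _ in range(max_iter):
        st = skel.fk_state(q)
        X = st.marker_positions()
        Jq = st.point_jacobian_q(X[vis_rows], skel._marker_seg[vis_rows])
        J = Jq.reshape(-1, skel.nq)
        g = J.T @ r.ravel()
        H = J.T @ J
        step = np.linalg.solve(H + lam * np.eye(skel.nq), -g)
        r_new = cost(q + step)
        obj_new = float(np.sum(r_new ** 2))
        if obj_new < obj:
            q = q + step
            improve = obj - obj_new
            r, obj = r_new, obj_new
            lam = max(lam * 0.3, 1e-9)
            if improve < tol * max(obj, 1e-12):
                break
        else:
            lam *= 10.0
            if lam > 1e6:
                break
    return q, obj


def ik_solve(
    skel: Skeleton,
    trial: MarkerTrial,
    q_init: Optional[np.ndarray] = None,
    frames: Optional[np.ndarray] = None,
    min_visible: int = 3,
) -> np.ndarray:
    """Per-frame least-squares marker fit with fixed (s, p).

    Frame t is warm-started from frame t-1; the first frame starts from a
    Procrustes root alignment (or the provided initial trajectory).  Frames
    with fewer than ``min_visible`` markers are interpolated from neighbors.
    """
    T = trial.n_frames
    if frames is None:
        frames = np.arange(T)
    label_index = {l: i for i, l in enumerate(trial.labels)}
    model_rows, trial_rows = [], []
    for mi, m in enumerate(skel.markers):
        if m.label in label_index:
            model_rows.append(mi)
            trial_rows.append(label_index[m.label])
    model_rows = np.array(model_rows, int)
    trial_rows = np.array(trial_rows, int)

    q_out = np.zeros((len(frames), skel.nq))
    bad = []
    prev_q = None
    for k, t in enumerate(frames):
        vis = trial.visible[t, trial_rows]
        if vis.sum() < min_visible:
            bad.append(k)
            q_out[k] = prev_q if prev_q is not None else np.zeros(skel.nq)
            continue
        if q_init is not None:
            q0 = q_init[k] if q_init.ndim == 2 else q_init
        elif prev_q is not None:
            q0 = prev_q
        else:
            q0 = root_pose_from_markers(skel, trial, t)
        q, _ = _ik_frame(skel, trial.positions[t], model_rows[vis], trial_rows[vis], q0)
        q_out[k] = q
        prev_q = q
    if bad:
        warnings.warn(f"{len(bad)} frames had <{min_visible} visible markers; interpolated")
        good = np.setdiff1d(np.arange(len(frames)), bad)
        for col in range(skel.nq):
            q_out[bad, col] = np.interp(np.array(bad, float), good.astype(float),
                                        q_out[good, col])
    return q_out
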