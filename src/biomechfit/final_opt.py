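"""Final optimization: tune segment masses and the root trajectory to drive
the residual wrench toward zero while preserving the marker fit.

The residual wrench is linear in the segment masses once the kinematics are
fixed (inertia scales with mass for a fixed geometry), so the mass step is an
exactly-solvable linear least squares with Gaussian priors pulling the mass
distribution toward the nominal fractions and the total toward the COM-fit
estimate.  Mass steps alternate with re-running the linear COM fit (at fixed
total mass) and the iterative angular fit, which re-zeroes the residuals for
the updated inertia.  Objective bookkeeping uses the same negative-log
posterior as the kinematic stage plus a Gaussian residual-load term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import lsq_linear

from .dynamics_fit import (
    ComFitSolution,
    ResidualMetrics,
    finite_difference_derivatives,
    fit_angular,
    fit_com,
    grf_wrenches,
    residual_metrics,
)
from .io import FootAssignment, GrfTrial, MarkerTrial
from .marker_fit import KinematicSolution, Priors, marker_error_metrics, neg_log_map_objective
from .skeleton import (
    Skeleton,
    _bias_from_state,
    _com_from_state,
    _local_inertia,
    _mass_matrix_from_state,
    _vel_acc_recursion,
    _world_inertias,
    external_generalized_forces,
    segment_com_points,
)

MIN_SEGMENT_MASS = 0.5  # kg


@dataclass
class FinalFitConfig:
    mass_iterations: int = 2
    total_mass_sigma_rel: float = 0.01   # prior tightness on the COM-fit total
    fraction_sigma_rel: float = 1.5      # prior tightness per segment fraction
    angular_tol: float = 1e-6
    angular_max_iter: int = 50
    frame_stride: int = 1                # subsample residual rows for speed


@dataclass
class DynamicSolution:
    q: np.ndarray
    scales: np.ndarray
    marker_offsets: np.ndarray
    segment_masses: np.ndarray
    marker_rmse: float
    marker_max_error: float
    residuals: ResidualMetrics
    joint_torques: np.ndarray    # (T, nq) generalized forces
    objective: float = np.nan
    converged: bool = True
    angular_iterations: int = 0

    @property
    def total_mass(self) -> float:
        return float(self.segment_masses.sum())

    def report_dict(self) -> dict:
        d = {
            "marker_rmse_m": float(self.marker_rmse),
            "marker_max_error_m": float(self.marker_max_error),
            "total_mass_kg": self.total_mass,
            "segment_masses_kg": self.segment_masses.tolist(),
            "scales": self.scales.tolist(),
            "objective": float(self.objective),
            "converged": bool(self.converged),
            "angular_iterations": int(self.angular_iterations),
        }
        d.update(self.residuals.report_dict())
        return d


# ---------------------------------------------------------------------------
# Residual basis (linear in segment masses)
# ---------------------------------------------------------------------------

def _unit_mass_residual_basis(skel: Skeleton, q_traj: np.ndarray, dt: float,
                              grf: GrfTrial, assignment: FootAssignment,
                              frames: np.ndarray):
    """Per frame: (B, 6) unit-mass contributions of each segment to the root
    residual rows, and the (6,) external generalized force at the root."""
    qd, qdd = finite_difference_derivatives(q_traj, dt)
    nseg = skel.n_segments
    basis = np.zeros((len(frames), nseg, 6))
    ext = np.zeros((len(frames), 6))
    unit = np.ones(nseg)
    for k, t in enumerate(frames):
        st = skel.fk_state(q_traj[t])
        vs = _vel_acc_recursion(skel, st, qd[t], qdd[t])
        coms = segment_com_points(skel, st)
        Jv = st.point_jacobian_q(coms, np.arange(nseg))
        Jw = st.angular_jacobian(np.arange(nseg))
        Iw_unit = _world_inertias(skel, st, unit)
        for b in range(nseg):
            F = vs.a_com[b] - skel.gravity
            Tq = Iw_unit[b] @ vs.omega_dot[b] + np.cross(vs.omega[b],
                                                         Iw_unit[b] @ vs.omega[b])
            basis[k, b] = Jv[b][:, :6].T @ F + Jw[b][:, :6].T @ Tq
        tau_ext = external_generalized_forces(
            skel, st, grf_wrenches(grf, assignment, t))
        ext[k] = tau_ext[:6]
    return basis, ext


def _mass_step(skel: Skeleton, q_traj: np.ndarray, dt: float, grf: GrfTrial,
               assignment: FootAssignment, masses0: np.ndarray,
               total_target: float, priors: Priors,
               cfg: FinalFitConfig) -> np.ndarray:
    """Linear least-squares mass re-estimation with Gaussian priors."""
    T = len(q_traj)
    frames = np.arange(1, T - 1, cfg.frame_stride)
    basis, ext = _unit_mass_residual_basis(skel, q_traj, dt, grf, assignment, frames)
    nseg = skel.n_segments
    w = np.concatenate([
        np.full(3, 1.0 / priors.residual_force_sigma),
        np.full(3, 1.0 / priors.residual_torque_sigma),
    ])
    A = (basis.transpose(0, 2, 1) * w[None, :, None]).reshape(-1, nseg)
    y = (ext * w[None, :]).reshape(-1)
    fracs = np.array([s.nominal_mass_fraction for s in skel.segments])
    prior_m = fracs * total_target
    sig_frac = cfg.fraction_sigma_rel * prior_m
    rows_prior = np.diag(1.0 / sig_frac)
    y_prior = prior_m / sig_frac
    sig_tot = cfg.total_mass_sigma_rel * total_target
    row_tot = np.ones((1, nseg)) / sig_tot
    y_tot = np.array([total_target / sig_tot])
    A_full = np.vstack([A, rows_prior, row_tot])
    y_full = np.concatenate([y, y_prior, y_tot])
    sol = lsq_linear(A_full, y_full, bounds=(MIN_SEGMENT_MASS, np.inf))
    m = sol.x
    if np.any(m <= MIN_SEGMENT_MASS + 1e-12):
        warnings.warn("segment mass clamped at the lower bound")
    return m


# ---------------------------------------------------------------------------
# Objective (negative log posterior incl. residual term)
# ---------------------------------------------------------------------------

def final_objective(
    skel_template: Skeleton,
    q_traj: np.ndarray,
    scales: np.ndarray,
    offsets: np.ndarray,
    masses: np.ndarray,
    trial: MarkerTrial,
    grf: GrfTrial,
    assignment: FootAssignment,
    priors: Priors,
    frames: Optional[np.ndarray] = None,
) -> float:
    """Negative log of the full posterior: marker data term, scale and
    marker-placement priors, and the Gaussian residual-load term."""
    T = len(q_traj)
    if frames is None:
        frames = np.arange(T)
    value = neg_log_map_objective(skel_template, q_traj[frames], scales, offsets,
                                  trial, frames, priors)
    work = skel_template.with_scales(scales)
    work.set_marker_offsets(offsets)
    res = residual_metrics(work, q_traj, grf, assignment, trial.dt, masses=masses)
    f = res.force_trajectory[1:-1]
    m = res.torque_trajectory[1:-1]
    value += 0.5 * float(np.sum((f / priors.residual_force_sigma) ** 2))
    value += 0.5 * float(np.sum((m / priors.residual_torque_sigma) ** 2))
    return value


# ---------------------------------------------------------------------------
# Final fit
# ---------------------------------------------------------------------------

def final_fit(
    skel_template: Skeleton,
    kin: KinematicSolution,
    q_dyn: np.ndarray,
    com_fit: ComFitSolution,
    trial: MarkerTrial,
    grf: GrfTrial,
    assignment: FootAssignment,
    priors: Priors,
    config: Optional[FinalFitConfig] = None,
) -> DynamicSolution:
    """Tune segment masses and the root trajectory for dynamic consistency.

    ``kin`` supplies the optimized scales and marker registrations; ``q_dyn``
    is the smoothed trajectory after the COM and angular initialization fits.
    Alternates the exact linear mass step with COM/angular refits.
    """
    cfg = config or FinalFitConfig()
    dt = trial.dt
    work = skel_template.with_scales(kin.scales)
    work.set_marker_offsets(kin.marker_offsets)

    total = com_fit.mass
    fracs = np.array([s.nominal_mass_fraction for s in work.segments])
    masses = fracs * total
    q = np.array(q_dyn, float, copy=True)
    obj_frames = np.linspace(0, len(q) - 1, min(50, len(q))).astype(int)
    init_state = (q.copy(), masses.copy())
    init_obj = final_objective(skel_template, q, kin.scales, kin.marker_offsets,
                               masses, trial, grf, assignment, priors,
                               frames=obj_frames)

    converged = True
    ang_iters = 0
    for _ in range(cfg.mass_iterations):
        masses = _mass_step(work, q, dt, grf, assignment, masses, total, priors, cfg)
        new_total = float(masses.sum())
        # re-zero the linear dynamics for the updated inertia
        z_hat = np.array([_com_from_state(work, work.fk_state(qt)) for qt in q])
        f_total = sum(p.force for p in grf.plates)
        cf = fit_com(z_hat.reshape(-1, 3), f_total, dt, work.gravity,
                     fixed_mass=new_total)
        from .dynamics_fit import apply_com_to_root
        work.segment_masses = masses
        q = apply_com_to_root(work, q, cf.Z)
        ang = fit_angular(work, q, grf, assignment, dt, masses=masses,
                          tol=cfg.angular_tol, max_iter=cfg.angular_max_iter)
        q = ang.q
        converged = converged and ang.converged
        ang_iters = ang.iterations

    if abs(masses.sum() - com_fit.mass) / com_fit.mass > 0.05:
        warnings.warn("final total mass deviates >5% from the COM-fit estimate")

    obj = final_objective(skel_template, q, kin.scales, kin.marker_offsets, masses,
                          trial, grf, assignment, priors, frames=obj_frames)
    if obj > init_obj:
        # the tuning steps are not strictly monotone in the posterior; never
        # return an iterate worse than the initialization
        warnings.warn("final fit did not improve the posterior; keeping the "
                      "initialization")
        q, masses = init_state
        obj = init_obj
    work.segment_masses = masses
    res = residual_metrics(work, q, grf, assignment, dt, masses=masses)
    torques = joint_torques(work, q, grf, assignment, dt, masses=masses)
    rmse, max_err, _, _ = marker_error_metrics(work, q, trial)
    return DynamicSolution(
        q=q, scales=kin.scales, marker_offsets=kin.marker_offsets,
        segment_masses=masses, marker_rmse=rmse, marker_max_error=max_err,
        residuals=res, joint_torques=torques, objective=float(obj),
        converged=converged, angular_iterations=ang_iters,
    )


def joint_torques(
    skel: Skeleton,
    q_traj: np.ndarray,
    grf: Optional[GrfTrial],
    assignment: Optional[FootAssignment],
    dt: float,
    masses: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Generalized forces from inverse dynamics along the trajectory.

    Root rows carry the residual wrench; the remaining rows are net joint
    torques.  Endpoint frames use one-sided accelerations.
    """
    masses = skel.segment_masses if masses is None else masses
    T = len(q_traj)
    qd, qdd = finite_difference_derivatives(q_traj, dt)
    out = np.zeros((T, skel.nq))
    for t in range(T):
        st = skel.fk_state(q_traj[t])
        M = _mass_matrix_from_state(skel, st, masses)
        bias = _bias_from_state(skel, st, qd[t], masses)
        tau = M @ qdd[t] + bias
        if grf is not None and assignment is not None:
            tau -= external_generalized_forces(
                skel, st, grf_wrenches(grf, assignment, t))
        out[t] = tau
    return out
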