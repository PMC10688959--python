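"""Dynamics fitting: jerk smoothing, the linear center-of-mass/mass fit, the
iteratively re-linearized root-rotation fit, and residual-load metrics.

The COM fit exploits that, with ground reaction forces prescribed, the COM
trajectory under semi-explicit Euler integration is linear in the initial
state and the inverse mass; the angular stage extends the same construction
to the root rotational coordinates by linearizing the effect of COM shifts on
the ground-reaction moment while freezing the mass matrix and Coriolis terms
at the current trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import solveh_banded

from .io import FootAssignment, GrfTrial
from .skeleton import (
    ExternalWrench,
    KinState,
    Skeleton,
    _bias_from_state,
    _com_from_state,
    _mass_matrix_from_state,
    external_generalized_forces,
    root_dynamics,
    root_wrench_world,
    skew,
)

DEFAULT_JERK_WEIGHT = 1e-9  # seconds^6; frame-rate-invariant smoothing strength


# ---------------------------------------------------------------------------
# Jerk smoothing
# ---------------------------------------------------------------------------

def smooth_jerk(q_traj: np.ndarray, dt: float,
                weight: float = DEFAULT_JERK_WEIGHT) -> np.ndarray:
    """Minimize ||q - q_in||^2 + (weight/dt^6) ||D3 q||^2 per coordinate.

    D3 is the third-order finite-difference stencil, so quadratic trajectories
    pass through unchanged.  Solved as a banded SPD system.
    """
    q_traj = np.asarray(q_traj, float)
    T = q_traj.shape[0]
    if T < 4:
        raise ValueError("jerk smoothing needs T >= 4")
    lam = weight / dt ** 6
    D = np.zeros((T - 3, T))
    for i in range(T - 3):
        D[i, i:i + 4] = [-1.0, 3.0, -3.0, 1.0]
    A = np.eye(T) + lam * (D.T @ D)
    # banded representation (bandwidth 3)
    ab = np.zeros((4, T))
    for d in range(4):
        ab[3 - d, d:] = np.diag(A, k=d)
    return solveh_banded(ab, q_traj, lower=False)


def finite_difference_derivatives(q_traj: np.ndarray, dt: float
                                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Central-difference velocities and accelerations (one-sided endpoints)."""
    qd = np.gradient(q_traj, dt, axis=0)
    qdd = np.empty_like(q_traj)
    qdd[1:-1] = (q_traj[2:] - 2 * q_traj[1:-1] + q_traj[:-2]) / dt ** 2
    qdd[0] = qdd[1]
    qdd[-1] = qdd[-2]
    return qd, qdd


# ---------------------------------------------------------------------------
# Linear COM system
# ---------------------------------------------------------------------------

def build_com_system(f_total: np.ndarray, dt: float, g: np.ndarray
                     ) -> Tuple[np.ndarray, np.ndarray]:
    """Assemble (A, b) with A zeta + b = Z for zeta = (z1, zdot1, mu).

    Row block t reproduces the semi-explicit Euler rollout
    zdot_{t+1} = zdot_t + (mu f_t + g) dt;  z_{t+1} = z_t + zdot_{t+1} dt,
    i.e. z_t = z1 + t dt zdot1 + dt^2 sum_{i<t} (t-i)(mu f_i + g).
    """
    f_total = np.asarray(f_total, float)
    T = f_total.shape[0]
    if T < 2:
        raise ValueError("need at least 2 frames")
    A = np.zeros((3 * T, 7))
    b = np.zeros(3 * T)
    # W_t = sum_{i<t}(t-i) f_i via the recursion W_{t+1} = W_t + S_t,
    # S_t = sum_{i<=t} f_i
    Wf = np.zeros(3)
    Sf = np.zeros(3)
    Wg = np.zeros(3)
    Sg = np.zeros(3)
    for t in range(T):
        A[3 * t:3 * t + 3, 0:3] = np.eye(3)
        A[3 * t:3 * t + 3, 3:6] = t * dt * np.eye(3)
        A[3 * t:3 * t + 3, 6] = dt ** 2 * Wf
        b[3 * t:3 * t + 3] = dt ** 2 * Wg
        Sf += f_total[t]
        Sg += g
        Wf += Sf
        Wg += Sg
    return A, b


def com_rollout(zeta: np.ndarray, f_total: np.ndarray, dt: float,
                g: np.ndarray) -> np.ndarray:
    """Step-by-step semi-explicit Euler integration (oracle counterpart of
    build_com_system)."""
    T = f_total.shape[0]
    z = np.zeros((T, 3))
    z[0] = zeta[0:3]
    v = zeta[3:6].copy()
    mu = zeta[6]
    for t in range(1, T):
        v = v + (mu * f_total[t - 1] + g) * dt
        z[t] = z[t - 1] + v * dt
    return z


@dataclass
class ComFitSolution:
    zeta: np.ndarray        # (7,) = (z1, zdot1, mu)
    mass: float
    Z: np.ndarray           # (T, 3) reconstructed COM trajectory
    fit_rmse: float
    degenerate: bool = False

    def report_dict(self) -> dict:
        return {"mass_kg": float(self.mass), "com_fit_rmse_m": float(self.fit_rmse),
                "degenerate": bool(self.degenerate)}


def fit_com(Z_hat: np.ndarray, f_total: np.ndarray, dt: float, g: np.ndarray,
            fallback_mass: float = 75.0,
            fixed_mass: Optional[float] = None) -> ComFitSolution:
    """Least-squares fit of (z1, zdot1, mu) to the observed COM trajectory.

    With ``fixed_mass`` only the initial state is fitted.  A non-positive
    mass estimate (e.g. a flight-only trial where the force column vanishes)
    is degenerate and falls back to ``fallback_mass``.
    """
    Z_hat = np.asarray(Z_hat, float)
    A, b = build_com_system(f_total, dt, g)
    y = Z_hat.ravel() - b
    if fixed_mass is not None:
        mu = 1.0 / fixed_mass
        y2 = y - A[:, 6] * mu
        x, *_ = np.linalg.lstsq(A[:, :6], y2, rcond=None)
        zeta = np.concatenate([x, [mu]])
        degenerate = False
        mass = fixed_mass
    else:
        zeta = np.linalg.pinv(A) @ y
        mu = zeta[6]
        degenerate = not (mu > 1e-6)
        if degenerate:
            warnings.warn(f"COM fit gave non-positive mass (mu={mu:.3g}); "
                          f"falling back to {fallback_mass} kg")
            out = fit_com(Z_hat, f_total, dt, g, fixed_mass=fallback_mass)
            out.degenerate = True
            return out
        mass = 1.0 / mu
    Z = (A @ zeta + b).reshape(-1, 3)
    rmse = float(np.sqrt(np.mean(np.sum((Z - Z_hat) ** 2, axis=1))))
    return ComFitSolution(zeta, float(mass), Z, rmse, degenerate=degenerate)


def apply_com_to_root(skel: Skeleton, q_traj: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Shift the root translation so the model COM tracks Z exactly, keeping
    all other coordinates fixed."""
    out = np.array(q_traj, float, copy=True)
    for t in range(len(out)):
        st = skel.fk_state(out[t])
        out[t, 0:3] += Z[t] - _com_from_state(skel, st)
    return out


# ---------------------------------------------------------------------------
# External wrenches from GRF + assignment
# ---------------------------------------------------------------------------

def grf_wrenches(grf: GrfTrial, assignment: FootAssignment, t: int
                 ) -> List[ExternalWrench]:
    out = []
    for pi, plate in enumerate(grf.plates):
        foot = assignment.assignment[t][pi]
        if foot is None:
            continue
        out.append(ExternalWrench(foot, plate.force[t], plate.torque[t],
                                  plate.cop[t]))
    return out


# ---------------------------------------------------------------------------
# Angular system
# ---------------------------------------------------------------------------

@dataclass
class AngularFitSolution:
    xi: np.ndarray          # (12,) = (z1, zdot1, theta1, thetadot1)
    Xi: np.ndarray          # (T, 6): columns (z, theta)
    q: np.ndarray           # (T, nq) updated trajectory
    iterations: int
    converged: bool

    def report_dict(self) -> dict:
        return {"iterations": int(self.iterations), "converged": bool(self.converged)}


def build_angular_system(
    skel: Skeleton,
    q_ref: np.ndarray,
    grf: GrfTrial,
    assignment: FootAssignment,
    dt: float,
    masses: Optional[np.ndarray] = None,
    return_parts: bool = False,
):
    """Assemble (A_tilde, b_tilde) mapping xi = (z1, zdot1, theta1, thetadot1)
    onto the stacked trajectory Xi = [Z; Theta] (6T vector, Z block first).

    The upper-left quadrant replicates the COM system at fixed mass; the
    upper-right quadrant is zero (the COM does not depend on the root
    rotation); the lower-left quadrant carries the chain-rule sensitivity of
    the root rotation to COM shifts through the ground-reaction moment; the
    offset accumulates the reference rotational accelerations corrected by the
    current inverse-dynamics residual (gravity, applied forces and Coriolis
    terms evaluated at the reference trajectory).
    """
    masses = skel.segment_masses if masses is None else masses
    m_tot = float(np.sum(masses))
    T = len(q_ref)
    g = skel.gravity
    f_total = sum(p.force for p in grf.plates)[:T]

    # kinematic accelerations of the root rotation at the reference
    theta_ref = q_ref[:, 3:6]
    z_ref = np.array([_com_from_state(skel, skel.fk_state(q)) for q in q_ref])
    qd, qdd = finite_difference_derivatives(q_ref, dt)

    K = np.zeros((T, 3, 3))
    tdd_base = np.zeros((T, 3))
    for t in range(T):
        st = skel.fk_state(q_ref[t])
        # the root coordinates are the unactuated ones: with the internal
        # trajectories prescribed, root accelerations respond to root-row
        # generalized forces through the 6x6 root block of M
        tau6, M66, E = root_dynamics(skel, st, qd[t], qdd[t],
                                     grf_wrenches(grf, assignment, t), masses)
        Minv66 = np.linalg.inv(M66)
        K[t] = Minv66[3:6, 3:6] @ E.T @ skew(f_total[t])
        tdd_base[t] = qdd[t, 3:6] - (Minv66 @ tau6)[3:6]
    tdd_base[0] = tdd_base[1]  # no central difference at the first frame

    # z rows: identical to build_com_system at fixed mass
    A_com, b_com = build_com_system(f_total, dt, g)
    bz = (b_com + A_com[:, 6] / m_tot).reshape(T, 3)  # z_t = z1 + t dt zdot1 + bz_t

    At = np.zeros((6 * T, 12))
    bt = np.zeros(6 * T)
    At[:3 * T, 0:6] = A_com[:, 0:6]
    bt[:3 * T] = bz.ravel()

    # theta rows: theta_t = theta1 + t dt thetadot1
    #   + dt^2 sum_{i<t}(t-i)[tdd_base_i + K_i (z_i(xi) - z_ref_i)]
    # with z_i(xi) = z1 + i dt zdot1 + bz_i
    Wz = np.zeros((3, 3))   # sum (t-i) K_i
    Sz = np.zeros((3, 3))
    Wv = np.zeros((3, 3))   # sum (t-i) i dt K_i
    Sv = np.zeros((3, 3))
    Wc = np.zeros(3)        # sum (t-i) [tdd_base_i + K_i (bz_i - z_ref_i)]
    Sc = np.zeros(3)
    for t in range(T):
        r0 = 3 * T + 3 * t
        At[r0:r0 + 3, 6:9] = np.eye(3)
        At[r0:r0 + 3, 9:12] = t * dt * np.eye(3)
        At[r0:r0 + 3, 0:3] = dt ** 2 * Wz
        At[r0:r0 + 3, 3:6] = dt ** 2 * Wv
        bt[r0:r0 + 3] = dt ** 2 * Wc
        ci = tdd_base[t] + K[t] @ (bz[t] - z_ref[t])
        Sz += K[t]
        Sv += t * dt * K[t]
        Sc += ci
        Wz += Sz
        Wv += Sv
        Wc += Sc
    if return_parts:
        return At, bt, (K, tdd_base, bz, z_ref)
    return At, bt


def angular_rollout(xi: np.ndarray, K: np.ndarray, tdd_base: np.ndarray,
                    bz: np.ndarray, z_ref: np.ndarray, dt: float
                    ) -> np.ndarray:
    """Step-by-step semi-explicit rollout of the linearized root dynamics
    (oracle counterpart of build_angular_system's theta block)."""
    T = len(K)
    z1, zd1 = xi[0:3], xi[3:6]
    th = np.zeros((T, 3))
    th[0] = xi[6:9]
    td = xi[9:12].copy()
    for t in range(1, T):
        i = t - 1
        z_i = z1 + i * dt * zd1 + bz[i]
        tdd = tdd_base[i] + K[i] @ (z_i - z_ref[i])
        td = td + tdd * dt
        th[t] = th[t - 1] + td * dt
    return th


def fit_angular(
    skel: Skeleton,
    q_init: np.ndarray,
    grf: GrfTrial,
    assignment: FootAssignment,
    dt: float,
    masses: Optional[np.ndarray] = None,
    com_fit: Optional[ComFitSolution] = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> AngularFitSolution:
    """Iteratively re-linearized least-squares fit of the root trajectory.

    Each outer iteration assembles the linear system at the current
    trajectory, solves for the initial conditions by pseudo-inverse, rolls the
    trajectory out, and rewrites the root translation (COM) and rotation.
    Terminates when the max-norm change of the reconstructed trajectory drops
    below ``tol``.
    """
    masses = skel.segment_masses if masses is None else masses
    T = len(q_init)
    z_hat = np.array([_com_from_state(skel, skel.fk_state(q)) for q in q_init])
    theta_hat = q_init[:, 3:6].copy()
    Xi_hat = np.concatenate([z_hat.ravel(), theta_hat.ravel()])

    q = np.array(q_init, float, copy=True)
    Xi_prev = None
    converged = False
    iterations = 0
    for it in range(max_iter):
        iterations = it + 1
        At, bt = build_angular_system(skel, q, grf, assignment, dt, masses)
        xi, *_ = np.linalg.lstsq(At, Xi_hat - bt, rcond=None)
        Xi = At @ xi + bt
        if Xi_prev is not None and np.max(np.abs(Xi - Xi_prev)) < tol:
            converged = True
            Xi_prev = Xi
            break
        Xi_prev = Xi
        Z = Xi[:3 * T].reshape(T, 3)
        Theta = Xi[3 * T:].reshape(T, 3)
        q[:, 3:6] = Theta
        q = apply_com_to_root(skel, q, Z)
    Z = Xi_prev[:3 * T].reshape(T, 3)
    Theta = Xi_prev[3 * T:].reshape(T, 3)
    q[:, 3:6] = Theta
    q = apply_com_to_root(skel, q, Z)
    out = np.column_stack([Z, Theta])
    if not converged:
        warnings.warn(f"angular fit did not converge in {max_iter} iterations")
    return AngularFitSolution(xi, out, q, iterations, converged)


# ---------------------------------------------------------------------------
# Residual metrics
# ---------------------------------------------------------------------------

@dataclass
class ResidualMetrics:
    force_rms: float            # N
    torque_rms: float           # N*m
    force_normalized_pct: float   # % of peak GRF magnitude
    torque_normalized_pct: float  # % of (peak GRF x mean COM height)
    force_trajectory: np.ndarray  # (T, 3); NaN at excluded endpoint frames
    torque_trajectory: np.ndarray

    def report_dict(self) -> dict:
        return {
            "residual_force_rms_N": float(self.force_rms),
            "residual_torque_rms_Nm": float(self.torque_rms),
            "residual_force_pct": float(self.force_normalized_pct),
            "residual_torque_pct": float(self.torque_normalized_pct),
        }


def residual_metrics(
    skel: Skeleton,
    q_traj: np.ndarray,
    grf: GrfTrial,
    assignment: FootAssignment,
    dt: float,
    masses: Optional[np.ndarray] = None,
) -> ResidualMetrics:
    """Root residual wrench statistics from inverse dynamics.

    Accelerations come from central differences of ``q_traj``; the two
    endpoint frames use one-sided differences and are excluded from the RMS.
    """
    masses = skel.segment_masses if masses is None else masses
    T = len(q_traj)
    qd, qdd = finite_difference_derivatives(q_traj, dt)
    f_res = np.full((T, 3), np.nan)
    m_res = np.full((T, 3), np.nan)
    com_heights = np.zeros(T)
    for t in range(T):
        st = skel.fk_state(q_traj[t])
        com_heights[t] = _com_from_state(skel, st)[1]
        if t == 0 or t == T - 1:
            continue
        tau6, _, _ = root_dynamics(skel, st, qd[t], qdd[t],
                                   grf_wrenches(grf, assignment, t), masses)
        f_res[t], m_res[t] = root_wrench_world(skel, st, tau6)
    interior = slice(1, T - 1)
    fmag = np.linalg.norm(f_res[interior], axis=1)
    mmag = np.linalg.norm(m_res[interior], axis=1)
    force_rms = float(np.sqrt(np.mean(fmag ** 2)))
    torque_rms = float(np.sqrt(np.mean(mmag ** 2)))
    peak_grf = float(np.linalg.norm(sum(p.force for p in grf.plates), axis=1).max())
    mean_h = float(np.mean(com_heights))
    return ResidualMetrics(
        force_rms, torque_rms,
        100.0 * force_rms / max(peak_grf, 1e-9),
        100.0 * torque_rms / max(peak_grf * mean_h, 1e-9),
        f_res, m_res,
    )
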