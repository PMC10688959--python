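import numpy as np
import pytest

from biomechfit.kinematics_init import (
    JointCenterFit,
    axis_fit,
    closed_form_joint_center,
    fit_joint_constraints,
    ik_solve,
    initialize_scales,
    rigid_align,
    select_joint_constraint,
    sphere_fit,
)
from biomechfit.kinematics_init import _sphere_objective
from biomechfit.marker_fit import marker_error_metrics
from biomechfit.skeleton import axis_angle, euler_xyz
from biomechfit.synthetic import NoiseConfig, synthesize_markers

AXIS = np.array([0.0, 0.0, 1.0])
CENTER = np.array([0.1, 0.9, 0.0])


def _clusters(hinge, noise, seed, T=80, soft=0.0):
    """Two marker clusters articulated about a known center (and axis when
    ``hinge``): the ground-truth oracle for the functional joint fits."""
    rng = np.random.default_rng(seed)
    par_local = rng.uniform(-0.12, 0.12, (4, 3)) + np.array([0, 1.25, 0])
    chi_local = rng.uniform(-0.12, 0.12, (4, 3)) + np.array([0.05, 0.55, 0])
    parent = np.zeros((T, 4, 3))
    child = np.zeros((T, 4, 3))
    truth = np.zeros((T, 3))
    axes = np.zeros((T, 3))
    for t in range(T):
        Rp = euler_xyz(np.array([0.25 * np.sin(t * 0.1), 0.15 * np.cos(t * 0.13),
                                 0.2 * np.sin(t * 0.07)]))
        tp = np.array([0.005 * t, 0.0, 0.002 * t])
        cw = Rp @ CENTER + tp
        parent[t] = par_local @ Rp.T + tp
        if hinge:
            Rc = Rp @ axis_angle(AXIS, 1.0 * np.sin(t * 0.2))
        else:
            Rc = Rp @ euler_xyz(np.array([0.6 * np.sin(t * 0.21),
                                          0.45 * np.cos(t * 0.17),
                                          0.5 * np.sin(t * 0.11)]))
        child[t] = (chi_local - CENTER) @ Rc.T + cw
        truth[t] = cw
        axes[t] = Rp @ AXIS
    n = np.random.default_rng(seed + 1)
    parent = parent + noise * n.standard_normal(parent.shape)
    child = child + noise * n.standard_normal(child.shape)
    if soft > 0:
        tt = np.arange(T) * 0.01
        for i in range(4):
            d = n.standard_normal(3)
            d /= np.linalg.norm(d)
            child[:, i] += soft * np.sin(2 * np.pi * 1.5 * tt + n.uniform(0, 6))[:, None] * d
    return parent, child, truth, axes


def _sphere_from_clusters(parent, child):
    cf = closed_form_joint_center(parent, child)
    both = np.concatenate([parent, child], axis=1)
    return both, cf, sphere_fit(both, JointCenterFit(
        "j", cf.centers, np.zeros(both.shape[1]), cf.rms_residual,
        parent_rot=cf.parent_rot, parent_trans=cf.parent_trans))


# ---------------------------------------------------------------------------
# rigid_align
# ---------------------------------------------------------------------------

def test_rigid_align_recovers_transform(rng):
    A = rng.random((5, 3))
    R_true = euler_xyz(np.array([0.3, -0.2, 0.5]))
    t_true = np.array([1.0, -2.0, 0.5])
    R, t = rigid_align(A, A @ R_true.T + t_true)
    np.testing.assert_allclose(R, R_true, atol=1e-12)
    np.testing.assert_allclose(t, t_true, atol=1e-12)


# ---------------------------------------------------------------------------
# Closed-form joint center
# ---------------------------------------------------------------------------

def test_closed_form_exact_rotation():
    parent, child, truth, _ = _clusters(hinge=False, noise=0.0, seed=0)
    cf = closed_form_joint_center(parent, child)
    assert not cf.degenerate
    np.testing.assert_allclose(cf.centers, truth, atol=1e-8)


def test_closed_form_with_noise_seeded():
    parent, child, truth, _ = _clusters(hinge=False, noise=0.001, seed=1)
    cf = closed_form_joint_center(parent, child)
    err = np.linalg.norm(cf.centers - truth, axis=1)
    assert err.mean() < 0.008
    assert err.max() < 0.015


def test_closed_form_static_markers_degenerate():
    parent, child, _, _ = _clusters(hinge=True, noise=0.0, seed=2)
    static_p = np.tile(parent[0], (30, 1, 1))
    static_c = np.tile(child[0], (30, 1, 1))
    cf = closed_form_joint_center(static_p, static_c)
    assert cf.degenerate


def test_closed_form_preconditions():
    parent, child, _, _ = _clusters(hinge=False, noise=0.0, seed=0)
    with pytest.raises(ValueError, match="frames"):
        closed_form_joint_center(parent[:5], child[:5])
    with pytest.raises(ValueError, match="markers"):
        closed_form_joint_center(parent[:, :1], child[:, :1])


# ---------------------------------------------------------------------------
# Sphere fit
# ---------------------------------------------------------------------------

def test_sphere_fit_exact_on_noise_free_rotation():
    parent, child, truth, _ = _clusters(hinge=False, noise=0.0, seed=3)
    both, cf, sph = _sphere_from_clusters(parent, child)
    assert sph.rms_residual < 1e-10
    np.testing.assert_allclose(sph.centers, truth, atol=1e-7)


def test_sphere_fit_noise_and_soft_tissue_seeded():
    parent, child, truth, _ = _clusters(hinge=False, noise=0.001, seed=3, soft=0.005)
    both, cf, sph = _sphere_from_clusters(parent, child)
    err = np.linalg.norm(sph.centers - truth, axis=1)
    assert err.mean() < 0.010


def test_sphere_fit_single_frame_flagged():
    parent, child, _, _ = _clusters(hinge=False, noise=0.0, seed=0)
    both = np.concatenate([parent, child], axis=1)[:1]
    init = JointCenterFit("j", both[:1, 0] * 0, np.zeros(8), 0.0)
    out = sphere_fit(both, init)
    assert out.degenerate


def test_sphere_fit_objective_not_worse_than_init():
    parent, child, _, _ = _clusters(hinge=False, noise=0.002, seed=5)
    cf = closed_form_joint_center(parent, child)
    both = np.concatenate([parent, child], axis=1)
    init = JointCenterFit("j", cf.centers, np.zeros(8), cf.rms_residual,
                          parent_rot=cf.parent_rot, parent_trans=cf.parent_trans)
    r0 = np.linalg.norm(both - cf.centers[:, None, :], axis=2).mean(axis=0)
    obj0 = _sphere_objective(both, cf.centers, r0)
    sph = sphere_fit(both, init)
    obj1 = _sphere_objective(both, sph.centers, sph.radii)
    assert obj1 <= obj0 + 1e-12


# ---------------------------------------------------------------------------
# Axis fit
# ---------------------------------------------------------------------------

def test_axis_fit_pure_hinge_exact():
    parent, child, truth, axes = _clusters(hinge=True, noise=0.0, seed=4)
    both, cf, sph = _sphere_from_clusters(parent, child)
    ax = axis_fit(both, sph)
    assert ax.succeeded
    assert ax.rms_residual < 1e-10
    ang = np.degrees(np.arccos(np.clip(np.abs(np.einsum("ti,ti->t", ax.axes, axes)),
                                       -1, 1)))
    assert ang.max() < 0.5


def test_axis_fit_ball_motion_fails():
    parent, child, _, _ = _clusters(hinge=False, noise=0.0, seed=6)
    both, cf, sph = _sphere_from_clusters(parent, child)
    ax = axis_fit(both, sph)
    assert not ax.succeeded


def test_axis_fit_noisy_hinge_succeeds():
    parent, child, _, axes = _clusters(hinge=True, noise=0.001, seed=7)
    both, cf, sph = _sphere_from_clusters(parent, child)
    ax = axis_fit(both, sph)
    assert ax.succeeded
    ang = np.degrees(np.arccos(np.clip(np.abs(np.einsum("ti,ti->t", ax.axes, axes)),
                                       -1, 1)))
    assert ang.mean() < 3.0


def test_axis_norms_are_unit():
    parent, child, _, _ = _clusters(hinge=True, noise=0.001, seed=8)
    both, cf, sph = _sphere_from_clusters(parent, child)
    ax = axis_fit(both, sph)
    np.testing.assert_allclose(np.linalg.norm(ax.axes, axis=1), 1.0, atol=1e-12)


def test_sphere_center_ambiguity_along_hinge_axis():
    """Moving the sphere center along the hinge axis barely changes the
    moving-sphere objective — the ambiguity the axis fit resolves."""
    parent, child, truth, axes = _clusters(hinge=True, noise=0.0, seed=4)
    both, cf, sph = _sphere_from_clusters(parent, child)
    r = np.linalg.norm(both - sph.centers[:, None, :], axis=2).mean(axis=0)
    base = _sphere_objective(both, sph.centers, r)
    shifted_c = sph.centers + 0.03 * axes
    r2 = np.linalg.norm(both - shifted_c[:, None, :], axis=2).mean(axis=0)
    shifted = _sphere_objective(both, shifted_c, r2)
    total = float(np.sum(np.linalg.norm(both - sph.centers[:, None, :], axis=2) ** 2))
    assert (shifted - base) / total < 0.01


# ---------------------------------------------------------------------------
# Constraint selection
# ---------------------------------------------------------------------------

def test_select_constraint_hinge_vs_ball():
    for hinge, kind in ((True, "axis"), (False, "point")):
        parent, child, _, _ = _clusters(hinge=hinge, noise=0.0, seed=9)
        both, cf, sph = _sphere_from_clusters(parent, child)
        ax = axis_fit(both, sph)
        con = select_joint_constraint(sph, ax)
        assert con.kind == kind


def test_select_constraint_noisy_revolute_still_axis():
    parent, child, _, _ = _clusters(hinge=True, noise=0.001, seed=10)
    both, cf, sph = _sphere_from_clusters(parent, child)
    con = select_joint_constraint(sph, axis_fit(both, sph))
    assert con.kind == "axis"


def test_joint_type_detection_on_clean_clusters():
    """Hinge vs large-excursion ball discrimination is exact on noise-free
    data across seeds."""
    for seed in range(3):
        for hinge in (True, False):
            parent, child, _, _ = _clusters(hinge=hinge, noise=0.0, seed=20 + seed)
            both, cf, sph = _sphere_from_clusters(parent, child)
            ax = axis_fit(both, sph)
            assert ax.succeeded == hinge


def test_fit_joint_constraints_on_walking_trial(gait_skel, short_trial_clean):
    trial, clean = short_trial_clean
    cons = fit_joint_constraints(gait_skel, clean, max_frames=60)
    # the revolute knees and ankles must be axis-constrained
    for j in ("knee_r", "knee_l", "ankle_r", "ankle_l"):
        assert j in cons and cons[j].kind == "axis"


# ---------------------------------------------------------------------------
# Scale initialization
# ---------------------------------------------------------------------------

def test_initialize_scales_uniform_truth(gait_skel, short_trial_clean):
    trial, _ = short_trial_clean
    skel = gait_skel.copy()
    skel.scales = np.full((skel.n_segments, 3), 1.1)
    truth = skel.copy()
    markers = synthesize_markers(truth, trial.q, 100.0,
                                 NoiseConfig(marker_sigma=0.0), seed=3)
    cons = fit_joint_constraints(gait_skel, markers, max_frames=60)
    s = initialize_scales(gait_skel, markers, cons)
    np.testing.assert_allclose(s, 1.1, atol=0.011)


def test_initialize_scales_identity_fixed_point(gait_skel, short_trial_clean):
    trial, _ = short_trial_clean
    markers = synthesize_markers(gait_skel, trial.q, 100.0,
                                 NoiseConfig(marker_sigma=0.0), seed=4)
    cons = fit_joint_constraints(gait_skel, markers, max_frames=60)
    s = initialize_scales(gait_skel, markers, cons)
    np.testing.assert_allclose(s, 1.0, atol=0.01)


def test_initialize_scales_marker_only_fallback(gait_skel, short_trial_clean):
    trial, markers = short_trial_clean
    s = initialize_scales(gait_skel, markers, {})
    serr = np.abs(s - trial.skeleton.scales) / trial.skeleton.scales
    assert np.median(serr) < 0.05


# ---------------------------------------------------------------------------
# Inverse kinematics
# ---------------------------------------------------------------------------

def test_ik_recovers_known_pose(gait_skel, short_trial_clean):
    trial, clean = short_trial_clean
    skel = trial.skeleton  # true scales and marker offsets
    frames = np.arange(0, 40)
    q = ik_solve(skel, clean, frames=frames)
    np.testing.assert_allclose(q, trial.q[frames], atol=1e-3)


def test_ik_static_pose_constant(gait_skel):
    q_true = np.zeros(gait_skel.nq)
    q_true[1] = 1.0
    q_traj = np.tile(q_true, (10, 1))
    markers = synthesize_markers(gait_skel, q_traj, 100.0,
                                 NoiseConfig(marker_sigma=0.0), seed=5)
    q = ik_solve(gait_skel, markers)
    assert np.abs(np.diff(q, axis=0)).max() < 1e-6
    np.testing.assert_allclose(q[0], q_true, atol=1e-5)


def test_ik_with_occlusions(gait_skel, short_trial_clean):
    trial, _ = short_trial_clean
    skel = trial.skeleton
    markers = synthesize_markers(skel, trial.q[:60], 100.0,
                                 NoiseConfig(marker_sigma=0.0015,
                                             occlusion_rate=0.2), seed=6)
    q = ik_solve(skel, markers)
    rmse, _, _, _ = marker_error_metrics(skel, q, markers)
    assert rmse < 0.01  # < 1 cm despite 20% occlusion


def test_ik_interpolates_starved_frames(gait_skel, short_trial_clean):
    trial, clean = short_trial_clean
    skel = trial.skeleton
    sub = clean.reordered(clean.labels)
    sub.visible[5, :] = False
    sub.positions[5, :] = np.nan
    with pytest.warns(UserWarning, match="visible markers"):
        q = ik_solve(skel, MarkerTrialPatch(sub), frames=np.arange(10))
    assert np.all(np.isfinite(q))


def MarkerTrialPatch(trial):
    # rebuild to re-validate the mutated mask/positions
    from biomechfit.io import MarkerTrial
    return MarkerTrial(trial.labels, trial.positions, trial.visible, trial.frame_rate)
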