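import numpy as np
import pytest

from biomechfit.skeleton import (
    ExternalWrench,
    JointSpec,
    MarkerDef,
    Pose,
    SegmentSpec,
    Skeleton,
    SkeletonError,
    axis_angle,
    com_position,
    euler_xyz,
    forward_dynamics,
    forward_kinematics,
    inverse_dynamics,
    kinetic_energy,
    marker_jacobians,
    marker_world_positions,
    mass_matrix,
    potential_energy,
    root_dynamics,
)


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

def test_fk_identity_pose(single_box):
    pose = Pose(np.zeros(6))
    out = forward_kinematics(single_box, pose)
    np.testing.assert_allclose(out["M0"], [0.1, 0.0, 0.0], atol=1e-15)


def test_fk_scales_offsets_linearly(single_box):
    single_box.scales[:] = 2.0
    out = forward_kinematics(single_box, Pose(np.zeros(6)))
    np.testing.assert_allclose(out["M0"], [0.2, 0.0, 0.0], atol=1e-15)


def _fk_oracle(skel, q):
    """Independent FK: explicit 4x4 homogeneous-matrix chain per joint."""
    def hom(R, t):
        H = np.eye(4)
        H[:3, :3] = R
        H[:3, 3] = t
        return H

    transforms = {}
    for j in skel.joints:
        sl = skel.joint_qslice(j.name)
        qj = q[sl]
        ci = skel.segment_index(j.child_segment)
        if j.type == "free6":
            H = hom(euler_xyz(qj[3:6]), qj[:3])
        else:
            pi = skel.segment_index(j.parent_segment)
            Hp = transforms[j.parent_segment]
            off = hom(np.eye(3), skel.scales[pi] * j.parent_offset_local)
            if j.type == "ball3":
                rot = hom(euler_xyz(qj), np.zeros(3))
            else:
                rot = hom(axis_angle(j.axis_local, qj[0]), np.zeros(3))
            H = Hp @ off @ rot
        H = H @ hom(np.eye(3), -(skel.scales[ci] * j.child_offset_local))
        transforms[j.child_segment] = H
    out = {}
    for m in skel.markers:
        H = transforms[m.segment]
        si = skel.segment_index(m.segment)
        out[m.label] = (H @ np.append(skel.scales[si] * m.offset_local, 1.0))[:3]
    return out


def test_fk_matches_homogeneous_matrix_oracle(chain3, rng):
    for _ in range(5):
        q = 0.8 * rng.standard_normal(chain3.nq)
        got = forward_kinematics(chain3, Pose(q))
        want = _fk_oracle(chain3, q)
        for label in want:
            np.testing.assert_allclose(got[label], want[label], atol=1e-12)


def test_fk_dimension_mismatch_raises(chain3):
    with pytest.raises(SkeletonError):
        forward_kinematics(chain3, Pose(np.zeros(chain3.nq + 1)))


def test_fk_oracle_on_full_gait_model(gait_skel, rng):
    q = 0.5 * rng.standard_normal(gait_skel.nq)
    got = forward_kinematics(gait_skel, Pose(q))
    want = _fk_oracle(gait_skel, q)
    for label in want:
        np.testing.assert_allclose(got[label], want[label], atol=1e-12)


# ---------------------------------------------------------------------------
# Jacobians
# ---------------------------------------------------------------------------

def test_marker_jacobian_p_block_identity(single_box):
    single_box.scales[:] = [1.0, 2.0, 3.0]
    J = marker_jacobians(single_box, Pose(np.zeros(6)))
    block = J[:3, 6 + 3:]  # after q (6) and s (3): the p block
    np.testing.assert_allclose(block, np.diag([1.0, 2.0, 3.0]), atol=1e-14)


def test_marker_jacobian_tree_sparsity(chain3):
    # base marker positions must not depend on distal joint coordinates
    J = marker_jacobians(chain3, Pose(np.zeros(chain3.nq)))
    distal = chain3.joint_qslice("j2")
    np.testing.assert_allclose(J[:9, distal], 0.0, atol=1e-15)


@pytest.mark.parametrize("seed", range(3))
def test_marker_jacobians_match_finite_differences(chain3, seed):
    rng = np.random.default_rng(seed)
    skel = chain3
    q = 0.5 * rng.standard_normal(skel.nq)
    skel.scales = 1.0 + 0.2 * rng.random((skel.n_segments, 3))
    h = 1e-6
    J = marker_jacobians(skel, Pose(q))
    nq, ns = skel.nq, 3 * skel.n_segments

    def fk_vec(qv, scales, offsets):
        w = skel.with_scales(scales)
        w.set_marker_offsets(offsets)
        return marker_world_positions(w, qv).ravel()

    offs = skel.marker_offsets()
    for k in range(nq):
        dq = np.zeros(nq)
        dq[k] = h
        fd = (fk_vec(q + dq, skel.scales, offs) - fk_vec(q - dq, skel.scales, offs)) / (2 * h)
        np.testing.assert_allclose(J[:, k], fd, atol=1e-5 * max(1, np.abs(fd).max()))
    for k in range(ns):
        ds = np.zeros((skel.n_segments, 3))
        ds[k // 3, k % 3] = h
        fd = (fk_vec(q, skel.scales + ds, offs) - fk_vec(q, skel.scales - ds, offs)) / (2 * h)
        np.testing.assert_allclose(J[:, nq + k], fd, atol=1e-5 * max(1, np.abs(fd).max()))
    for k in range(3 * skel.n_markers):
        dp = np.zeros((skel.n_markers, 3))
        dp[k // 3, k % 3] = h
        fd = (fk_vec(q, skel.scales, offs + dp) - fk_vec(q, skel.scales, offs - dp)) / (2 * h)
        np.testing.assert_allclose(J[:, nq + ns + k], fd, atol=1e-5 * max(1, np.abs(fd).max()))


def test_jacobian_fd_agreement_many_draws(gait_skel):
    """Spec invariant: analytic vs finite differences over >= 100 random draws
    (random subsets of columns per draw to keep it fast)."""
    skel = gait_skel.copy()
    rng = np.random.default_rng(7)
    h = 1e-6
    for _ in range(100):
        q = 0.4 * rng.standard_normal(skel.nq)
        skel.scales = 1.0 + 0.2 * (rng.random((skel.n_segments, 3)) - 0.5)
        J = marker_jacobians(skel, Pose(q))
        k = rng.integers(skel.nq)
        dq = np.zeros(skel.nq)
        dq[k] = h
        fd = (marker_world_positions(skel, q + dq)
              - marker_world_positions(skel, q - dq)).ravel() / (2 * h)
        scale = max(1.0, np.abs(fd).max())
        np.testing.assert_allclose(J[:, k], fd, atol=1e-5 * scale)


# ---------------------------------------------------------------------------
# Center of mass
# ---------------------------------------------------------------------------

def test_com_single_segment_at_root(single_box):
    q = np.zeros(6)
    q[:3] = [1.0, 2.0, 3.0]
    np.testing.assert_allclose(com_position(single_box, Pose(q)), [1, 2, 3], atol=1e-14)


def test_com_two_equal_masses():
    segs = [SegmentSpec("a", (0.1, 0.1, 0.1), 0.5),
            SegmentSpec("b", (0.1, 0.1, 0.1), 0.5)]
    joints = [JointSpec("root", "free6", "", "a"),
              JointSpec("j", "ball3", "a", "b", (1.0, 0.0, 0.0))]
    skel = Skeleton(segs, joints, total_mass=2.0)
    np.testing.assert_allclose(com_position(skel, Pose(np.zeros(skel.nq))),
                               [0.5, 0, 0], atol=1e-14)


def test_com_matches_weighted_sum_of_fk(gait_skel, rng):
    from biomechfit.skeleton import segment_com_points
    skel = gait_skel
    q = 0.4 * rng.standard_normal(skel.nq)
    st = skel.fk_state(q)
    pts = segment_com_points(skel, st)
    want = skel.segment_masses @ pts / skel.segment_masses.sum()
    np.testing.assert_allclose(com_position(skel, Pose(q)), want, atol=1e-14)


# ---------------------------------------------------------------------------
# Mass matrix
# ---------------------------------------------------------------------------

def test_mass_matrix_single_box_translation_block(single_box):
    M = mass_matrix(single_box, Pose(np.zeros(6)))
    np.testing.assert_allclose(M[:3, :3], 10.0 * np.eye(3), atol=1e-12)


def test_mass_matrix_symmetry_and_spd(gait_skel, rng):
    for _ in range(5):
        q = 0.5 * rng.standard_normal(gait_skel.nq)
        M = mass_matrix(gait_skel, Pose(q))
        assert np.abs(M - M.T).max() < 1e-10
        assert np.linalg.eigvalsh(M).min() > 0


def test_mass_matrix_kinetic_energy_oracle(gait_skel, rng):
    """0.5 qd^T M qd must equal the per-body kinetic energy computed from
    finite differences of the (independently tested) forward kinematics."""
    skel = gait_skel
    q = 0.3 * rng.standard_normal(skel.nq)
    qd = rng.standard_normal(skel.nq)
    h = 1e-6
    st0 = skel.fk_state(q - h * qd)
    st1 = skel.fk_state(q + h * qd)
    from biomechfit.skeleton import _world_inertias, segment_com_points
    v = (segment_com_points(skel, st1) - segment_com_points(skel, st0)) / (2 * h)
    ke = 0.0
    Iw = _world_inertias(skel, skel.fk_state(q))
    for b in range(skel.n_segments):
        ke += 0.5 * skel.segment_masses[b] * v[b] @ v[b]
        W = st1.R[b] @ st0.R[b].T  # rotation over 2h
        wvec = np.array([W[2, 1] - W[1, 2], W[0, 2] - W[2, 0], W[1, 0] - W[0, 1]])
        omega = wvec / (2 * 2 * h)
        ke += 0.5 * omega @ Iw[b] @ omega
    assert kinetic_energy(skel, Pose(q, qd)) == pytest.approx(ke, rel=1e-4)


# ---------------------------------------------------------------------------
# Inverse dynamics
# ---------------------------------------------------------------------------

def test_static_equilibrium_zero_residual(single_box):
    pose = Pose(np.zeros(6), np.zeros(6), np.zeros(6))
    w = ExternalWrench("box", -10.0 * single_box.gravity)
    tau = inverse_dynamics(single_box, pose, [w])
    np.testing.assert_allclose(tau, 0.0, atol=1e-10)


def test_free_fall(single_box):
    qdd = forward_dynamics(single_box, np.zeros(6), np.zeros(6), np.zeros(6))
    np.testing.assert_allclose(qdd[:3], single_box.gravity, atol=1e-12)
    np.testing.assert_allclose(qdd[3:], 0.0, atol=1e-12)


def test_inverse_forward_dynamics_round_trip(gait_skel, rng):
    skel = gait_skel
    for _ in range(5):
        q = 0.4 * rng.standard_normal(skel.nq)
        qd = rng.standard_normal(skel.nq)
        qdd = rng.standard_normal(skel.nq)
        w = [ExternalWrench("foot_r", rng.standard_normal(3) * 100,
                            rng.standard_normal(3) * 10, rng.standard_normal(3))]
        tau = inverse_dynamics(skel, Pose(q, qd, qdd), w)
        back = forward_dynamics(skel, q, qd, tau, w)
        np.testing.assert_allclose(back, qdd, atol=1e-8)


def test_inverse_dynamics_requires_derivatives(gait_skel):
    with pytest.raises(SkeletonError):
        inverse_dynamics(gait_skel, Pose(np.zeros(gait_skel.nq)))


def test_inverse_dynamics_lagrangian_oracle(chain3, rng):
    """tau_k = d/dt(dL/dqd_k) - dL/dq_k via finite differences of the
    energies - fully independent of the Newton-Euler implementation."""
    skel = chain3
    q = 0.4 * rng.standard_normal(skel.nq)
    qd = rng.standard_normal(skel.nq)
    qdd = rng.standard_normal(skel.nq)
    tau = inverse_dynamics(skel, Pose(q, qd, qdd))
    h = 1e-5

    def lag(qv, qdv):
        return kinetic_energy(skel, Pose(qv, qdv)) - potential_energy(skel, Pose(qv))

    for k in range(skel.nq):
        qp, qm = q.copy(), q.copy()
        qp[k] += h
        qm[k] -= h
        dLdq = (lag(qp, qd) - lag(qm, qd)) / (2 * h)

        def dLdqd(t):
            qt = q + qd * t + 0.5 * qdd * t * t
            qdt = qd + qdd * t
            qdp, qdm = qdt.copy(), qdt.copy()
            qdp[k] += h
            qdm[k] -= h
            return (lag(qt, qdp) - lag(qt, qdm)) / (2 * h)

        want = (dLdqd(h) - dLdqd(-h)) / (2 * h) - dLdq
        assert tau[k] == pytest.approx(want, rel=2e-3, abs=2e-3)


def test_energy_conservation_under_integration(chain3):
    """Zero torques, zero gravity: symplectic-Euler integration conserves
    energy to O(dt); halving dt roughly halves the drift."""
    skel = chain3.copy()
    skel.gravity = np.zeros(3)
    q0 = np.array([0.0, 0.0, 0.0, 0.1, -0.2, 0.3, 0.2, -0.1, 0.15, 0.4])
    qd0 = 0.5 * np.ones(skel.nq)

    def drift(dt, steps):
        q, qd = q0.copy(), qd0.copy()
        e0 = kinetic_energy(skel, Pose(q, qd))
        for _ in range(steps):
            qdd = forward_dynamics(skel, q, qd, np.zeros(skel.nq))
            qd = qd + qdd * dt
            q = q + qd * dt
        return abs(kinetic_energy(skel, Pose(q, qd)) - e0)

    d1 = drift(2e-3, 250)
    d2 = drift(1e-3, 500)
    assert d2 < 0.7 * d1


def test_root_dynamics_matches_full_id(gait_skel, rng):
    q = 0.4 * rng.standard_normal(gait_skel.nq)
    qd = rng.standard_normal(gait_skel.nq)
    qdd = rng.standard_normal(gait_skel.nq)
    w = [ExternalWrench("foot_l", [0, 700, 0], [0, 5, 0], [0.1, 0, -0.1])]
    st = gait_skel.fk_state(q)
    tau6, M66, _ = root_dynamics(gait_skel, st, qd, qdd, w)
    tau = inverse_dynamics(gait_skel, Pose(q, qd, qdd), w)
    M = mass_matrix(gait_skel, Pose(q))
    np.testing.assert_allclose(tau6, tau[:6], atol=1e-9 * max(1, np.abs(tau).max()))
    np.testing.assert_allclose(M66, M[:6, :6], atol=1e-10 * max(1, np.abs(M).max()))


# ---------------------------------------------------------------------------
# Construction and serialization
# ---------------------------------------------------------------------------

def test_mass_fractions_must_sum_to_one():
    with pytest.raises(SkeletonError):
        Skeleton([SegmentSpec("a", (0.1, 0.1, 0.1), 0.9)],
                 [JointSpec("root", "free6", "", "a")])


def test_tree_must_have_single_free_root():
    segs = [SegmentSpec("a", (0.1, 0.1, 0.1), 1.0)]
    with pytest.raises(SkeletonError):
        Skeleton(segs, [JointSpec("root", "ball3", "", "a")])


def test_revolute_axis_must_be_unit():
    with pytest.raises(SkeletonError):
        JointSpec("j", "revolute1", "a", "b", axis_local=(0.0, 0.0, 2.0))


def test_skeleton_json_round_trip(gait_skel, tmp_path, rng):
    skel = gait_skel.copy()
    skel.scales = 1.0 + 0.1 * rng.random((skel.n_segments, 3))
    skel.segment_masses = skel.segment_masses * 1.1
    path = tmp_path / "skel.json"
    skel.save(path)
    back = type(skel).load(path)
    np.testing.assert_allclose(back.scales, skel.scales, atol=1e-12)
    np.testing.assert_allclose(back.segment_masses, skel.segment_masses, atol=1e-12)
    assert [m.label for m in back.markers] == [m.label for m in skel.markers]
    q = 0.3 * rng.standard_normal(skel.nq)
    np.testing.assert_allclose(marker_world_positions(back, q),
                               marker_world_positions(skel, q), atol=1e-12)
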