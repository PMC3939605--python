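"""Inverse/forward dynamics against independent mechanics oracles."""

import numpy as np
import pytest

from reachdim import (
    AnthropometricProfile,
    JointTrajectory,
    TorqueTrajectory,
    estimate_segment_parameters,
    forward_dynamics,
    inverse_dynamics,
    perturb_model,
    split_torques,
)
from reachdim.arm import PERM, SegmentInertia, chain_transforms
from reachdim.arm import segment_parameter_table
from reachdim.dynamics import _rne


# --- independent Lagrangian oracle -----------------------------------------
# Kinetic/potential energy assembled from geometric Jacobians built on the
# chain transforms only; Christoffel terms by finite differences of the
# mass matrix.  Shares nothing with the Newton-Euler force recursion.

def _oracle_mass_matrix(model, q_full):
    Ts = chain_transforms(model, q_full)
    M = np.zeros((7, 7))
    for i, seg in enumerate(model.inertias, 1):
        if seg.mass == 0 and not np.any(seg.inertia):
            continue
        pc = Ts[i][:3, 3] + Ts[i][:3, :3] @ seg.com
        Jv = np.zeros((3, 7))
        Jw = np.zeros((3, 7))
        for j in range(min(i, 7)):
            z = Ts[j][:3, 2]
            if model.links[j].joint_type == "revolute":
                Jv[:, j] = np.cross(z, pc - Ts[j][:3, 3])
                Jw[:, j] = z
            else:
                Jv[:, j] = z
        Iw = Ts[i][:3, :3] @ seg.inertia @ Ts[i][:3, :3].T
        M += seg.mass * (Jv.T @ Jv) + Jw.T @ Iw @ Jw
    return M


def _oracle_gravity(model, q_full, h=1e-7):
    g_base = PERM.T @ model.gravity

    def V(q):
        Ts = chain_transforms(model, q)
        return -sum(
            seg.mass * g_base @ (Ts[i][:3, 3] + Ts[i][:3, :3] @ seg.com)
            for i, seg in enumerate(model.inertias, 1)
            if seg.mass
        )

    return np.array(
        [(V(q_full + h * np.eye(7)[j]) - V(q_full - h * np.eye(7)[j])) / (2 * h) for j in range(7)]
    )


def _oracle_torque(model, q, qd, qdd, h=1e-6):
    dM = [
        (_oracle_mass_matrix(model, q + h * np.eye(7)[l]) - _oracle_mass_matrix(model, q - h * np.eye(7)[l]))
        / (2 * h)
        for l in range(7)
    ]
    M = _oracle_mass_matrix(model, q)
    Mdot = sum(dM[l] * qd[l] for l in range(7))
    quad = np.array([0.5 * qd @ dM[k] @ qd for k in range(7)])
    return M @ qdd + Mdot @ qd - quad + _oracle_gravity(model, q)


def test_rne_matches_lagrangian_oracle(model, rng):
    """Newton-Euler generalized forces equal M(q)qdd + C(q,qd)qd + G(q)
    assembled from energies, to 1e-6 N m over 100 random states."""
    worst = 0.0
    for _ in range(100):
        q = np.concatenate(
            [rng.uniform(-0.1, 0.1, 3), rng.uniform(-0.8, 0.8, 3), [rng.uniform(0.5, 2.2)]]
        )
        qd = rng.uniform(-3, 3, 7)
        qdd = rng.uniform(-20, 20, 7)
        tau = _rne(model, q[None], qd[None], qdd[None])[0]
        ref = _oracle_torque(model, q, qd, qdd)
        worst = max(worst, np.max(np.abs(tau - ref)))
    assert worst < 1e-6


def _static_traj(q4, S=5, fs=120.0, trans=None):
    q = np.tile(q4, (S, 1))
    z = np.zeros((S, 4))
    tr = np.zeros((S, 3)) if trans is None else np.tile(trans, (S, 1))
    return JointTrajectory(np.arange(S) / fs, q, z, z, tr)


def test_static_torque_is_gravitational(model):
    """With zero velocity and acceleration the total torque is G(q) and the
    dynamic component vanishes."""
    traj = _static_traj(np.array([0.2, -0.3, 0.5, 1.1]))
    tot = inverse_dynamics(model, traj)
    out = split_torques(model, traj, tot)
    assert np.allclose(out.dynamic, 0.0, atol=1e-10)
    assert np.allclose(out.total, out.gravitational, atol=1e-10)
    q_full = np.concatenate([np.zeros(3), traj.q[0]])
    assert np.allclose(out.total[0], _oracle_gravity(model, q_full)[3:], atol=1e-6)


def test_vertical_upper_arm_has_no_upper_arm_gravity_moment(model):
    """With the upper arm vertical its CoM sits on the shoulder rotation
    axes, so the upper-arm term of the adduction/flexion gravitational
    torques vanishes (checked with the forearm mass removed)."""
    import copy

    m = copy.deepcopy(model)
    m.inertias = list(m.inertias[:6]) + [SegmentInertia(0.0, np.zeros(3), np.zeros((3, 3)))]
    traj = _static_traj(np.array([0.0, 0.0, 0.4, 1.2]))
    tot = inverse_dynamics(m, traj)
    assert np.allclose(tot.total[0, :2], 0.0, atol=1e-10)


def test_zero_gravity_split(model):
    import copy

    m = copy.deepcopy(model)
    m.gravity = np.zeros(3)
    S = 40
    t = np.arange(S) / 120.0
    q = np.tile([0.1, 0.2, 0.3, 1.2], (S, 1)) + 0.2 * np.sin(2 * np.pi * 3 * t)[:, None]
    from reachdim import differentiate

    traj = JointTrajectory(t, q, differentiate(q, 120.0), differentiate(q, 120.0, 2), np.zeros((S, 3)))
    tot = inverse_dynamics(m, traj)
    out = split_torques(m, traj, tot)
    assert np.allclose(out.gravitational, 0.0, atol=1e-12)
    assert np.allclose(out.dynamic, out.total, atol=1e-12)


def test_split_conservation(model, small_session):
    from reachdim import compute_joint_angles

    tr = small_session[0][0]
    traj = compute_joint_angles(tr.markers, model)
    tot = inverse_dynamics(model, traj)
    out = split_torques(model, traj, tot)
    assert np.allclose(out.total - out.gravitational - out.dynamic, 0.0, atol=0.0)


def test_locked_shoulder_reduces_to_planar_pendulum(model):
    """With the shoulder locked the elbow torque obeys the planar closed
    form (I_c + m r^2) qdd + m g r sin(angle from vertical)."""
    tab = segment_parameter_table(model.profile)
    m_F = tab["M_F"]
    r = tab["rF"] / 100.0
    I_c = tab["I_tr_F"] * 1e-4
    S, fs = 200, 1000.0
    t = np.arange(S) / fs
    q7 = 1.2 + 0.4 * np.sin(2 * np.pi * 2 * t)
    q7d = 0.4 * 2 * np.pi * 2 * np.cos(2 * np.pi * 2 * t)
    q7dd = -0.4 * (2 * np.pi * 2) ** 2 * np.sin(2 * np.pi * 2 * t)
    q = np.column_stack([np.zeros((S, 3)), q7])
    qd = np.column_stack([np.zeros((S, 3)), q7d])
    qdd = np.column_stack([np.zeros((S, 3)), q7dd])
    traj = JointTrajectory(t, q, qd, qdd, np.zeros((S, 3)))
    tau = inverse_dynamics(model, traj).total[:, 3]
    # at q7 = 0 the forearm hangs along the upper arm (vertical down), so
    # the gravity moment goes with sin(q7)
    expected = (I_c + m_F * r**2) * q7dd + m_F * 9.81 * r * np.sin(q7)
    assert np.allclose(tau, expected, atol=1e-8)


def test_forward_dynamics_rest_with_zero_torque(model):
    import copy

    m = copy.deepcopy(model)
    m.gravity = np.zeros(3)
    S, fs = 30, 120.0
    torq = TorqueTrajectory(np.arange(S) / fs, np.zeros((S, 4)))
    q0 = np.array([0.2, -0.1, 0.3, 1.4])
    sim = forward_dynamics(m, torq, q0, np.zeros(4))
    assert np.allclose(sim.q, q0[None, :], atol=1e-9)


def test_forward_dynamics_conserves_energy(model):
    """Unactuated swing under gravity keeps total mechanical energy
    constant to integrator tolerance."""
    S, fs = 61, 120.0
    torq = TorqueTrajectory(np.arange(S) / fs, np.zeros((S, 4)))
    q0 = np.array([0.4, 0.3, 0.0, 1.2])
    qd0 = np.array([0.0, 0.5, 0.0, -0.5])
    sim = forward_dynamics(model, torq, q0, qd0)

    g_base = PERM.T @ model.gravity

    def energy(q4, qd4):
        q_full = np.concatenate([np.zeros(3), q4])
        qd_full = np.concatenate([np.zeros(3), qd4])
        M = _oracle_mass_matrix(model, q_full)
        Ts = chain_transforms(model, q_full)
        V = -sum(
            seg.mass * g_base @ (Ts[i][:3, 3] + Ts[i][:3, :3] @ seg.com)
            for i, seg in enumerate(model.inertias, 1)
            if seg.mass
        )
        return 0.5 * qd_full @ M @ qd_full + V

    e = [energy(sim.q[s], sim.qd[s]) for s in range(0, S, 10)]
    assert np.max(np.abs(np.diff(e))) < 1e-6


def test_roundtrip_on_synthetic_conditions(model, small_session):
    """Forward simulation of inverse-dynamics torques reproduces the
    joint angles (R^2 >= 0.99 per joint, pooled over conditions)."""
    from reachdim.pipeline import roundtrip_validation

    out = roundtrip_validation(model, small_session[0])
    assert np.all(out["per_joint_r2"] >= 0.99)


def test_dynamic_torques_biphasic_with_small_integral(model, small_session):
    """The dominant dynamic torque of each reach is biphasic (changes
    sign) and integrates to nearly zero across the movement — the limb
    starts and ends at rest, so the accelerating impulse is paid back.
    Minor joints carry interaction torques whose integral need not
    vanish, so only the dominant joint is checked."""
    from reachdim.pipeline import torque_condition_trials

    processed, _ = torque_condition_trials(model, small_session[0])
    for tr in processed:
        mov = tr.values[:, 25:75]
        totals = [np.trapezoid(np.abs(mov[j])) for j in range(4)]
        j = int(np.argmax(totals))
        assert abs(np.trapezoid(mov[j])) < 0.15 * totals[j]
        assert mov[j].min() < 0 < mov[j].max()


class TestPerturbModel:
    def test_identity_scales(self, profile, model):
        m = perturb_model(profile, 1.0, 1.0)
        assert m.upper_arm_length == pytest.approx(model.upper_arm_length)
        assert m.inertias[6].mass == pytest.approx(model.inertias[6].mass)

    def test_mass_scaling_follows_affine_regression(self, profile):
        """The upper-arm mass regression is affine in body weight, so a 20%
        weight change does not scale M_U by 20%."""
        m = perturb_model(profile, mass_scale=1.2)
        W, H = profile.weight * 1.2, profile.height
        assert m.inertias[5].mass == pytest.approx(0.250 + 0.03012 * W - 0.0027 * H, abs=1e-12)

    def test_out_of_range_rejected(self, profile):
        with pytest.raises(ValueError):
            perturb_model(profile, mass_scale=1.5)
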