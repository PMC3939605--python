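"""Inverse and forward dynamics of the 7-DoF arm chain.

Joint torques are computed with a recursive Newton-Euler (RNE) pass over
the Denavit-Hartenberg chain, vectorized over time samples.  The
recursion is carried out in the base frame: angular velocity/acceleration
and CoM accelerations propagate outward, forces and moments (accumulated
about the base origin) propagate inward, and each joint's generalized
force is the projection of the inter-link wrench on the joint axis.
Gravity enters through a fictitious base acceleration, so the output of
:func:`inverse_dynamics` is the total torque tau = M(q) qdd + C(q, qd) qd
+ G(q); the gravitational component G(q) is isolated by re-running the
recursion with zero velocities and accelerations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .arm import PERM, AnthropometricProfile, ArmModel, estimate_segment_parameters
from .kinematics import JointTrajectory, differentiate

__all__ = [
    "TorqueTrajectory",
    "inverse_dynamics",
    "split_torques",
    "forward_dynamics",
    "perturb_model",
    "mass_matrix",
]


@dataclass
class TorqueTrajectory:
    """Total, gravitational and dynamic torques of the four revolute joints."""

    time: np.ndarray
    total: np.ndarray                 # (S, 4) N m
    gravitational: np.ndarray | None = None
    dynamic: np.ndarray | None = None


def _vec_dh(link, q):
    """(S,4,4) homogeneous transforms of one link at joint values q (S,)."""
    S = len(q)
    if link.joint_type == "revolute":
        theta = link.theta + q + link.offset
        d = np.full(S, link.d)
    else:
        theta = np.full(S, link.theta)
        d = link.d + q + link.offset
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(link.alpha), np.sin(link.alpha)
    T = np.zeros((S, 4, 4))
    T[:, 0, 0], T[:, 0, 1], T[:, 0, 2], T[:, 0, 3] = ct, -st * ca, st * sa, link.a * ct
    T[:, 1, 0], T[:, 1, 1], T[:, 1, 2], T[:, 1, 3] = st, ct * ca, -ct * sa, link.a * st
    T[:, 2, 1], T[:, 2, 2], T[:, 2, 3] = sa, ca, d
    T[:, 3, 3] = 1.0
    return T


def _rne(model: ArmModel, Q, Qd, Qdd, gravity: np.ndarray | None = None) -> np.ndarray:
    """Generalized forces (S,7) for joint trajectories Q, Qd, Qdd (S,7)."""
    Q, Qd, Qdd = (np.asarray(a, float) for a in (Q, Qd, Qdd))
    if not (np.isfinite(Q).all() and np.isfinite(Qd).all() and np.isfinite(Qdd).all()):
        raise ValueError("non-finite joint kinematics")
    S, n = Q.shape
    g_world = model.gravity if gravity is None else gravity
    g_base = PERM.T @ np.asarray(g_world, float)

    # outward pass: frames, angular motion, origin accelerations (base frame)
    R_prev = np.broadcast_to(np.eye(3), (S, 3, 3))
    o_prev = np.zeros((S, 3))
    w_prev = np.zeros((S, 3))
    wd_prev = np.zeros((S, 3))
    a_prev = np.tile(-g_base, (S, 1))  # gravity as base acceleration

    Rs, zs, ws, wds, a_com, p_com, joint_origins = [], [], [], [], [], [], []
    for i, link in enumerate(model.links):
        T = _vec_dh(link, Q[:, i])
        z_axis = np.asarray(R_prev)[..., 2]
        joint_origins.append(np.asarray(o_prev))  # origin of frame i-1 = joint i position
        R_i = R_prev @ T[:, :3, :3]
        o_i = o_prev + np.einsum("sij,sj->si", np.asarray(R_prev), T[:, :3, 3])
        r = o_i - o_prev
        qd = Qd[:, i, None]
        qdd = Qdd[:, i, None]
        if link.joint_type == "revolute":
            w_i = w_prev + qd * z_axis
            wd_i = wd_prev + qdd * z_axis + qd * np.cross(w_prev, z_axis)
            a_i = a_prev + np.cross(wd_i, r) + np.cross(w_i, np.cross(w_i, r))
        else:
            w_i = w_prev
            wd_i = wd_prev
            a_i = (
                a_prev
                + qdd * z_axis
                + 2.0 * qd * np.cross(w_i, z_axis)
                + np.cross(wd_i, r)
                + np.cross(w_i, np.cross(w_i, r))
            )
        seg = model.inertias[i]
        c = np.einsum("sij,j->si", R_i, seg.com)
        ac = a_i + np.cross(wd_i, c) + np.cross(w_i, np.cross(w_i, c))
        Rs.append(R_i)
        zs.append(np.asarray(z_axis))
        ws.append(w_i)
        wds.append(wd_i)
        a_com.append(ac)
        p_com.append(o_i + c)
        R_prev, o_prev, w_prev, wd_prev, a_prev = R_i, o_i, w_i, wd_i, a_i

    # inward pass: force and moment about the base origin
    f = np.zeros((S, 3))
    Mom = np.zeros((S, 3))
    tau = np.empty((S, n))
    for i in range(n - 1, -1, -1):
        seg = model.inertias[i]
        if seg.mass > 0 or np.any(seg.inertia):
            Iw = np.einsum("sij,jk,slk->sil", Rs[i], seg.inertia, Rs[i])
            F = seg.mass * a_com[i]
            N = np.einsum("sij,sj->si", Iw, wds[i]) + np.cross(ws[i], np.einsum("sij,sj->si", Iw, ws[i]))
            f = f + F
            Mom = Mom + np.cross(p_com[i], F) + N
        link = model.links[i]
        if link.joint_type == "revolute":
            m_joint = Mom - np.cross(joint_origins[i], f)
            tau[:, i] = np.einsum("si,si->s", zs[i], m_joint)
        else:
            tau[:, i] = np.einsum("si,si->s", zs[i], f)
    return tau


def _frames(model: ArmModel, q_full: np.ndarray):
    """Base-frame origins, rotations and joint axes along the chain."""
    T = np.eye(4)
    origins = [T[:3, 3]]
    rots = [T[:3, :3]]
    for link, qi in zip(model.links, q_full):
        if link.joint_type == "revolute":
            theta, d = link.theta + qi + link.offset, link.d
        else:
            theta, d = link.theta, link.d + qi + link.offset
        ct, st = np.cos(theta), np.sin(theta)
        ca, sa = np.cos(link.alpha), np.sin(link.alpha)
        Ti = np.array(
            [
                [ct, -st * ca, st * sa, link.a * ct],
                [st, ct * ca, -ct * sa, link.a * st],
                [0.0, sa, ca, d],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        T = T @ Ti
        origins.append(T[:3, 3])
        rots.append(T[:3, :3])
    return origins, rots


def _revolute_mass_matrix(model: ArmModel, q_full: np.ndarray) -> np.ndarray:
    """4x4 inertia matrix of the revolute joints from link Jacobians."""
    origins, rots = _frames(model, q_full)
    M = np.zeros((4, 4))
    for i, seg in enumerate(model.inertias):
        if seg.mass == 0 and not np.any(seg.inertia):
            continue
        R_i = rots[i + 1]
        pc = origins[i + 1] + R_i @ seg.com
        Jv = np.zeros((3, 4))
        Jw = np.zeros((3, 4))
        for j in range(3, min(i + 1, 7)):  # revolute joints j+1 proximal to link i+1
            z = rots[j][:, 2]
            Jv[:, j - 3] = np.cross(z, pc - origins[j])
            Jw[:, j - 3] = z
        Iw = R_i @ seg.inertia @ R_i.T
        M += seg.mass * (Jv.T @ Jv) + Jw.T @ Iw @ Jw
    return M


def _full_kinematics(traj: JointTrajectory, feed_translation: bool = True):
    S = len(traj)
    Q = np.zeros((S, 7))
    Qd = np.zeros((S, 7))
    Qdd = np.zeros((S, 7))
    Q[:, 3:] = traj.q
    Qd[:, 3:] = traj.qd
    Qdd[:, 3:] = traj.qdd
    Q[:, :3] = traj.shoulder_translation
    if feed_translation and S >= 3:
        Qd[:, :3] = differentiate(traj.shoulder_translation, traj.fs)
        Qdd[:, :3] = differentiate(traj.shoulder_translation, traj.fs, order=2)
    return Q, Qd, Qdd


def inverse_dynamics(
    model: ArmModel, traj: JointTrajectory, feed_translation: bool = True
) -> TorqueTrajectory:
    """Total torques of the four revolute joints along a joint trajectory.

    With ``feed_translation`` the measured shoulder translation is
    differentiated and fed to the recursion as prescribed prismatic motion;
    otherwise the shoulder is treated quasi-statically (position only).
    """
    Q, Qd, Qdd = _full_kinematics(traj, feed_translation)
    tau = _rne(model, Q, Qd, Qdd)
    return TorqueTrajectory(time=traj.time.copy(), total=tau[:, 3:])


def split_torques(
    model: ArmModel, traj: JointTrajectory, total: TorqueTrajectory
) -> TorqueTrajectory:
    """Fill the gravitational and dynamic (total - gravitational) components."""
    if total.total.shape != traj.q.shape:
        raise ValueError("torque/trajectory shape mismatch")
    Q, _, _ = _full_kinematics(traj, feed_translation=False)
    grav = _rne(model, Q, np.zeros_like(Q), np.zeros_like(Q))[:, 3:]
    return TorqueTrajectory(
        time=total.time.copy(),
        total=total.total.copy(),
        gravitational=grav,
        dynamic=total.total - grav,
    )


def mass_matrix(model: ArmModel, q_full: np.ndarray) -> np.ndarray:
    """7x7 generalized inertia matrix at configuration ``q_full``."""
    q_full = np.asarray(q_full, float)
    M = np.empty((7, 7))
    Z = np.zeros((1, 7))
    for j in range(7):
        e = np.zeros((1, 7))
        e[0, j] = 1.0
        M[:, j] = _rne(model, q_full[None, :], Z, e, gravity=np.zeros(3))[0]
    return 0.5 * (M + M.T)


def forward_dynamics(
    model: ArmModel,
    torques: TorqueTrajectory,
    q0: np.ndarray,
    qd0: np.ndarray,
    shoulder_translation: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> JointTrajectory:
    """Integrate the arm motion driven by the given total-torque profiles.

    The four revolute DoF are integrated (adaptive Runge-Kutta, linearly
    interpolated torques); the shoulder translation is a prescribed
    kinematic input (constant zero if omitted).
    """
    t = np.asarray(torques.time, float)
    tau = np.asarray(torques.total, float)
    fs = 1.0 / float(np.mean(np.diff(t)))
    S = len(t)
    if shoulder_translation is None:
        trans = np.zeros((S, 3))
    else:
        trans = np.asarray(shoulder_translation, float)
    tr_d = differentiate(trans, fs)
    tr_dd = differentiate(trans, fs, order=2)

    def interp(arr, ti):
        return np.array([np.interp(ti, t, arr[:, j]) for j in range(arr.shape[1])])

    def rhs(ti, y):
        q, qd = y[:4], y[4:]
        if np.any(np.abs(q) > 50):
            raise FloatingPointError("forward dynamics diverged")
        q_full = np.concatenate([interp(trans, ti), q])
        qd_full = np.concatenate([interp(tr_d, ti), qd])
        qdd_bias = np.concatenate([interp(tr_dd, ti), np.zeros(4)])
        bias = _rne(model, q_full[None], qd_full[None], qdd_bias[None])[0, 3:]
        M = _revolute_mass_matrix(model, q_full)
        qdd = np.linalg.solve(M, interp(tau, ti) - bias)
        return np.concatenate([qd, qdd])

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        np.concatenate([np.asarray(q0, float), np.asarray(qd0, float)]),
        t_eval=t,
        rtol=rtol,
        atol=atol,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"forward dynamics integration failed: {sol.message}")
    q = sol.y[:4].T
    qd = sol.y[4:].T
    return JointTrajectory(
        time=t.copy(),
        q=q,
        qd=qd,
        qdd=differentiate(qd, fs),
        shoulder_translation=trans.copy(),
    )


def perturb_model(
    profile: AnthropometricProfile, mass_scale: float = 1.0, height_scale: float = 1.0
) -> ArmModel:
    """Arm model re-estimated after scaling the subject's weight and height.

    Used for sensitivity reruns of the torque pipeline; scales must lie in
    [0.8, 1.2] (up to +-20%).
    """
    for s in (mass_scale, height_scale):
        if not 0.8 <= s <= 1.2:
            raise ValueError("perturbation scales must be within [0.8, 1.2]")
    scaled = AnthropometricProfile(
        height=profile.height * height_scale,
        weight=profile.weight * mass_scale,
        handle_mass=profile.handle_mass,
    )
    return estimate_segment_parameters(scaled)
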