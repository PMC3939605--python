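"""Subject-specific 7-DoF arm model.

The arm is modelled as a Denavit-Hartenberg chain of seven links: three
prismatic links carrying the spatial position of the shoulder, three
revolute links realizing a spherical shoulder joint (adduction, flexion,
external rotation) and one revolute elbow-flexion link.  Segment lengths,
masses, centers of mass and inertia tensors are estimated from the
subject's height and weight with published anthropometric regression
equations (Winter segment lengths; Zatsiorsky-Seluyanov inertial
parameters).  The upper-arm mass sits on link 6; forearm, hand and the
hand-held handle are lumped into a single rigid body on link 7.

All public quantities are SI (m, kg, rad) and positions are expressed in
a gravity-aligned world frame with +z pointing up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnthropometricProfile",
    "DHLink",
    "SegmentInertia",
    "ArmModel",
    "estimate_segment_parameters",
    "dh_transform",
    "forward_kinematics",
    "START_POSTURE",
]

GRAVITY = 9.81

#: Joint values of the reference start posture: upper arm vertical along the
#: trunk, elbow flexed at 90 degrees (forearm horizontal).
START_POSTURE = np.array([0.0, 0.0, 0.0, np.pi / 2])

# World frame (gravity-aligned, z up) vs D-H base frame: p_world = PERM @ p_base.
# With this permutation the three prismatic joint values equal the world
# x, y, z coordinates of the shoulder.
PERM = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])


@dataclass(frozen=True)
class AnthropometricProfile:
    """Subject height (cm), weight (kg) and the mass of the hand-held handle."""

    height: float
    weight: float
    handle_mass: float = 0.18

    def __post_init__(self) -> None:
        if not (self.height > 0 and self.weight > 0):
            raise ValueError("height and weight must be positive")
        if self.handle_mass < 0:
            raise ValueError("handle_mass must be non-negative")


@dataclass(frozen=True)
class DHLink:
    """One Denavit-Hartenberg link.

    For a revolute link the joint value adds to ``theta`` (plus ``offset``);
    for a prismatic link it adds to ``d``.
    """

    joint_type: str  # "prismatic" | "revolute"
    alpha: float
    a: float
    theta: float
    d: float
    offset: float = 0.0


@dataclass(frozen=True)
class SegmentInertia:
    """Mass, CoM position (link frame, m) and inertia tensor about the CoM."""

    mass: float
    com: np.ndarray
    inertia: np.ndarray

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError("mass must be non-negative")
        I = np.asarray(self.inertia, float)
        if not np.allclose(I, I.T, atol=1e-12):
            raise ValueError("inertia tensor must be symmetric")
        if np.min(np.linalg.eigvalsh(I)) < -1e-12:
            raise ValueError("inertia tensor must be positive semidefinite")


ZERO_INERTIA = SegmentInertia(0.0, np.zeros(3), np.zeros((3, 3)))


@dataclass
class ArmModel:
    """Seven-link kinematic/kinetic arm model (SI units)."""

    links: list[DHLink]
    inertias: list[SegmentInertia]
    upper_arm_length: float
    forearm_length: float
    gravity: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, -GRAVITY]))
    profile: AnthropometricProfile | None = None

    @property
    def n_joints(self) -> int:
        return len(self.links)

    def to_dict(self) -> dict:
        return {
            "upper_arm_length_m": self.upper_arm_length,
            "forearm_length_m": self.forearm_length,
            "gravity": list(map(float, self.gravity)),
            "links": [
                {
                    "joint_type": l.joint_type,
                    "alpha": l.alpha,
                    "a": l.a,
                    "theta": l.theta,
                    "d": l.d,
                    "offset": l.offset,
                }
                for l in self.links
            ],
            "inertias": [
                {
                    "mass": s.mass,
                    "com": list(map(float, s.com)),
                    "inertia": np.asarray(s.inertia).tolist(),
                }
                for s in self.inertias
            ],
        }

    def dump_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# --- anthropometric regressions -------------------------------------------
# All in table units: height H in cm, weight W in kg, lengths/CoM in cm,
# masses in kg, moments of inertia in kg cm^2.  Segment lengths follow
# Winter's proportions; masses, CoM positions and principal moments follow
# the Zatsiorsky-Seluyanov regressions.  "lo" = longitudinal axis, "ap" =
# anteroposterior, "tr" = transverse (mediolateral) axis.

def _regressions(H: float, W: float) -> dict:
    return {
        "L_U": 0.186 * H,
        "L_F": 0.252 * H,          # forearm + open hand, elbow to handle tip
        "L_forearm": 0.146 * H,    # elbow to wrist, used for composite CoM
        "M_U": 0.250 + 0.03012 * W - 0.0027 * H,
        "m_forearm": 0.3185 + 0.01445 * W - 0.00114 * H,
        "m_hand": -0.1165 + 0.0036 * W + 0.00175 * H,
        "rU": 1.67 + 0.03 * W + 0.054 * H,
        "r_forearm": 0.192 - 0.028 * W + 0.093 * H,   # from elbow
        "r_hand": 4.11 + 0.026 * W + 0.033 * H,       # from wrist
        "I_lo_U": -16.9 + 0.662 * W + 0.0435 * H,
        "I_ap_U": -232.0 + 1.525 * W + 1.343 * H,
        "I_tr_U": -250.7 + 1.56 * W + 1.512 * H,
        "I_lo_fa": 5.66 + 0.306 * W - 0.088 * H,
        "I_ap_fa": -67.9 + 0.855 * W + 0.376 * H,
        "I_tr_fa": -64.0 + 0.95 * W + 0.34 * H,
        "I_lo_hand": -6.26 + 0.0762 * W + 0.0347 * H,
        "I_ap_hand": -13.68 + 0.088 * W + 0.092 * H,
        "I_tr_hand": -19.5 + 0.17 * W + 0.116 * H,
    }


def segment_parameter_table(profile: AnthropometricProfile) -> dict:
    """Geometric/inertial parameters in table units (cm, kg, kg cm^2).

    Returns the per-subject parameter summary: segment lengths, masses,
    CoM distances from the proximal joint and principal moments of inertia
    for the upper arm and for the composite forearm+hand+handle link.
    """
    R = _regressions(profile.height, profile.weight)
    m_fa = R["m_forearm"]
    m_hh = R["m_hand"] + profile.handle_mass  # handle CoM coincides with hand CoM
    M_F = m_fa + m_hh
    c_fa = R["r_forearm"]
    c_hh = R["L_forearm"] + R["r_hand"]
    rF = (m_fa * c_fa + m_hh * c_hh) / M_F
    # Parallel-axis composition about the composite CoM.  Displacements are
    # along the longitudinal axis, so the longitudinal moment is unaffected.
    d_fa, d_hh = c_fa - rF, c_hh - rF
    I_lo_F = R["I_lo_fa"] + R["I_lo_hand"]
    I_ap_F = R["I_ap_fa"] + m_fa * d_fa**2 + R["I_ap_hand"] + m_hh * d_hh**2
    I_tr_F = R["I_tr_fa"] + m_fa * d_fa**2 + R["I_tr_hand"] + m_hh * d_hh**2
    return {
        "L_U": R["L_U"],
        "L_F": R["L_F"],
        "rU": R["rU"],
        "rF": rF,
        "M_U": R["M_U"],
        "M_F": M_F,
        "I_lo_U": R["I_lo_U"],
        "I_ap_U": R["I_ap_U"],
        "I_tr_U": R["I_tr_U"],
        "I_lo_F": I_lo_F,
        "I_ap_F": I_ap_F,
        "I_tr_F": I_tr_F,
    }


def _dh_rows(L_U: float, L_F: float) -> list[DHLink]:
    hp = np.pi / 2
    return [
        DHLink("prismatic", hp, 0.0, hp, 0.0, 0.0),   # Sh X
        DHLink("prismatic", hp, 0.0, hp, 0.0, 0.0),   # Sh Y
        DHLink("prismatic", hp, 0.0, hp, 0.0, 0.0),   # Sh Z
        DHLink("revolute", hp, 0.0, 0.0, 0.0, -hp),   # shoulder adduction
        DHLink("revolute", hp, 0.0, 0.0, 0.0, hp),    # shoulder flexion
        DHLink("revolute", hp, 0.0, 0.0, L_U, np.pi), # shoulder external rotation
        DHLink("revolute", 0.0, L_F, 0.0, 0.0, hp),   # elbow flexion
    ]


def estimate_segment_parameters(profile: AnthropometricProfile) -> ArmModel:
    """Build the subject-specific arm model from height and weight.

    Links 1-5 are massless.  Link 6 carries the upper arm: in its frame the
    segment runs from the elbow (origin) to the shoulder along -y, so the
    CoM sits at ``-(L_U - rU)`` on y and the longitudinal inertia axis is y.
    Link 7 carries the composite forearm+hand+handle body along +x with its
    frame origin at the distal end of the link.
    """
    tab = segment_parameter_table(profile)
    L_U, L_F = tab["L_U"] / 100.0, tab["L_F"] / 100.0
    cm2_to_m2 = 1e-4

    I_U = np.diag([tab["I_ap_U"], tab["I_lo_U"], tab["I_tr_U"]]) * cm2_to_m2
    com_U = np.array([0.0, -(L_U - tab["rU"] / 100.0), 0.0])
    upper = SegmentInertia(tab["M_U"], com_U, I_U)

    I_F = np.diag([tab["I_lo_F"], tab["I_ap_F"], tab["I_tr_F"]]) * cm2_to_m2
    com_F = np.array([-(L_F - tab["rF"] / 100.0), 0.0, 0.0])
    forearm = SegmentInertia(tab["M_F"], com_F, I_F)

    inertias = [ZERO_INERTIA] * 5 + [upper, forearm]
    return ArmModel(_dh_rows(L_U, L_F), inertias, L_U, L_F, profile=profile)


# --- kinematics ------------------------------------------------------------

def dh_transform(link: DHLink, q: float) -> np.ndarray:
    """4x4 homogeneous transform of one link at joint value ``q``."""
    if not np.isfinite(q):
        raise ValueError("joint value must be finite")
    if link.joint_type == "revolute":
        theta, d = link.theta + q + link.offset, link.d
    else:
        theta, d = link.theta, link.d + q + link.offset
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(link.alpha), np.sin(link.alpha)
    return np.array(
        [
            [ct, -st * ca, st * sa, link.a * ct],
            [st, ct * ca, -ct * sa, link.a * st],
            [0.0, sa, ca, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def chain_transforms(model: ArmModel, q: np.ndarray) -> list[np.ndarray]:
    """Cumulative base-frame transforms T_0..T_7 (T_0 = identity)."""
    q = np.asarray(q, float)
    if q.shape != (7,):
        raise ValueError("q must be a 7-vector (3 prismatic + 4 revolute)")
    out = [np.eye(4)]
    T = np.eye(4)
    for link, qi in zip(model.links, q):
        T = T @ dh_transform(link, qi)
        out.append(T.copy())
    return out


def _full_q(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, float)
    if q.shape == (4,):
        return np.concatenate([np.zeros(3), q])
    if q.shape == (7,):
        return q
    raise ValueError("q must have 4 (revolute) or 7 entries")


def forward_kinematics(model: ArmModel, q: np.ndarray) -> dict[str, np.ndarray]:
    """World-frame positions of shoulder, elbow, wrist and endpoint.

    ``q`` is either the 4 revolute joint values (shoulder at the origin) or
    the full 7-vector including the shoulder translation.  The wrist point
    is on the forearm axis at the anatomical wrist (elbow + forearm bone
    length); the endpoint is the distal end of link 7.
    """
    qf = _full_q(q)
    Ts = chain_transforms(model, qf)
    shoulder_b = Ts[3][:3, 3]
    elbow_b = Ts[6][:3, 3]
    end_b = Ts[7][:3, 3]
    wrist_frac = 0.146 / 0.252  # anatomical wrist as fraction of link 7
    wrist_b = elbow_b + wrist_frac * (end_b - elbow_b)
    return {
        "shoulder": PERM @ shoulder_b,
        "elbow": PERM @ elbow_b,
        "wrist": PERM @ wrist_b,
        "endpoint": PERM @ end_b,
    }
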