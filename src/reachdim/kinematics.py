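"""Marker-based joint kinematics.

Joint angles are recovered from the marker positions segment by segment:
the shoulder->elbow vector fixes shoulder adduction and flexion, the
elbow->wrist vector (mean of the two wrist markers) fixes shoulder
external rotation and elbow flexion.  Each angle is obtained with a
quadrant-safe two-argument arctangent of the segment vector expressed in
the reference frame of the corresponding joint axis, walking down the
Denavit-Hartenberg chain.  The two-fold branch ambiguity of each
two-angle pair is resolved by continuity with the previous sample
(starting from a reference posture).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .arm import PERM, START_POSTURE, ArmModel, dh_transform

__all__ = [
    "MarkerFrameSeries",
    "JointTrajectory",
    "MovementEvents",
    "compute_joint_angles",
    "differentiate",
    "lowpass_fir",
    "endpoint_speed_events",
]

MARKER_NAMES = ("shoulder", "upper_arm", "elbow", "wrist_radial", "wrist_ulnar", "endpoint")


@dataclass
class MarkerFrameSeries:
    """Uniformly sampled 3-D marker trajectories (world frame, m)."""

    time: np.ndarray
    positions: dict[str, np.ndarray]  # name -> (S, 3)

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class JointTrajectory:
    """Angles, velocities and accelerations of the four revolute joints."""

    time: np.ndarray
    q: np.ndarray    # (S, 4) rad
    qd: np.ndarray   # (S, 4) rad/s
    qdd: np.ndarray  # (S, 4) rad/s^2
    shoulder_translation: np.ndarray  # (S, 3) m, world frame

    @property
    def fs(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.time)))

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class MovementEvents:
    """Movement onset/end times from the 10%-of-peak speed threshold."""

    onset: float
    end: float

    def __post_init__(self) -> None:
        if not self.onset < self.end:
            raise ValueError("onset must precede end")

    @property
    def MT(self) -> float:
        return self.end - self.onset


def differentiate(series: np.ndarray, fs: float, order: int = 1) -> np.ndarray:
    """Numerical time derivative along axis 0 (central differences).

    Interior samples use central differences, edges one-sided differences;
    ``order=2`` applies the rule twice.
    """
    x = np.asarray(series, float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    d = np.gradient(x, 1.0 / fs, axis=0, edge_order=1)
    if order == 2:
        d = np.gradient(d, 1.0 / fs, axis=0, edge_order=1)
    return d


def lowpass_fir(x: np.ndarray, fs: float, cutoff: float, width_s: float = 0.1) -> np.ndarray:
    """Zero-phase FIR low-pass along axis 0 (forward-backward filtering)."""
    numtaps = int(round(width_s * fs))
    numtaps += 1 - numtaps % 2  # odd
    numtaps = max(numtaps, 5)
    h = signal.firwin(numtaps, cutoff, fs=fs)
    return signal.filtfilt(h, [1.0], x, axis=0, padlen=min(3 * numtaps, x.shape[0] - 1))


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def _pick_branch(cands: list[tuple[float, float]], ref: tuple[float, float]) -> tuple[float, float]:
    best, cost = cands[0], np.inf
    for c in cands:
        d = abs(_wrap(c[0] - ref[0])) + abs(_wrap(c[1] - ref[1]))
        if d < cost:
            best, cost = c, d
    return best


def compute_joint_angles(
    markers: MarkerFrameSeries,
    model: ArmModel,
    gravity_rotation: np.ndarray | None = None,
    reference_q: np.ndarray = START_POSTURE,
) -> JointTrajectory:
    """Joint angles (and derivatives) from marker trajectories.

    ``gravity_rotation`` is an optional 3x3 rotation applied to all marker
    coordinates first, mapping them into the gravity-aligned frame (z up);
    identity by default.
    """
    R = np.eye(3) if gravity_rotation is None else np.asarray(gravity_rotation, float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("gravity_rotation must be orthonormal")

    sh = markers.positions["shoulder"] @ R.T
    el = markers.positions["elbow"] @ R.T
    wr = 0.5 * (markers.positions["wrist_radial"] + markers.positions["wrist_ulnar"]) @ R.T

    # world -> D-H base frame
    v_se = (el - sh) @ PERM
    v_ew = (wr - el) @ PERM

    n_se = np.linalg.norm(v_se, axis=1)
    n_ew = np.linalg.norm(v_ew, axis=1)
    for name, n in (("shoulder-elbow", n_se), ("elbow-wrist", n_ew)):
        bad = np.flatnonzero(n < 1e-9)
        if bad.size:
            raise ValueError(f"degenerate {name} segment vector at frame {bad[0]}")
    u = v_se / n_se[:, None]

    links = model.links
    # fixed rotation of frame 3 (after the prismatic links)
    R3 = np.eye(4)
    for link in links[:3]:
        R3 = R3 @ dh_transform(link, 0.0)
    R3 = R3[:3, :3]
    u3 = u @ R3  # = R3.T applied row-wise

    S = len(markers)
    q = np.empty((S, 4))
    ref45 = (float(reference_q[0] + links[3].offset), float(reference_q[1] + links[4].offset))
    ref67 = (float(reference_q[2] + links[5].offset), float(reference_q[3] + links[6].offset))
    off = [l.offset for l in links[3:]]

    for s in range(S):
        ux, uy, uz = u3[s]
        h = np.hypot(ux, uy)
        # u3 = (sin(t5)cos(t4), sin(t5)sin(t4), -cos(t5))
        cands = [
            (np.arctan2(uy, ux), np.arctan2(h, -uz)),
            (np.arctan2(-uy, -ux), np.arctan2(-h, -uz)),
        ]
        t4, t5 = _pick_branch(cands, ref45)
        ref45 = (t4, t5)

        T4 = dh_transform(links[3], t4 - off[0])
        T5 = dh_transform(links[4], t5 - off[1])
        R5 = R3 @ T4[:3, :3] @ T5[:3, :3]
        w = R5.T @ v_ew[s] / n_ew[s]
        hw = np.hypot(w[0], w[1])
        # w = (cos(t7)cos(t6), cos(t7)sin(t6), sin(t7))
        cands = [
            (np.arctan2(w[1], w[0]), np.arctan2(w[2], hw)),
            (np.arctan2(-w[1], -w[0]), np.arctan2(w[2], -hw)),
        ]
        t6, t7 = _pick_branch(cands, ref67)
        ref67 = (t6, t7)

        q[s] = [t4 - off[0], t5 - off[1], t6 - off[2], t7 - off[3]]

    # keep angles continuous (no 2*pi jumps) and near the reference posture
    q = np.asarray(reference_q, float) + _wrap(q - np.asarray(reference_q, float)[None, :])
    q = np.unwrap(q, axis=0)

    fs = markers.fs
    return JointTrajectory(
        time=markers.time.copy(),
        q=q,
        qd=differentiate(q, fs),
        qdd=differentiate(q, fs, order=2),
        shoulder_translation=sh.copy(),
    )


def endpoint_speed_events(
    endpoint: np.ndarray,
    fs: float,
    cutoff: float = 15.0,
    threshold: float = 0.10,
) -> tuple[np.ndarray, MovementEvents]:
    """Endpoint speed profile and movement onset/end events.

    The position is low-pass filtered (zero-phase FIR, 15 Hz cutoff) and
    differentiated; onset and end are the outermost crossings of 10% of the
    peak speed bracketing the global peak, located by linear interpolation.
    """
    pos = np.atleast_2d(np.asarray(endpoint, float))
    if pos.shape[0] == 3 and pos.shape[1] != 3:
        pos = pos.T
    filt = lowpass_fir(pos, fs, cutoff)
    vel = differentiate(filt, fs)
    speed = np.linalg.norm(vel, axis=1)
    vmax = speed.max()
    if vmax <= 0:
        raise ValueError("flat endpoint trajectory: no speed peak")
    thr = threshold * vmax
    ipk = int(np.argmax(speed))
    below = speed < thr

    def _cross(i0: int, step: int) -> float:
        i = i0
        while 0 <= i + step < len(speed) and not below[i + step]:
            i += step
        j = i + step
        if j < 0 or j >= len(speed):
            return i / fs
        # linear interpolation of the threshold crossing between j and i
        f = (thr - speed[j]) / (speed[i] - speed[j])
        return (j + f * (i - j)) / fs

    onset = _cross(ipk, -1)
    end = _cross(ipk, +1)
    return speed, MovementEvents(onset=onset, end=end)
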