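"""Synthetic reaching sessions with known generator structure.

Emulates the study design — fast point-to-point reaches between a
central start (upper arm vertical, elbow at 90 deg) and 8 targets on a
15-cm circle, in the frontal and sagittal vertical planes, out and back,
5 repetitions each (160 trials) — producing marker trajectories, torque
trials and EMG trials whose ground-truth spatial/temporal/spatiotemporal
generators are known, so every pipeline stage can be validated against
construction.

Reaches are minimum-jerk in task space: the endpoint follows the
straight line to the target with the quintic minimum-jerk time law
(bell-shaped speed), and joint postures along the path are found by
inverse kinematics (minimum joint excursion from the start posture),
precomputed on a path grid per condition and interpolated in the path
parameter per repetition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import START_POSTURE, ArmModel, forward_kinematics
from .kinematics import MarkerFrameSeries
from .preprocessing import MUSCLES, N_NORMALIZED_SAMPLES, ProcessedTrial

__all__ = [
    "SessionConfig",
    "SyntheticGroundTruth",
    "SyntheticTrial",
    "minimum_jerk_path",
    "solve_posture",
    "generate_session",
    "generate_emg",
    "generate_torque_trials",
]

TORQUE_CHANNELS = ["sh_adduction", "sh_flexion", "sh_ext_rotation", "el_flexion"]


@dataclass(frozen=True)
class SessionConfig:
    """Study-design parameters of one synthetic session."""

    planes: tuple[str, ...] = ("frontal", "sagittal")
    n_targets: int = 8
    target_radius: float = 0.15
    directions: tuple[str, ...] = ("out", "back")
    repetitions: int = 5
    MT_nominal: float = 0.35
    fs: float = 120.0
    hold_s: float = 0.5
    #: additive Gaussian noise of the optically tracked arm markers
    marker_noise_sd: float = 0.0003
    #: noise of the electromagnetically tracked endpoint sphere
    endpoint_noise_sd: float = 0.002
    mt_jitter: float = 0.10
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.planes) * self.n_targets * len(self.directions) * self.repetitions

    @property
    def n_conditions(self) -> int:
        return len(self.planes) * self.n_targets * len(self.directions)


@dataclass
class SyntheticTrial:
    """One generated movement trial."""

    condition: tuple  # (plane, target index, direction)
    repetition: int
    markers: MarkerFrameSeries
    true_q: np.ndarray       # (S, 4)
    MT: float
    onset: float
    end: float


@dataclass
class SyntheticGroundTruth:
    """Everything needed to check recovery against construction."""

    generators: np.ndarray | None = None     # arrangement-specific layout
    coefficients: np.ndarray | None = None
    arrangement: str | None = None
    tonic_pre: np.ndarray | None = None
    tonic_post: np.ndarray | None = None
    noise: float = 0.0
    phasic: np.ndarray | None = None         # (D, T, K) noiseless phasic part
    extras: dict = field(default_factory=dict)


def minimum_jerk_path(
    start: np.ndarray, end: np.ndarray, MT: float, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Quintic minimum-jerk interpolation between two points.

    Returns (time, positions); the path is straight with the bell-shaped
    speed profile whose peak is 15 d / (8 MT).
    """
    if MT <= 0:
        raise ValueError("MT must be positive")
    n = int(round(MT * fs)) + 1
    t = np.arange(n) / fs
    tau = np.clip(t / MT, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    return t, start[None, :] + s[:, None] * (end - start)[None, :]


def _mj_profile(t: np.ndarray, MT: float) -> np.ndarray:
    tau = np.clip(t / MT, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def solve_posture(
    model: ArmModel, endpoint_target: np.ndarray, reference_q: np.ndarray = START_POSTURE
) -> np.ndarray:
    """Inverse kinematics: joint configuration reaching ``endpoint_target``
    (world frame, shoulder at origin) closest to ``reference_q``."""
    from .arm import PERM
    from .dynamics import _frames

    target = np.asarray(endpoint_target, float)
    reach = model.upper_arm_length + model.forearm_length
    if np.linalg.norm(target) >= reach - 1e-9:
        raise ValueError("target out of reach")

    target_b = PERM.T @ target
    q = np.asarray(reference_q, float).copy()
    ref = np.asarray(reference_q, float)
    for _ in range(100):
        q_full = np.concatenate([np.zeros(3), q])
        origins, rots = _frames(model, q_full)
        p = origins[7]
        r = target_b - p
        # endpoint Jacobian of the four revolute joints (base frame)
        J = np.column_stack(
            [np.cross(rots[j][:, 2], p - origins[j]) for j in range(3, 7)]
        )
        JJt = J @ J.T + 1e-10 * np.eye(3)
        dq_task = J.T @ np.linalg.solve(JJt, r)
        # project the pull toward the reference posture into the nullspace
        null = np.eye(4) - J.T @ np.linalg.solve(JJt, J)
        dq_null = null @ (ref - q)
        if np.linalg.norm(r) < 1e-10 and np.linalg.norm(dq_null) < 1e-10:
            break
        q = q + dq_task + 0.5 * dq_null
    err = np.linalg.norm(forward_kinematics(model, q)["endpoint"] - target)
    if err > 1e-6:
        raise RuntimeError(f"inverse kinematics did not converge (residual {err:.2e} m)")
    return q


def _target_points(center: np.ndarray, plane: str, n: int, radius: float) -> np.ndarray:
    phis = 2 * np.pi * np.arange(n) / n
    if plane == "frontal":  # y-z plane of the gravity-aligned frame
        offs = np.stack([np.zeros(n), np.cos(phis), np.sin(phis)], axis=1)
    elif plane == "sagittal":  # x-z plane
        offs = np.stack([np.cos(phis), np.zeros(n), np.sin(phis)], axis=1)
    else:
        raise ValueError(f"unknown plane {plane!r}")
    return center[None, :] + radius * offs


def _perp(v: np.ndarray) -> np.ndarray:
    v = v / np.linalg.norm(v)
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def generate_session(
    model: ArmModel, config: SessionConfig
) -> tuple[list[SyntheticTrial], SyntheticGroundTruth]:
    """Generate one full synthetic session of marker trials.

    Each trial holds the initial posture, performs a straight task-space
    minimum-jerk reach (MT jittered across repetitions by +-10%), then
    holds the final posture; markers are forward-kinematics positions
    plus additive Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    q_start = START_POSTURE
    start_pt = forward_kinematics(model, q_start)["endpoint"]

    # joint postures along each straight outward path, on a path-parameter
    # grid (reused for every repetition and both directions)
    n_grid = 101
    s_grid = np.linspace(0.0, 1.0, n_grid)
    postures = {}
    paths = {}
    for plane in config.planes:
        pts = _target_points(start_pt, plane, config.n_targets, config.target_radius)
        for i, pt in enumerate(pts):
            qs = np.empty((n_grid, 4))
            q_prev = q_start
            for g, s in enumerate(s_grid):
                q_prev = solve_posture(model, start_pt + s * (pt - start_pt), q_prev)
                qs[g] = q_prev
            paths[(plane, i)] = qs
            postures[(plane, i)] = qs[-1]

    fs, hold = config.fs, config.hold_s
    n_hold = int(round(hold * fs))
    trials = []
    for plane in config.planes:
        for tgt in range(config.n_targets):
            path = paths[(plane, tgt)]
            for direction in config.directions:
                for rep in range(config.repetitions):
                    mt = config.MT_nominal * (1 + config.mt_jitter * rng.uniform(-1, 1))
                    n_mov = int(round(mt * fs)) + 1
                    t_mov = np.arange(n_mov) / fs
                    s = _mj_profile(t_mov, mt)
                    if direction == "back":
                        s = 1.0 - s
                    q_mov = np.column_stack(
                        [np.interp(s, s_grid, path[:, j]) for j in range(4)]
                    )
                    qa, qb = q_mov[0], q_mov[-1]
                    q = np.vstack(
                        [np.tile(qa, (n_hold, 1)), q_mov, np.tile(qb, (n_hold, 1))]
                    )
                    S = q.shape[0]
                    time = np.arange(S) / fs
                    positions = _markers_from_q(
                        model, q, rng, config.marker_noise_sd, config.endpoint_noise_sd
                    )
                    trials.append(
                        SyntheticTrial(
                            condition=(plane, tgt, direction),
                            repetition=rep,
                            markers=MarkerFrameSeries(time, positions),
                            true_q=q,
                            MT=mt,
                            onset=n_hold / fs,
                            end=n_hold / fs + mt,
                        )
                    )
    gt = SyntheticGroundTruth(
        noise=config.marker_noise_sd,
        extras={"postures": postures, "start_posture": q_start, "config": config},
    )
    return trials, gt


def _markers_from_q(
    model: ArmModel,
    q: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float,
    endpoint_noise_sd: float | None = None,
) -> dict[str, np.ndarray]:
    S = q.shape[0]
    names = ("shoulder", "upper_arm", "elbow", "wrist_radial", "wrist_ulnar", "endpoint")
    pos = {n: np.empty((S, 3)) for n in names}
    for s in range(S):
        fk = forward_kinematics(model, q[s])
        sh, el, wr, ep = fk["shoulder"], fk["elbow"], fk["wrist"], fk["endpoint"]
        d = 0.01 * _perp(ep - el)
        pos["shoulder"][s] = sh
        pos["upper_arm"][s] = sh + 0.4 * (el - sh)
        pos["elbow"][s] = el
        pos["wrist_radial"][s] = wr + d
        pos["wrist_ulnar"][s] = wr - d
        pos["endpoint"][s] = ep
    if endpoint_noise_sd is None:
        endpoint_noise_sd = noise_sd
    for n in names:
        sd = endpoint_noise_sd if n == "endpoint" else noise_sd
        if sd > 0:
            pos[n] = pos[n] + rng.normal(0.0, sd, (S, 3))
    return pos


# --- EMG and torque trial generators ---------------------------------------

def _burst(T: int, center: float, width: float) -> np.ndarray:
    t = np.arange(T)
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _apply_noise(x: np.ndarray, noise: float, rng: np.random.Generator) -> np.ndarray:
    """Signal-dependent multiplicative Gaussian noise, truncated at zero."""
    if noise <= 0:
        return x
    return np.clip(x * (1.0 + noise * rng.standard_normal(x.shape)), 0.0, None)


def generate_emg(
    arrangement: str,
    N: int,
    D: int = 19,
    K: int = 32,
    T: int = N_NORMALIZED_SAMPLES,
    tonic: float = 0.2,
    noise: float = 0.05,
    seed: int = 0,
    asynchronous: bool = False,
) -> tuple[list[ProcessedTrial], SyntheticGroundTruth]:
    """Synthetic phasic+tonic EMG trials with known generator structure.

    The phasic part is a non-negative combination of N smooth non-negative
    generators of the requested arrangement (movement-locked Gaussian
    bursts); ``asynchronous`` spatiotemporal generators stagger the burst
    per muscle.  A constant-plus-ramp tonic component and multiplicative
    truncated-Gaussian noise are added on top.
    """
    if arrangement not in ("spatial", "temporal", "spatiotemporal"):
        raise ValueError("unknown arrangement")
    if N < 1 or N > min(D, K):
        raise ValueError("need 1 <= N <= min(D, K)")
    rng = np.random.default_rng(seed)
    channels = list(MUSCLES[:D]) if D <= len(MUSCLES) else [f"m{i}" for i in range(D)]

    # movement occupies samples 25..75 of the normalized base
    centers = np.linspace(T * 0.30, T * 0.70, N)
    width = T * 0.06

    phasic = np.zeros((D, T, K))
    if arrangement == "spatial":
        W = rng.random((D, N)) ** 2 + 0.05  # (D, N) spatial generators
        C = np.zeros((N, K, T))
        for n in range(N):
            for k in range(K):
                amp = rng.gamma(2.0, 0.5)
                jit = rng.uniform(-0.05, 0.05) * T
                C[n, k] = amp * _burst(T, centers[n] + jit, width)
        phasic = np.einsum("dn,nkt->dtk", W, C)
        gens, coefs = W, C
    elif arrangement == "temporal":
        Cg = np.stack([_burst(T, c, width) for c in centers], axis=1)  # (T, N)
        Wk = rng.gamma(2.0, 0.5, (N, D, K))
        phasic = np.einsum("tn,ndk->dtk", Cg, Wk)
        gens, coefs = Cg, Wk
    else:  # spatiotemporal
        V = np.zeros((N, D, T))
        for n in range(N):
            w = rng.random(D) ** 2 + 0.05
            if asynchronous:
                delays = rng.uniform(-0.15, 0.15, D) * T
            else:
                delays = np.zeros(D)
            for d in range(D):
                V[n, d] = w[d] * _burst(T, centers[n] + delays[d], width)
        A = rng.gamma(2.0, 0.5, (N, K))
        phasic = np.einsum("ndt,nk->dtk", V, A)
        gens, coefs = V, A

    pre = tonic * (rng.random(D) + 0.2)
    post = tonic * (rng.random(D) + 0.2)
    i_on, i_end = 25, 75
    tonic_tc = np.empty((D, T))
    tonic_tc[:, :i_on] = pre[:, None]
    tonic_tc[:, i_end:] = post[:, None]
    # same ramp convention as the tonic-subtraction model (post reached at i_end)
    lin = np.arange(i_end - i_on) / (i_end - i_on)
    tonic_tc[:, i_on:i_end] = pre[:, None] + (post - pre)[:, None] * lin[None, :]

    trials = []
    for k in range(K):
        x = phasic[:, :, k] + tonic_tc
        x = _apply_noise(x, noise, rng)
        trials.append(ProcessedTrial(channels=channels, values=x, MT=1.0, condition=(k,)))
    gt = SyntheticGroundTruth(
        generators=gens,
        coefficients=coefs,
        arrangement=arrangement,
        tonic_pre=pre,
        tonic_post=post,
        noise=noise,
        phasic=phasic,
        extras={"asynchronous": asynchronous, "centers": centers, "width": width},
    )
    return trials, gt


def biphasic_waveform(T: int = N_NORMALIZED_SAMPLES, center: float | None = None, width: float | None = None) -> np.ndarray:
    """Zero-integral biphasic pulse (derivative of a Gaussian), the shared
    temporal shape of dynamic torques: acceleration then deceleration."""
    if center is None:
        center = T * 0.5
    if width is None:
        width = T * 0.09
    t = np.arange(T)
    u = -(t - center) / width * np.exp(-0.5 * ((t - center) / width) ** 2)
    return u / np.max(np.abs(u))


def generate_torque_trials(
    N_spatial: int = 3,
    K: int = 32,
    T: int = N_NORMALIZED_SAMPLES,
    noise: float = 0.03,
    seed: int = 0,
) -> tuple[list[ProcessedTrial], SyntheticGroundTruth]:
    """Dynamic-torque-like trials: a single shared biphasic waveform times
    condition-dependent signed joint-weight vectors of spatial rank
    ``N_spatial`` (temporal rank 1), plus additive Gaussian noise scaled to
    the signal RMS."""
    if not 1 <= N_spatial <= 4:
        raise ValueError("N_spatial must be within 1..4")
    rng = np.random.default_rng(seed)
    u = biphasic_waveform(T)
    # orthonormal spatial basis and well-conditioned signed condition weights
    W, _ = np.linalg.qr(rng.standard_normal((4, N_spatial)))
    C = rng.standard_normal((N_spatial, K))
    B = W @ C  # (4, K) per-condition joint balances
    clean = np.einsum("dk,t->dtk", B, u)
    rms = float(np.sqrt(np.mean(clean**2)))
    data = clean + rng.normal(0.0, noise * rms, clean.shape) if noise > 0 else clean
    trials = [
        ProcessedTrial(channels=TORQUE_CHANNELS, values=data[:, :, k], MT=1.0, condition=(k,))
        for k in range(K)
    ]
    gt = SyntheticGroundTruth(
        generators=W,
        coefficients=C,
        arrangement="spatial",
        noise=noise,
        phasic=clean,
        extras={"waveform": u},
    )
    return trials, gt
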