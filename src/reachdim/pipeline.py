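"""End-to-end torque and EMG analyses.

``run_torque_analysis`` takes a session (synthetic by default, or marker
CSV files) through joint angles, recursive Newton-Euler inverse
dynamics, gravitational/dynamic torque splitting, repetition averaging
and time normalization, then estimates the spatial, temporal and
spatiotemporal dimensionality of the dynamic torques with PCA and the
threshold/knee/shuffle criteria.  ``run_emg_analysis`` does the same for
phasic muscle patterns with NMF, including the clipped-vs-unclipped
(gradient descent) comparison.  Both are deterministic given the
configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .arm import AnthropometricProfile, estimate_segment_parameters
from .comparison import match_similarity, separability_index
from .decomposition import build_matrix, curve_for_method, pca_curve
from .dimensionality import select_knee, select_shuffle, select_threshold
from .dynamics import inverse_dynamics, perturb_model, split_torques
from .kinematics import MovementEvents, compute_joint_angles, endpoint_speed_events, lowpass_fir, MarkerFrameSeries
from .preprocessing import (
    N_NORMALIZED_SAMPLES,
    ProcessedTrial,
    average_repetitions,
    subtract_tonic,
    time_normalize,
)
from .synthetic import (
    SessionConfig,
    SyntheticTrial,
    TORQUE_CHANNELS,
    generate_emg,
    generate_session,
)

__all__ = [
    "AnalysisReport",
    "run_torque_analysis",
    "run_emg_analysis",
    "torque_condition_trials",
]

ARRANGEMENTS = ("spatial", "temporal", "spatiotemporal")

# events on the normalized 100-sample base: onset at sample 25, end at 75
NORMALIZED_EVENTS = MovementEvents(onset=25.0, end=75.0)


@dataclass
class AnalysisReport:
    """Dimensionality table plus diagnostics, serializable to JSON."""

    kind: str
    dimensionality: dict = field(default_factory=dict)  # arrangement -> criterion -> N
    r2_curves: dict = field(default_factory=dict)
    separability: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    seed: int = 0
    config_hash: str = ""

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {str(k): clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, np.ndarray):
                return clean(o.tolist())
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o

        return json.dumps(
            clean(
                {
                    "kind": self.kind,
                    "seed": self.seed,
                    "config_hash": self.config_hash,
                    "dimensionality": self.dimensionality,
                    "r2_curves": self.r2_curves,
                    "separability": self.separability,
                    "extras": self.extras,
                }
            ),
            indent=1,
            sort_keys=True,
        )


def _hash_config(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def extract_kinematics(
    model, trials: list[SyntheticTrial] | list[dict], marker_cutoff: float = 15.0
) -> dict:
    """Markers -> joint trajectories and movement events, per condition.

    Model-independent up to the link geometry; the result can be fed to
    :func:`condition_torques` repeatedly (e.g. for anthropometric
    sensitivity reruns) without re-deriving the kinematics.
    """
    by_cond: dict = {}
    for tr in trials:
        markers = tr.markers if isinstance(tr, SyntheticTrial) else tr["markers"]
        cond = tr.condition if isinstance(tr, SyntheticTrial) else tr["condition"]
        fs = markers.fs
        if marker_cutoff:
            markers = MarkerFrameSeries(
                markers.time,
                {k: lowpass_fir(v, fs, marker_cutoff) for k, v in markers.positions.items()},
            )
        traj = compute_joint_angles(markers, model)
        _, events = endpoint_speed_events(markers.positions["endpoint"], fs)
        by_cond.setdefault(cond, []).append((traj, events))
    return by_cond


def condition_torques(model, by_cond: dict) -> list[ProcessedTrial]:
    """Joint trajectories -> per-condition normalized dynamic-torque trials.

    Per trial: total torques by RNE and gravitational/dynamic split;
    repetitions of each condition are aligned on movement onset,
    averaged, and resampled to the 100-sample normalized base.
    """
    processed = []
    for cond, items in by_cond.items():
        dyn, evs = [], []
        fs = items[0][0].fs
        for traj, events in items:
            total = inverse_dynamics(model, traj)
            torq = split_torques(model, traj, total)
            dyn.append(torq.dynamic.T)
            evs.append(events)
        avg, ev = average_repetitions(dyn, evs, fs)
        vals = time_normalize(avg, ev, fs)
        processed.append(
            ProcessedTrial(channels=TORQUE_CHANNELS, values=vals, MT=ev.MT, condition=cond)
        )
    return processed


def torque_condition_trials(
    model, trials: list[SyntheticTrial] | list[dict], marker_cutoff: float = 15.0
) -> tuple[list[ProcessedTrial], dict]:
    """Markers -> per-condition normalized dynamic-torque trials."""
    by_cond = extract_kinematics(model, trials, marker_cutoff)
    return condition_torques(model, by_cond), by_cond


def roundtrip_validation(
    model,
    trials: list[SyntheticTrial],
    marker_cutoff: float = 15.0,
    pad_s: float = 0.25,
) -> dict:
    """Inverse->forward dynamics consistency of a session.

    Repetitions of each condition are averaged (angles aligned on movement
    onset, as in the torque pipeline), total torques are computed from the
    averaged trajectory, the arm is re-simulated forward from the same
    initial state over a window from ``pad_s`` before onset to ``pad_s``
    after end, and the coefficient of determination between simulated and
    original joint-angle trajectories is computed.  Returns per-condition
    R^2 (conditions x 4), per-joint R^2 pooled over conditions (so that
    conditions in which a joint barely moves do not produce a degenerate
    ratio of noise over noise), and their mean.
    """
    from .dynamics import forward_dynamics

    by_cond: dict = {}
    for tr in trials:
        markers = tr.markers
        fs = markers.fs
        if marker_cutoff:
            markers = MarkerFrameSeries(
                markers.time,
                {k: lowpass_fir(v, fs, marker_cutoff) for k, v in markers.positions.items()},
            )
        traj = compute_joint_angles(markers, model)
        _, events = endpoint_speed_events(markers.positions["endpoint"], fs)
        by_cond.setdefault(tr.condition, []).append((traj, events, fs))

    r2 = []
    for cond, items in by_cond.items():
        fs = items[0][2]
        sig = [np.vstack([t.q.T, t.shoulder_translation.T]) for t, _, _ in items]
        avg, ev = average_repetitions(sig, [e for _, e, _ in items], fs)
        i0 = max(int((ev.onset - pad_s) * fs), 0)
        i1 = min(int((ev.end + pad_s) * fs) + 1, avg.shape[1])
        q = avg[:4, i0:i1].T
        trans = avg[4:, i0:i1].T
        from .kinematics import JointTrajectory, differentiate

        traj = JointTrajectory(
            time=np.arange(q.shape[0]) / fs,
            q=q,
            qd=differentiate(q, fs),
            qdd=differentiate(q, fs, order=2),
            shoulder_translation=trans,
        )
        tot = inverse_dynamics(model, traj)
        sim = forward_dynamics(model, tot, traj.q[0], traj.qd[0], trans)
        sse = np.sum((sim.q - q) ** 2, axis=0)
        sst = np.sum((q - q.mean(axis=0)) ** 2, axis=0)
        r2.append((sse, sst))
    sse = np.array([x[0] for x in r2])
    sst = np.array([x[1] for x in r2])
    with np.errstate(divide="ignore", invalid="ignore"):
        per_condition = 1.0 - sse / sst
    per_joint = 1.0 - sse.sum(axis=0) / sst.sum(axis=0)
    return {
        "per_condition_r2": per_condition,
        "per_joint_r2": per_joint,
        "mean_r2": float(per_joint.mean()),
    }


def _dimensionality_block(
    trials: list[ProcessedTrial],
    method: str,
    seed: int,
    N_max: dict | None = None,
    n_shuffles: int = 50,
    criteria: tuple[str, ...] = ("threshold", "knee", "shuffle"),
    runs: int = 20,
    shuffle_runs: int = 5,
) -> tuple[dict, dict, dict]:
    dims, curves, sets_by_arr = {}, {}, {}
    defaults = {"spatial": None, "temporal": 12, "spatiotemporal": 12}
    for arr in ARRANGEMENTS:
        dm = build_matrix(trials, arr)
        nmax = (N_max or {}).get(arr, defaults[arr]) or dm.max_dim
        nmax = min(nmax, dm.max_dim)
        curve, sets = curve_for_method(dm, method, nmax, seed=seed, runs=runs)
        curves[arr] = curve.r2_by_N.tolist()
        sets_by_arr[arr] = (dm, sets)
        block = {}
        if "threshold" in criteria:
            block["threshold"] = select_threshold(curve).N_selected
        if "knee" in criteria:
            try:
                block["knee"] = select_knee(curve).N_selected
            except ValueError:
                block["knee"] = None  # inapplicable (curve too short)
        if "shuffle" in criteria:
            block["shuffle"] = select_shuffle(
                dm, method, nmax, n_shuffles=n_shuffles, seed=seed,
                runs=runs, shuffle_runs=shuffle_runs,
            ).N_selected
        dims[arr] = block
    return dims, curves, sets_by_arr


def run_torque_analysis(config: dict) -> AnalysisReport:
    """Full dynamic-torque dimensionality analysis of one session."""
    seed = int(config.get("seed", 0))
    profile = AnthropometricProfile(
        height=config.get("height_cm", 180.0),
        weight=config.get("weight_kg", 84.0),
        handle_mass=config.get("handle_mass_kg", 0.18),
    )
    model = estimate_segment_parameters(profile)
    if config.get("mass_scale") or config.get("height_scale"):
        model = perturb_model(
            profile,
            mass_scale=config.get("mass_scale", 1.0),
            height_scale=config.get("height_scale", 1.0),
        )

    if "trials" in config:
        trials = config["trials"]
    else:
        sess = SessionConfig(
            planes=tuple(config.get("planes", ("frontal", "sagittal"))),
            repetitions=int(config.get("repetitions", 5)),
            MT_nominal=float(config.get("MT_nominal", 0.35)),
            marker_noise_sd=float(config.get("marker_noise_sd", 0.001)),
            seed=seed,
        )
        trials, _ = generate_session(model, sess)

    processed, _ = torque_condition_trials(model, trials)
    dims, curves, sets_by_arr = _dimensionality_block(
        processed,
        "pca",
        seed,
        n_shuffles=int(config.get("n_shuffles", 50)),
    )

    # synchrony of the selected spatiotemporal generators
    dm_st, sets_st = sets_by_arr["spatiotemporal"]
    n_st = dims["spatiotemporal"]["shuffle"]
    sep = [
        separability_index(g.reshape(dm_st.D, dm_st.T))
        for g in sets_st[n_st - 1].generators.T
    ]

    return AnalysisReport(
        kind="torques",
        dimensionality=dims,
        r2_curves=curves,
        separability={"spatiotemporal": sep},
        extras={"n_conditions": len(processed)},
        seed=seed,
        config_hash=_hash_config({k: v for k, v in config.items() if k != "trials"}),
    )


def run_emg_analysis(config: dict) -> AnalysisReport:
    """Phasic muscle-pattern dimensionality analysis (NMF + criteria).

    The session is synthesized from the configured generator structure;
    tonic components are removed by constant-plus-ramp subtraction,
    negatives clipped for NMF, and the clipped-NMF vs unclipped-gradient-
    descent comparison is reported for the spatial arrangement.
    """
    seed = int(config.get("seed", 0))
    gen_cfg = {
        "arrangement": config.get("arrangement", "spatial"),
        "N": int(config.get("N", 4)),
        "D": int(config.get("D", 19)),
        "K": int(config.get("K", 32)),
        "noise": float(config.get("noise", 0.05)),
        "asynchronous": bool(config.get("asynchronous", False)),
    }
    trials, gt = generate_emg(seed=seed, **gen_cfg)

    drop = set(config.get("drop_channels", ()))
    phasic_trials, neg_ratios, unclipped = [], [], []
    for tr in trials:
        keep = [i for i, ch in enumerate(tr.channels) if ch not in drop]
        channels = [tr.channels[i] for i in keep]
        res = subtract_tonic(tr.values[keep], NORMALIZED_EVENTS, fs=1.0, clip=True)
        neg_ratios.append(res.negative_area_ratio)
        unclipped.append(res.unclipped)
        phasic_trials.append(
            ProcessedTrial(channels=channels, values=res.phasic, MT=tr.MT, condition=tr.condition)
        )

    runs = int(config.get("runs", 20))
    dims, curves, sets_by_arr = _dimensionality_block(
        phasic_trials,
        "nmf",
        seed,
        N_max={"spatial": min(10, len(phasic_trials[0].channels)), "temporal": 12, "spatiotemporal": 12},
        n_shuffles=int(config.get("n_shuffles", 50)),
        runs=runs,
    )

    extras = {
        "negative_area_ratio": float(np.mean(neg_ratios)),
        "ground_truth_N": gen_cfg["N"],
        "dropped_channels": sorted(drop),
        "n_channels": len(phasic_trials[0].channels),
    }

    if config.get("compare_clipping", True):
        arr = "spatial"
        dm, sets = sets_by_arr[arr]
        n_sel = dims[arr]["knee"] or dims[arr]["shuffle"]
        from .decomposition import DataMatrix, gd_fit

        uncl = np.stack(unclipped, axis=2)  # (D, T, K)
        from .decomposition import _stack

        dm_u = DataMatrix(arr, _stack(uncl, arr), dm.D, dm.T, dm.K, list(dm.channels))
        gd = gd_fit(dm_u, n_sel, seed=seed, runs=runs)
        extras["clipping_similarity"] = match_similarity(sets[n_sel - 1], gd)
        extras["clipping_N"] = n_sel

    sep = None
    dm_st, sets_st = sets_by_arr["spatiotemporal"]
    n_st = dims["spatiotemporal"]["shuffle"]
    sep = [
        separability_index(g.reshape(dm_st.D, dm_st.T))
        for g in sets_st[n_st - 1].generators.T
    ]

    return AnalysisReport(
        kind="emg",
        dimensionality=dims,
        r2_curves=curves,
        separability={"spatiotemporal": sep},
        extras=extras,
        seed=seed,
        config_hash=_hash_config(config),
    )
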