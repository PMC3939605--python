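"""Plain-text I/O: marker/EMG CSV dialects, subject JSON, reports.

Marker files have columns ``time, <marker>_x, <marker>_y, <marker>_z``
(meters, gravity-aligned frame); EMG files ``time`` plus one column per
muscle; subject profiles are small JSON/YAML mappings with ``height_cm``,
``weight_kg`` and optional ``handle_mass_kg``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arm import AnthropometricProfile
from .kinematics import MarkerFrameSeries
from .preprocessing import ProcessedTrial

__all__ = [
    "read_markers_csv",
    "write_markers_csv",
    "read_emg_csv",
    "write_emg_csv",
    "read_subject",
    "write_processed_trial",
    "read_processed_trial",
]

MARKERS = ("shoulder", "upper_arm", "elbow", "wrist_radial", "wrist_ulnar", "endpoint")


def write_markers_csv(path, markers: MarkerFrameSeries) -> None:
    cols = {"time": markers.time}
    for name, pos in markers.positions.items():
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = pos[:, j]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_markers_csv(path) -> MarkerFrameSeries:
    df = pd.read_csv(path)
    names = sorted({c[:-2] for c in df.columns if c.endswith(("_x", "_y", "_z"))})
    positions = {
        n: df[[f"{n}_x", f"{n}_y", f"{n}_z"]].to_numpy(float) for n in names
    }
    return MarkerFrameSeries(df["time"].to_numpy(float), positions)


def write_emg_csv(path, time: np.ndarray, values: np.ndarray, channels: list[str]) -> None:
    df = pd.DataFrame(values.T, columns=channels)
    df.insert(0, "time", time)
    df.to_csv(path, index=False)


def read_emg_csv(path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c != "time"]
    return df["time"].to_numpy(float), df[channels].to_numpy(float).T, channels


def read_subject(path) -> AnthropometricProfile:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return AnthropometricProfile(
        height=float(d["height_cm"]),
        weight=float(d["weight_kg"]),
        handle_mass=float(d.get("handle_mass_kg", 0.18)),
    )


def write_processed_trial(path, trial: ProcessedTrial) -> None:
    df = pd.DataFrame(trial.values.T, columns=trial.channels)
    meta = json.dumps({"condition": list(trial.condition), "MT": trial.MT})
    with open(path, "w") as fh:
        fh.write(f"# {meta}\n")
        df.to_csv(fh, index=False)


def read_processed_trial(path) -> ProcessedTrial:
    with open(path) as fh:
        meta = json.loads(fh.readline().lstrip("# "))
        df = pd.read_csv(fh)
    return ProcessedTrial(
        channels=list(df.columns),
        values=df.to_numpy(float).T,
        MT=float(meta.get("MT", 1.0)),
        condition=tuple(meta.get("condition", ())),
    )
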