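"""EMG and torque conditioning shared by both pipelines.

Raw EMG (1 kHz) is full-wave rectified, low-pass filtered with a
zero-phase FIR (20 Hz cutoff) and integrated over non-overlapping 10 ms
bins (100 Hz envelopes).  Repetitions of a condition are aligned on
movement onset and averaged; the tonic (anti-gravity) component is
removed by subtracting the pre-movement level, the post-movement level,
and a linear ramp between them during the movement; remaining negative
samples may be clipped to zero for non-negative factorization.  Finally
each condition average is normalized in time to 100 samples: 50 samples
per movement time (MT) plus half an MT of padding on each side, so that
sample 25 falls at movement onset and sample 75 at movement end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import MovementEvents, lowpass_fir

__all__ = [
    "ProcessedTrial",
    "PhasicResult",
    "preprocess_emg",
    "average_repetitions",
    "subtract_tonic",
    "time_normalize",
    "N_NORMALIZED_SAMPLES",
]

N_NORMALIZED_SAMPLES = 100
SAMPLES_PER_MT = 50

#: canonical muscle list (19 channels)
MUSCLES = (
    "BicShort", "BicLong", "Brac", "PronTer", "BrRad",
    "TrLat", "TrLong", "TrMed",
    "DeltA", "DeltM", "DeltP",
    "PectClav", "PectLow",
    "TrapSup", "TrapMid", "TrapInf",
    "LatDors", "TeresMaj", "InfraSp",
)


@dataclass
class ProcessedTrial:
    """One condition's channels x 100 matrix on the normalized time base."""

    channels: list[str]
    values: np.ndarray  # (D, 100)
    MT: float
    condition: tuple = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.channels), N_NORMALIZED_SAMPLES):
            raise ValueError(
                f"expected ({len(self.channels)}, {N_NORMALIZED_SAMPLES}) values, "
                f"got {self.values.shape}"
            )


@dataclass
class PhasicResult:
    """Phasic waveforms plus the fraction of (pre-clipping) negative area."""

    phasic: np.ndarray            # (D, S) clipped if requested
    unclipped: np.ndarray         # (D, S)
    negative_area_ratio: float


def preprocess_emg(
    raw: np.ndarray, fs: float = 1000.0, cutoff: float = 20.0, bin_ms: float = 10.0
) -> np.ndarray:
    """Rectify, low-pass filter and bin-integrate raw EMG.

    ``raw`` is channels x samples at 1 kHz; the output is channels x
    (samples/10) envelope values at 100 Hz (mean over each 10 ms bin).
    """
    if abs(fs - 1000.0) > 1e-9:
        raise ValueError("raw EMG must be sampled at 1 kHz")
    x = np.abs(np.asarray(raw, float))
    filt = lowpass_fir(x.T, fs, cutoff).T
    nbin = int(round(bin_ms * fs / 1000.0))
    nkeep = (filt.shape[1] // nbin) * nbin
    return filt[:, :nkeep].reshape(filt.shape[0], -1, nbin).mean(axis=2)


def average_repetitions(
    trials: list[np.ndarray],
    events: list[MovementEvents],
    fs: float,
) -> tuple[np.ndarray, MovementEvents]:
    """Average repeated trials of one condition, aligned on movement onset.

    Each trial (channels x samples) is shifted so that all onsets coincide;
    the overlapping support is averaged sample-wise.  Returns the average
    and events on the average's own time base (time 0 = first sample).
    """
    if not trials:
        raise ValueError("no trials to average")
    if len(trials) != len(events):
        raise ValueError("one MovementEvents per trial required")
    onset_idx = [int(round(ev.onset * fs)) for ev in events]
    pre = min(onset_idx)
    post = min(t.shape[1] - i for t, i in zip(trials, onset_idx))
    stack = np.stack([t[:, i - pre : i + post] for t, i in zip(trials, onset_idx)])
    avg = stack.mean(axis=0)
    mt = float(np.mean([ev.MT for ev in events]))
    return avg, MovementEvents(onset=pre / fs, end=pre / fs + mt)


def subtract_tonic(
    avg: np.ndarray,
    events: MovementEvents,
    fs: float,
    clip: bool = True,
    margin_s: float = 0.05,
) -> PhasicResult:
    """Remove the tonic component from a condition-average waveform.

    The tonic model is a constant level before movement onset, a constant
    level after movement end, and a linear ramp in between.  The two levels
    are the channel means over the padding windows, excluding ``margin_s``
    around the events.  The negative-area ratio (negative area over total
    absolute area, all channels pooled) is measured before clipping.
    """
    avg = np.asarray(avg, float)
    S = avg.shape[1]
    t = np.arange(S) / fs
    i_on, i_end = int(round(events.onset * fs)), int(round(events.end * fs))
    pad = 0.5 * events.MT
    slack = 2.0 / fs  # the normalized base ends 0.48 MT after movement end
    if events.onset < pad - slack - 1e-9 or (S - 1) / fs - events.end < pad - slack - 1e-9:
        raise ValueError("window must extend at least 0.5 MT beyond both events")
    m = int(round(margin_s * fs))
    pre_sl = slice(0, max(i_on - m, 1))
    post_sl = slice(min(i_end + m, S - 1), S)
    pre = avg[:, pre_sl].mean(axis=1)
    post = avg[:, post_sl].mean(axis=1)

    tonic = np.empty_like(avg)
    tonic[:, :i_on] = pre[:, None]
    tonic[:, i_end:] = post[:, None]
    ramp = (t[i_on:i_end] - t[i_on]) / max(t[i_end] - t[i_on], 1e-12)
    tonic[:, i_on:i_end] = pre[:, None] + (post - pre)[:, None] * ramp[None, :]

    phasic = avg - tonic
    neg = -phasic[phasic < 0].sum()
    total = np.abs(phasic).sum()
    # guard against a phasic residue that is pure floating-point dust
    floor = 1e-12 * max(np.abs(avg).sum(), 1e-300)
    ratio = float(neg / total) if total > floor else 0.0
    clipped = np.clip(phasic, 0.0, None) if clip else phasic
    return PhasicResult(phasic=clipped, unclipped=phasic, negative_area_ratio=ratio)


def time_normalize(
    avg: np.ndarray, events: MovementEvents, fs: float
) -> np.ndarray:
    """Resample a condition average to the normalized 100-sample time base.

    Linear interpolation from 0.5 MT before onset to 0.5 MT after end,
    50 samples per MT (100 samples total).
    """
    avg = np.asarray(avg, float)
    S = avg.shape[1]
    mt = events.MT
    t0, t1 = events.onset - 0.5 * mt, events.end + 0.5 * mt
    if t0 < -0.5 / fs or t1 > (S - 1) / fs + 0.5 / fs:
        raise ValueError("series does not cover [onset - 0.5 MT, end + 0.5 MT]")
    t = np.arange(S) / fs
    # 50 samples per MT: sample 25 falls on onset, sample 75 on end
    tn = t0 + np.arange(N_NORMALIZED_SAMPLES) * mt / SAMPLES_PER_MT
    tn = np.minimum(tn, t[-1])
    return np.vstack([np.interp(tn, t, row) for row in avg])
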