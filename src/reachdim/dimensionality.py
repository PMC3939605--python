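"""Selection of the number of generators.

Three criteria are provided:

* ``threshold`` -- smallest N whose R^2 reaches a fixed fraction of data
  variation (default 0.90), the convention used for torque generators.
* ``knee``      -- smallest N for which a linear fit of the R^2 curve
  from N to the end has mean squared error below 1e-4, i.e. the tail of
  the curve is essentially straight.  Used for muscle patterns; it needs
  at least three points in the tail, so it is inapplicable to very short
  curves (such as the 4-point spatial torque curve).
* ``shuffle``   -- noise-aware criterion: R^2 curves are extracted from
  row-shuffled surrogate data (low-pass filtered to match the smoothness
  of the original), and the selected N is the last point before the
  original curve's increment drops below 75% of the mean shuffled
  increment.  Applicable to both datasets because the surrogates inherit
  each dataset's intrinsic variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .decomposition import DataMatrix, RSquaredCurve, curve_for_method, unstack_matrix, _stack

__all__ = [
    "DimensionalityReport",
    "select_threshold",
    "select_knee",
    "select_shuffle",
]


@dataclass
class DimensionalityReport:
    criterion: str
    N_selected: int
    diagnostics: dict = field(default_factory=dict)


def select_threshold(curve: RSquaredCurve, threshold: float = 0.90) -> DimensionalityReport:
    """Smallest N explaining at least ``threshold`` of the data variation."""
    r2 = curve.r2_by_N
    idx = np.flatnonzero(r2 >= threshold)
    if idx.size:
        n, reached = int(idx[0]) + 1, True
    else:
        n, reached = len(r2), False
    return DimensionalityReport(
        "threshold", n, {"threshold": threshold, "reached": reached, "r2": r2.tolist()}
    )


def select_knee(curve: RSquaredCurve, mse_threshold: float = 1e-4) -> DimensionalityReport:
    """Smallest N whose R^2-curve tail (N to the end) is essentially straight."""
    r2 = curve.r2_by_N
    if len(r2) < 3:
        raise ValueError("knee criterion inapplicable: curve has fewer than 3 points")
    mses = {}
    selected = None
    for n in range(1, len(r2) - 1):  # tail must keep >= 3 points
        xs = np.arange(n, len(r2) + 1, dtype=float)
        ys = r2[n - 1 :]
        coef = np.polyfit(xs, ys, 1)
        mse = float(np.mean((np.polyval(coef, xs) - ys) ** 2))
        mses[n] = mse
        if selected is None and mse < mse_threshold:
            selected = n
    found = selected is not None
    if not found:
        selected = len(r2)
    return DimensionalityReport(
        "knee", selected, {"tail_fit_mse": mses, "found": found, "threshold": mse_threshold}
    )


def _row_shuffle(X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        out[i] = X[i, rng.permutation(X.shape[1])]
    return out


def _rolloff_cutoff(values: np.ndarray, power_fraction: float = 0.95) -> float:
    """Normalized frequency below which ``power_fraction`` of the non-DC
    power of the average per-channel spectrum lies (Nyquist = 0.5)."""
    D, T, K = values.shape
    x = values - values.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    psd = spec.mean(axis=(0, 2))
    psd[0] = 0.0
    total = psd.sum()
    if total <= 0:
        return 0.5
    cum = np.cumsum(psd) / total
    freqs = np.fft.rfftfreq(T)
    return float(freqs[np.searchsorted(cum, power_fraction)])


def _smooth_like(dm: DataMatrix, shuffled: np.ndarray, cutoff: float) -> np.ndarray:
    """Low-pass filter a shuffled matrix along the time axis of its trials."""
    if cutoff >= 0.45:  # already as broadband as white noise: nothing to match
        return shuffled
    vals = unstack_matrix(dm, shuffled)
    b, a = signal.butter(4, cutoff / 0.5)
    vals = signal.filtfilt(b, a, vals, axis=1)
    if np.all(dm.matrix >= 0):
        vals = np.clip(vals, 0.0, None)
    return _stack(vals, dm.arrangement)


def select_shuffle(
    data: DataMatrix,
    method: str,
    N_max: int,
    n_shuffles: int = 50,
    fraction: float = 0.75,
    seed: int = 0,
    per_N: bool = True,
    runs: int = 20,
    shuffle_runs: int = 5,
) -> DimensionalityReport:
    """Shuffle-null criterion for the number of generators.

    Rows of the data matrix are independently permuted across columns,
    smoothness-matched by low-pass filtering, and decomposed with the same
    method; the selected N is the last point before the original curve's
    increment R^2(N) -> R^2(N+1) falls below ``fraction`` times the mean
    shuffled increment (per-N by default, pooled over N otherwise).
    ``shuffle_runs`` restarts are used for the surrogate extractions (the
    original curve uses ``runs``).
    """
    if n_shuffles < 2:
        raise ValueError("need at least 2 shuffles")
    curve, _ = curve_for_method(data, method, N_max, seed=seed, runs=runs)
    cutoff = _rolloff_cutoff(unstack_matrix(data))
    rng = np.random.default_rng(seed)
    null_curves = []
    for s in range(n_shuffles):
        Xs = _row_shuffle(data.matrix, rng)
        Xs = _smooth_like(data, Xs, cutoff)
        dm_s = DataMatrix(data.arrangement, Xs, data.D, data.T, data.K, list(data.channels))
        c, _ = curve_for_method(dm_s, method, N_max, seed=seed + 7919 * (s + 1), runs=shuffle_runs)
        null_curves.append(c.r2_by_N)
    null = np.array(null_curves)

    inc = np.diff(curve.r2_by_N)
    null_inc = np.diff(null, axis=1).mean(axis=0)
    ref = null_inc if per_N else np.full_like(null_inc, null_inc.mean())
    below = inc < fraction * ref
    idx = np.flatnonzero(below)
    n = int(idx[0]) + 1 if idx.size else N_max
    return DimensionalityReport(
        "shuffle",
        n,
        {
            "r2": curve.r2_by_N.tolist(),
            "null_r2_mean": null.mean(axis=0).tolist(),
            "increments": inc.tolist(),
            "null_increments": null_inc.tolist(),
            "fraction": fraction,
            "smoothing_cutoff": cutoff,
        },
    )
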