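"""Comparison of generator sets across datasets.

Generators identified in one dataset are tested on another by re-fitting
only the combination coefficients (ordinary least squares for signed PCA
generators, non-negative least squares for NMF generators) and measuring
the reconstruction R^2.  Significance comes from a Monte-Carlo null:
generators extracted from row-shuffled data reconstruct the original
data, and the 95th percentile of those R^2 values is the chance level.
Structural similarity between two sets of generators is the mean
normalized scalar product over optimally matched pairs, and the
synchrony of a spatiotemporal generator is measured by how much of its
energy a rank-1 (waveform x weight-vector) approximation captures.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment, nnls

from .decomposition import DataMatrix, GeneratorSet, curve_for_method, r_squared
from .dimensionality import _row_shuffle, select_shuffle

__all__ = [
    "cross_reconstruct",
    "monte_carlo_null",
    "match_similarity",
    "separability_index",
    "crosstalk_simulation",
]


def cross_reconstruct(generators: GeneratorSet, data: DataMatrix) -> float:
    """R^2 of the target data reconstructed by a fixed generator set.

    Coefficients are re-fitted to the target: least squares (with the
    target's row-mean offset) for signed generators, non-negative least
    squares on the raw data for NMF generators.
    """
    if generators.arrangement != data.arrangement:
        raise ValueError("arrangement mismatch")
    G = generators.generators
    X = data.matrix
    if G.shape[0] != X.shape[0]:
        raise ValueError("row-dimension mismatch between generators and data")
    if generators.method == "nmf":
        C = np.column_stack([nnls(G, X[:, j])[0] for j in range(X.shape[1])])
        rec = G @ C
    else:
        mean = X.mean(axis=1)
        C, *_ = np.linalg.lstsq(G, X - mean[:, None], rcond=None)
        rec = mean[:, None] + G @ C
    return r_squared(X, rec)


def monte_carlo_null(
    data: DataMatrix,
    method: str,
    N: int,
    runs: int = 50,
    seed: int = 0,
    extraction_runs: int = 5,
) -> float:
    """95th percentile of R^2 for reconstructing the data with generators
    identified from row-shuffled surrogates."""
    if runs < 20:
        raise ValueError("need at least 20 Monte-Carlo runs")
    rng = np.random.default_rng(seed)
    vals = []
    for r in range(runs):
        Xs = _row_shuffle(data.matrix, rng)
        dm_s = DataMatrix(data.arrangement, Xs, data.D, data.T, data.K, list(data.channels))
        _, sets = curve_for_method(dm_s, method, N, seed=seed + 7919 * (r + 1), runs=extraction_runs)
        vals.append(cross_reconstruct(sets[N - 1], data))
    return float(np.percentile(vals, 95))


def _abs_cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.maximum(np.linalg.norm(A, axis=0), 1e-300)
    Bn = B / np.maximum(np.linalg.norm(B, axis=0), 1e-300)
    return np.abs(An.T @ Bn)


def match_similarity(setA: GeneratorSet, setB: GeneratorSet) -> float:
    """Mean normalized scalar product over optimally matched generator pairs.

    Pairing maximizes the total |cosine| over all permutations (optimal
    assignment); invariant to sign flips and positive rescaling.
    """
    if setA.arrangement != setB.arrangement:
        raise ValueError("arrangement mismatch")
    if setA.N != setB.N:
        raise ValueError("generator sets must have the same N")
    S = _abs_cosine_matrix(setA.generators, setB.generators)
    if setA.N <= 8:
        best = max(sum(S[i, p[i]] for i in range(setA.N)) for p in permutations(range(setA.N)))
    else:
        ri, ci = linear_sum_assignment(-S)
        best = S[ri, ci].sum()
    return float(best / setA.N)


def separability_index(generator: np.ndarray) -> float:
    """Fraction of a D x T generator's squared norm captured by its best
    rank-1 (synchronous) approximation: sigma_1^2 / sum(sigma_i^2)."""
    G = np.asarray(generator, float)
    s = np.linalg.svd(G, compute_uv=False)
    total = float((s**2).sum())
    if total <= 0:
        raise ValueError("zero generator matrix")
    return float(s[0] ** 2 / total)


def crosstalk_simulation(
    data: DataMatrix,
    method: str = "nmf",
    runs: int = 100,
    mean_alpha: float = 0.1,
    seed: int = 0,
    N_max: int | None = None,
    extraction_runs: int = 20,
    **shuffle_kwargs,
) -> dict:
    """Effect of simulated EMG cross-talk on the estimated dimensionality.

    Per run, every channel (row) i receives a contamination
    ``X'_i = X_i + alpha * X_j`` from one uniformly chosen other row,
    with alpha drawn from an exponential distribution of mean
    ``mean_alpha``; the shuffle-criterion dimensionality of X' is then
    compared with that of the uncontaminated matrix.
    """
    X = data.matrix
    if X.shape[0] < 2:
        raise ValueError("cross-talk needs at least two channels")
    if np.any(X < 0):
        raise ValueError("cross-talk simulation expects non-negative data")
    if N_max is None:
        N_max = min(data.max_dim, 10)
    base = select_shuffle(
        data, method, N_max, seed=seed, runs=extraction_runs, **shuffle_kwargs
    ).N_selected
    rng = np.random.default_rng(seed)
    diffs = []
    for r in range(runs):
        Xc = X.copy()
        for i in range(X.shape[0]):
            j = rng.integers(0, X.shape[0] - 1)
            j = j + (j >= i)
            alpha = rng.exponential(mean_alpha) if mean_alpha > 0 else 0.0
            Xc[i] = X[i] + alpha * X[j]
        dm_c = DataMatrix(data.arrangement, Xc, data.D, data.T, data.K, list(data.channels))
        n = select_shuffle(
            dm_c, method, N_max, seed=seed + 104729 * (r + 1), runs=extraction_runs, **shuffle_kwargs
        ).N_selected
        diffs.append(n - base)
    diffs = np.asarray(diffs)
    return {
        "baseline_N": base,
        "differences": diffs.tolist(),
        "changed_fraction": float(np.mean(diffs != 0)),
    }
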