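"""Multidimensional decomposition of multichannel trial data.

Condition-wise channels x time trials are arranged into one of three data
matrices and factorized into generators times combination coefficients:

* ``spatial``        -- X is D x (T*K): time-invariant channel-weight
  vectors (synergies) with time- and condition-dependent coefficients.
* ``temporal``       -- X is T x (D*K): condition-independent waveforms
  with channel- and condition-dependent weights.
* ``spatiotemporal`` -- X is (D*T) x K: channels x time patterns scaled
  by one coefficient per condition.

Torque-like (signed) data are decomposed with PCA; non-negative muscle
patterns with NMF (multiplicative updates, best of 20 random restarts);
signed phasic patterns may also be factorized by an alternating gradient
descent with a penalty on negative synergy values, used to gauge the
effect of clipping.  Goodness of fit is R^2 = 1 - SSE/SST with SST taken
about the row means of the data matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ProcessedTrial

__all__ = [
    "DataMatrix",
    "GeneratorSet",
    "RSquaredCurve",
    "build_matrix",
    "unstack_matrix",
    "r_squared",
    "pca_curve",
    "nmf_fit",
    "gd_fit",
    "plane_cone_r2",
]

ARRANGEMENTS = ("spatial", "temporal", "spatiotemporal")


@dataclass
class DataMatrix:
    """One arrangement of D channels x T samples x K conditions."""

    arrangement: str
    matrix: np.ndarray
    D: int
    T: int
    K: int
    channels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        expected = {
            "spatial": (self.D, self.T * self.K),
            "temporal": (self.T, self.D * self.K),
            "spatiotemporal": (self.D * self.T, self.K),
        }[self.arrangement]
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != expected:
            raise ValueError(f"{self.arrangement} matrix must be {expected}, got {self.matrix.shape}")
        if not np.isfinite(self.matrix).all():
            raise ValueError("data matrix contains non-finite values")

    @property
    def max_dim(self) -> int:
        return min(self.matrix.shape)


@dataclass
class GeneratorSet:
    """N generators plus combination coefficients for one arrangement.

    ``reconstruction = offset[:, None] + generators @ coefficients``;
    the offset is the row-mean vector for PCA and zero otherwise.
    """

    arrangement: str
    N: int
    generators: np.ndarray    # rows x N
    coefficients: np.ndarray  # N x cols
    method: str               # pca | nmf | gd
    r2: float
    offset: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        rec = self.generators @ self.coefficients
        if self.offset is not None:
            rec = rec + self.offset[:, None]
        return rec


@dataclass
class RSquaredCurve:
    """R^2 as a function of the number of generators N = 1..N_max."""

    r2_by_N: np.ndarray

    def __post_init__(self) -> None:
        self.r2_by_N = np.asarray(self.r2_by_N, float)

    def __len__(self) -> int:
        return len(self.r2_by_N)


def _stack(values: np.ndarray, arrangement: str) -> np.ndarray:
    """(D, T, K) -> data matrix of the requested arrangement."""
    D, T, K = values.shape
    if arrangement == "spatial":
        # columns: condition-major, time within condition
        return values.transpose(0, 2, 1).reshape(D, K * T)
    if arrangement == "temporal":
        # columns: condition-major, channel within condition
        return values.transpose(1, 2, 0).reshape(T, K * D)
    # spatiotemporal: one column per condition, channel-major flatten
    return values.transpose(0, 1, 2).reshape(D * T, K)


def build_matrix(trials: list[ProcessedTrial], arrangement: str) -> DataMatrix:
    """Arrange processed trials (one per condition) into a data matrix."""
    if not trials:
        raise ValueError("no trials")
    channels = trials[0].channels
    T = trials[0].values.shape[1]
    for tr in trials:
        if tr.channels != channels or tr.values.shape[1] != T:
            raise ValueError("all trials must share channels and sample count")
    values = np.stack([tr.values for tr in trials], axis=2)  # (D, T, K)
    return DataMatrix(
        arrangement=arrangement,
        matrix=_stack(values, arrangement),
        D=len(channels),
        T=T,
        K=len(trials),
        channels=list(channels),
    )


def unstack_matrix(dm: DataMatrix, matrix: np.ndarray | None = None) -> np.ndarray:
    """Inverse of :func:`build_matrix`: data matrix -> (D, T, K) array."""
    X = dm.matrix if matrix is None else np.asarray(matrix, float)
    D, T, K = dm.D, dm.T, dm.K
    if dm.arrangement == "spatial":
        return X.reshape(D, K, T).transpose(0, 2, 1)
    if dm.arrangement == "temporal":
        return X.reshape(T, K, D).transpose(2, 0, 1)
    return X.reshape(D, T, K)


def r_squared(data: np.ndarray, reconstruction: np.ndarray) -> float:
    """1 - SSE/SST with SST about the row means of ``data``."""
    X = np.asarray(data, float)
    R = np.asarray(reconstruction, float)
    if X.shape != R.shape:
        raise ValueError("data and reconstruction must have the same shape")
    sst = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
    if sst <= 0:
        raise ValueError("zero total variation: all rows constant")
    sse = float(((X - R) ** 2).sum())
    return 1.0 - sse / sst


def pca_curve(
    data: DataMatrix, N_max: int | None = None
) -> tuple[RSquaredCurve, list[GeneratorSet]]:
    """Principal-component decomposition for N = 1..N_max.

    Generators are the leading eigenvectors of the row covariance (sign
    fixed so the largest-magnitude element is positive); coefficients are
    projections of the row-mean-centered data, and the reconstruction
    includes the row-mean offset so that R^2(0) = 0.
    """
    X = data.matrix
    if N_max is None:
        N_max = data.max_dim
    if not 1 <= N_max <= X.shape[0]:
        raise ValueError("N_max must be between 1 and the number of rows")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|.| element of each generator positive
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    ev = s**2
    sst = ev.sum()
    r2 = np.cumsum(ev)[:N_max] / sst
    sets = []
    for N in range(1, N_max + 1):
        G = U[:, :N]
        C = s[:N, None] * Vt[:N]
        sets.append(
            GeneratorSet(
                arrangement=data.arrangement,
                N=N,
                generators=G,
                coefficients=C,
                method="pca",
                r2=float(r2[N - 1]),
                offset=mean,
            )
        )
    return RSquaredCurve(r2), sets


def _terminated(history: list[float], tol: float = 1e-4, run: int = 5) -> bool:
    if len(history) < run + 1:
        return False
    recent = np.diff(history[-(run + 1):])
    return bool(np.all(recent < tol))


def nmf_fit(
    data: DataMatrix,
    N: int,
    runs: int = 20,
    seed: int = 0,
    max_iter: int = 1000,
) -> GeneratorSet:
    """Non-negative matrix factorization, best of ``runs`` random restarts.

    Multiplicative updates on the squared Frobenius error; each run stops
    once the R^2 gain per iteration stays below 1e-4 for five consecutive
    iterations.  Generators are rescaled to unit norm (coefficients
    compensated).  Run r uses seed + r.
    """
    X = data.matrix
    if np.any(X < 0):
        raise ValueError("NMF requires non-negative data: clip negative values first")
    if N < 1:
        raise ValueError("N must be >= 1")
    eps = 1e-12
    best = None
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        W = rng.random((X.shape[0], N)) + 0.1
        H = rng.random((N, X.shape[1])) + 0.1
        hist = []
        for _ in range(max_iter):
            H *= (W.T @ X) / (W.T @ W @ H + eps)
            W *= (X @ H.T) / (W @ H @ H.T + eps)
            hist.append(r_squared(X, W @ H))
            if _terminated(hist):
                break
        if best is None or hist[-1] > best[0]:
            best = (hist[-1], W, H)
    r2, W, H = best
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return GeneratorSet(
        arrangement=data.arrangement,
        N=N,
        generators=W / norms,
        coefficients=H * norms[:, None],
        method="nmf",
        r2=float(r2),
    )


# per-arrangement gradient step sizes: (generators/synergies, coefficients/weights)
_GD_STEPS = {
    "spatial": (0.0005, 0.05),
    "spatiotemporal": (0.0005, 0.05),
    "temporal": (0.0019, 0.0018),
}


def gd_fit(
    data: DataMatrix,
    N: int,
    seed: int = 0,
    runs: int = 20,
    penalty: float = 1.0,
    max_iter: int = 4000,
    step_scale: float = 8.0,
) -> GeneratorSet:
    """Alternating gradient descent factorization allowing signed data.

    Minimizes the squared reconstruction error with fixed per-arrangement
    step sizes, plus ``penalty * sum(min(0, W)^2)`` discouraging negative
    synergy values in the spatial and spatiotemporal cases.  The data are
    scaled to unit maximum absolute value and the generators re-normalized
    to unit columns after every update (coefficients compensated), which
    keeps the negativity penalty meaningful -- without the projection the
    optimizer can evade it by shrinking the generators and growing the
    coefficients.  ``step_scale`` adapts the step sizes to the unit data
    scale; its default was selected, like the step sizes themselves, as
    the value giving the highest reconstruction R^2 short of divergence.
    Same restart count and termination rule as :func:`nmf_fit`.
    """
    X = data.matrix
    if N < 1:
        raise ValueError("N must be >= 1")
    scale = np.max(np.abs(X))
    if scale == 0:
        raise ValueError("all-zero data matrix")
    Xs = X / scale
    eta_w, eta_c = (s * step_scale for s in _GD_STEPS[data.arrangement])
    penalize = data.arrangement in ("spatial", "spatiotemporal")
    best = None
    for r in range(runs):
        rng = np.random.default_rng(seed + r)
        W = np.abs(rng.normal(0.0, 0.3, (X.shape[0], N))) + 0.1
        W /= np.linalg.norm(W, axis=0)
        C = rng.normal(0, 0.3, (N, X.shape[1]))
        hist, errs, rises = [], [], 0
        for _ in range(max_iter):
            E = Xs - W @ C
            C = C + eta_c * (W.T @ E)
            E = Xs - W @ C
            gradW = -(E @ C.T)
            if penalize:
                gradW = gradW + penalty * np.minimum(W, 0.0)
            W = W - eta_w * gradW
            norms = np.linalg.norm(W, axis=0)
            norms[norms == 0] = 1.0
            W = W / norms
            C = C * norms[:, None]
            err = float(((Xs - W @ C) ** 2).sum())
            if not np.isfinite(err):
                raise RuntimeError(
                    "gradient descent diverged; reduce step_scale"
                )
            if errs and err > errs[-1]:
                rises += 1
                if rises >= 100:
                    raise RuntimeError(
                        "gradient descent diverging: error increased for 100 "
                        "consecutive iterations; reduce step sizes"
                    )
            else:
                rises = 0
            errs.append(err)
            hist.append(r_squared(Xs, W @ C))
            if _terminated(hist):
                break
        if best is None or hist[-1] > best[0]:
            best = (hist[-1], W, C)
    r2, W, C = best
    return GeneratorSet(
        arrangement=data.arrangement,
        N=N,
        generators=W,
        coefficients=C * scale,
        method="gd",
        r2=float(r2),
    )


def curve_for_method(
    data: DataMatrix,
    method: str,
    N_max: int,
    seed: int = 0,
    runs: int = 20,
) -> tuple[RSquaredCurve, list[GeneratorSet]]:
    """R^2 curve (and generator sets) for PCA, NMF, or gradient descent."""
    if method == "pca":
        curve, sets = pca_curve(data, N_max)
        return curve, sets
    fit = {"nmf": nmf_fit, "gd": gd_fit}[method]
    sets = [fit(data, N, seed=seed + 1000 * N, runs=runs) for N in range(1, N_max + 1)]
    return RSquaredCurve(np.array([g.r2 for g in sets])), sets


# --- minimal non-negative spanning set (the N_tau + 1 bound) ---------------

def _best_nonneg_residual(x: np.ndarray, G: np.ndarray) -> float:
    """Exact 2-D non-negative least-squares residual of x against columns of G."""
    best = float(x @ x)  # zero reconstruction
    n = G.shape[1]
    for i in range(n):
        g = G[:, i]
        c = max(0.0, float(x @ g))
        r = x - c * g
        best = min(best, float(r @ r))
    for i in range(n):
        for j in range(i + 1, n):
            A = G[:, [i, j]]
            det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
            if abs(det) < 1e-12:
                continue
            c = np.linalg.solve(A.T @ A, A.T @ x)
            if c[0] >= 0 and c[1] >= 0:
                return 0.0  # inside the cone: exact
    return best


def plane_cone_r2(
    directions: np.ndarray, N: int, angle_step_deg: float = 7.5
) -> float:
    """Best achievable R^2 reconstructing signed 2-D data with N
    non-negatively combined unit generators, by brute force over a grid of
    generator angles.

    Because muscle-like generators can only be combined with non-negative
    coefficients, spanning a full 2-D signed plane requires at least 3 of
    them; with 2 the reconstruction of directions outside their cone
    degrades.  ``directions`` is 2 x K.
    """
    X = np.asarray(directions, float)
    if X.shape[0] != 2:
        raise ValueError("directions must be 2 x K")
    angles = np.deg2rad(np.arange(0.0, 360.0, angle_step_deg))
    sst = float(((X - X.mean(axis=1, keepdims=True)) ** 2).sum())
    from itertools import combinations

    best = -np.inf
    for combo in combinations(range(len(angles)), N):
        G = np.vstack([np.cos(angles[list(combo)]), np.sin(angles[list(combo)])])
        sse = sum(_best_nonneg_residual(X[:, k], G) for k in range(X.shape[1]))
        best = max(best, 1.0 - sse / sst)
        if best >= 1.0 - 1e-12:
            return float(best)
    return float(best)
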