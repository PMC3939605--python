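"""Data-matrix arrangements and PCA/NMF/gradient-descent factorization."""

import numpy as np
import pytest

from reachdim import (
    DataMatrix,
    ProcessedTrial,
    build_matrix,
    gd_fit,
    nmf_fit,
    pca_curve,
    plane_cone_r2,
    r_squared,
    unstack_matrix,
)
from reachdim.decomposition import _stack, curve_for_method


def _trials(D, K, rng, channels=None, nonneg=False):
    channels = channels or [f"c{i}" for i in range(D)]
    vals = rng.standard_normal((D, 100, K))
    if nonneg:
        vals = np.abs(vals)
    return [
        ProcessedTrial(channels=channels, values=vals[:, :, k], MT=1.0, condition=(k,))
        for k in range(K)
    ], vals


class TestDataMatrix:
    def test_arrangement_shapes(self, rng):
        trials, _ = _trials(4, 32, rng)
        assert build_matrix(trials, "spatial").matrix.shape == (4, 3200)
        assert build_matrix(trials, "temporal").matrix.shape == (100, 128)
        assert build_matrix(trials, "spatiotemporal").matrix.shape == (400, 32)

    def test_unstack_inverts_build(self, rng):
        trials, vals = _trials(5, 7, rng)
        for arr in ("spatial", "temporal", "spatiotemporal"):
            dm = build_matrix(trials, arr)
            assert np.array_equal(unstack_matrix(dm), vals)

    def test_inconsistent_channels_rejected(self, rng):
        trials, _ = _trials(3, 2, rng)
        bad = ProcessedTrial(["x", "y", "z"], trials[0].values, 1.0)
        with pytest.raises(ValueError):
            build_matrix([trials[0], bad], "spatial")


class TestRSquared:
    def test_perfect_and_rowmean_reconstructions(self, rng):
        X = rng.standard_normal((6, 40))
        assert r_squared(X, X) == pytest.approx(1.0)
        rowmeans = np.tile(X.mean(axis=1, keepdims=True), (1, 40))
        assert r_squared(X, rowmeans) == pytest.approx(0.0, abs=1e-12)

    def test_manual_2x2_case(self):
        # X = [[1, 2], [3, 5]]; row means 1.5, 4 -> SST = 2.5
        # reconstruction [[1, 2], [3, 4]] -> SSE = 1 -> R^2 = 0.6
        X = np.array([[1.0, 2.0], [3.0, 5.0]])
        R = np.array([[1.0, 2.0], [3.0, 4.0]])
        assert r_squared(X, R) == pytest.approx(0.6)

    def test_constant_rows_rejected(self):
        with pytest.raises(ValueError):
            r_squared(np.ones((2, 5)), np.ones((2, 5)))


class TestPCA:
    def test_exact_low_rank(self, rng):
        W = rng.standard_normal((8, 2))
        C = rng.standard_normal((2, 50))
        dm = DataMatrix("spatial", W @ C, 8, 10, 5)
        curve, sets = pca_curve(dm, 5)
        assert curve.r2_by_N[1] == pytest.approx(1.0, abs=1e-9)
        assert r_squared(dm.matrix, sets[1].reconstruct()) == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_reaches_one(self, rng):
        X = rng.standard_normal((6, 60))
        dm = DataMatrix("spatial", X, 6, 10, 6)
        curve, _ = pca_curve(dm, 6)
        assert curve.r2_by_N[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(curve.r2_by_N) >= -1e-12)  # monotone

    def test_increments_equal_eigenvalue_shares(self, rng):
        """R^2 increments equal the normalized eigenvalues of the row
        covariance (eigendecomposition oracle)."""
        X = np.random.default_rng(5).standard_normal((7, 90))
        dm = DataMatrix("spatial", X, 7, 10, 9)
        curve, _ = pca_curve(dm, 7)
        Xc = X - X.mean(axis=1, keepdims=True)
        ev = np.sort(np.linalg.eigvalsh(Xc @ Xc.T))[::-1]
        inc = np.diff(np.concatenate([[0.0], curve.r2_by_N]))
        assert np.allclose(inc, ev / ev.sum(), atol=1e-9)

    def test_generator_sign_convention(self, rng):
        X = rng.standard_normal((5, 50))
        _, sets = pca_curve(DataMatrix("spatial", X, 5, 10, 5), 3)
        for g in sets[-1].generators.T:
            assert g[np.argmax(np.abs(g))] > 0


class TestNMF:
    def test_rank1_nonnegative_data(self, rng):
        w = rng.random(6) + 0.1
        c = rng.random(40) + 0.1
        dm = DataMatrix("spatial", np.outer(w, c), 6, 10, 4)
        out = nmf_fit(dm, 1, runs=5, seed=0)
        assert out.r2 >= 0.999
        assert np.all(out.generators >= 0)
        assert np.all(out.coefficients >= 0)

    def test_negative_data_rejected(self):
        dm = DataMatrix("spatial", np.array([[1.0, -0.1], [0.2, 0.3]]), 2, 1, 2)
        with pytest.raises(ValueError, match="clip"):
            nmf_fit(dm, 1)

    def test_unit_norm_generators(self, rng):
        X = np.abs(rng.standard_normal((8, 60)))
        out = nmf_fit(DataMatrix("spatial", X, 8, 10, 6), 3, runs=3, seed=1)
        assert np.allclose(np.linalg.norm(out.generators, axis=0), 1.0, atol=1e-9)

    def test_multiplicative_updates_never_increase_error(self, rng):
        """Lee-Seung multiplicative updates are monotone in the Frobenius
        objective; checked directly on the update rule."""
        X = np.abs(rng.standard_normal((10, 40))) + 0.01
        W = rng.random((10, 3)) + 0.1
        H = rng.random((3, 40)) + 0.1
        eps = 1e-12
        prev = np.inf
        for _ in range(50):
            H *= (W.T @ X) / (W.T @ W @ H + eps)
            W *= (X @ H.T) / (W @ H @ H.T + eps)
            err = ((X - W @ H) ** 2).sum()
            assert err <= prev + 1e-10
            prev = err

    def test_matches_sklearn_reconstruction_error(self, rng):
        """Best-of-restarts multiplicative NMF reaches a reconstruction at
        least as good as scikit-learn's NMF on the same small matrix."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = np.abs(rng.standard_normal((9, 30))) + 0.01
        dm = DataMatrix("spatial", X, 9, 10, 3)
        ours = nmf_fit(dm, 3, runs=10, seed=2)
        ref = sklearn.NMF(3, init="random", random_state=0, max_iter=2000, tol=1e-10).fit(X)
        err_ref = ref.reconstruction_err_ ** 2
        err_ours = ((X - ours.reconstruct()) ** 2).sum()
        assert err_ours <= err_ref * 1.10

    def test_best_of_runs_curve_nearly_monotone(self, rng):
        X = np.abs(rng.standard_normal((6, 80)))
        dm = DataMatrix("spatial", X, 6, 10, 8)
        curve, _ = curve_for_method(dm, "nmf", 5, seed=3, runs=5)
        assert np.all(np.diff(curve.r2_by_N) >= -1e-3)


class TestGradientDescent:
    def test_signed_rank1_without_penalty(self, rng):
        w = rng.standard_normal(6)
        c = rng.standard_normal(40)
        dm = DataMatrix("spatial", np.outer(w, c), 6, 10, 4)
        out = gd_fit(dm, 1, seed=0, runs=5, penalty=0.0)
        assert out.r2 >= 0.999

    def test_consistent_with_nmf_on_nonnegative_rank1(self, rng):
        w = rng.random(6) + 0.1
        c = rng.random(40) + 0.1
        dm = DataMatrix("spatial", np.outer(w, c), 6, 10, 4)
        out_gd = gd_fit(dm, 1, seed=0, runs=5)
        out_nmf = nmf_fit(dm, 1, runs=5, seed=0)
        assert abs(out_gd.r2 - out_nmf.r2) < 0.01

    def test_temporal_arrangement_step_sizes(self, rng):
        X = rng.standard_normal((30, 24))
        dm = DataMatrix("temporal", X, 4, 30, 6)
        out = gd_fit(dm, 2, seed=1, runs=3)
        assert out.generators.shape == (30, 2)
        assert out.r2 > 0.0


class TestNonNegativeSpanBound:
    def test_two_generators_cannot_span_signed_plane_three_can(self):
        """Muscle-like generators combine with non-negative coefficients,
        so spanning a full 2-D signed torque plane needs at least 3 of
        them (the N_tau + 1 bound); brute-force search over generator
        angles confirms both sides."""
        K = 16
        phis = 2 * np.pi * np.arange(K) / K
        X = np.vstack([np.cos(phis), np.sin(phis)])
        assert plane_cone_r2(X, 2) < 0.99
        assert plane_cone_r2(X, 3) >= 0.99
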