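"""Proximal gradient descent solver against closed-form and brute-force oracles."""

import itertools

import numpy as np
import pytest

import spirecon as sr
from spirecon.recon_classical import (ReconSpec, gradient_step, initialize,
                                      least_squares_oracle, objective,
                                      pgd_reconstruct, prox_step, spectral_bound)


class TestInitialize:
    def test_zero_measurement_gives_zero_image(self, small_op, small_scene):
        rec = sr.measure(small_op, sr.ImageScene(np.zeros((4, 4))))
        assert np.all(initialize(rec, small_op) == 0)

    def test_square_hadamard_inverts_exactly(self, rng):
        op = sr.hadamard_operator(4)
        x = rng.random((4, 4))
        rec = sr.measure(op, sr.ImageScene(x))
        assert np.allclose(initialize(rec, op), x, atol=1e-13)

    def test_matches_transpose_multiply_oracle(self, rng):
        op = sr.random_operator(8, 4, 4, seed=5)
        rec = sr.measure(op, sr.ImageScene(rng.random((4, 4))))
        oracle = np.zeros(16)
        for j in range(16):
            for i in range(8):
                oracle[j] += op.values[i, j] * rec.values[i]
        assert np.allclose(initialize(rec, op).reshape(-1), oracle, atol=1e-12)


class TestGradientStep:
    def test_consistent_estimate_is_fixed_point(self, small_op, small_scene):
        x = small_scene.flatten()
        y = small_op.values @ x
        z = gradient_step(x, y, small_op.values, rho=0.8)
        assert np.allclose(z, x, atol=1e-12)

    def test_zero_step_size_is_identity(self, small_op, small_scene, rng):
        x = rng.random(16)
        y = small_op.values @ small_scene.flatten()
        assert np.array_equal(gradient_step(x, y, small_op.values, 0.0), x)

    def test_matches_elementwise_oracle(self, small_op, rng):
        x = rng.random(16)
        y = rng.random(12)
        rho = 0.3
        a = small_op.values
        oracle = x - rho * np.array([
            sum(a[i, j] * (a[i] @ x - y[i]) for i in range(12)) for j in range(16)
        ])
        assert np.allclose(gradient_step(x, y, a, rho), oracle, atol=1e-12)


class TestProx:
    def test_l1_soft_threshold_example(self):
        out = prox_step(np.array([2.0, -0.5, 0.3]), 0.5, "l1")
        assert np.allclose(out, [1.5, 0.0, 0.0])

    def test_l1_agrees_with_scalar_grid_search(self):
        # prox is separable: brute-force the 1-D objective per coordinate
        z, lam = np.array([1.3, -0.7, 0.05]), 0.4
        out = prox_step(z, lam, "l1")
        grid = np.linspace(-3, 3, 24001)
        for zi, oi in zip(z, out):
            obj = 0.5 * (grid - zi) ** 2 + lam * np.abs(grid)
            assert abs(grid[np.argmin(obj)] - oi) < 5e-4

    def test_zero_weight_is_identity(self, rng):
        z = rng.standard_normal(9)
        assert np.array_equal(prox_step(z, 0.0, "l1"), z)
        assert np.array_equal(prox_step(z, 0.3, "none"), z)

    def test_tv_decreases_its_objective(self, rng):
        z = np.kron(rng.random((2, 2)), np.ones((4, 4))) + 0.05 * rng.standard_normal((8, 8))
        lam = 0.05
        out = prox_step(z.reshape(-1), lam, "tv", shape=(8, 8)).reshape(8, 8)

        def prox_obj(x):
            gx = np.abs(np.diff(x, axis=0)).sum() + np.abs(np.diff(x, axis=1)).sum()
            return 0.5 * np.sum((x - z) ** 2) + lam * gx

        assert prox_obj(out) < prox_obj(z)

    def test_unknown_regularizer_rejected(self):
        with pytest.raises(ValueError):
            prox_step(np.zeros(4), 0.1, "ridge")


class TestPGD:
    def test_hadamard_converges_in_one_step(self, rng):
        op = sr.hadamard_operator(4)
        x = rng.random((4, 4))
        rec = sr.measure(op, sr.ImageScene(x))
        est, info = pgd_reconstruct(rec, op, ReconSpec(max_iters=2, regularizer="none"))
        assert np.allclose(est, x, atol=1e-12)

    def test_unregularized_limit_matches_pseudoinverse(self, rng):
        op = sr.random_operator(40, 8, 8, seed=6)
        rec = sr.measure(op, sr.ImageScene(rng.random((8, 8))))
        rho = 1.0 / spectral_bound(op.values)
        spec = ReconSpec(max_iters=20000, step_size=rho, regularizer="none",
                         tolerance=1e-14)
        est, _ = pgd_reconstruct(rec, op, spec)
        oracle = least_squares_oracle(rec, op)
        assert np.abs(est - oracle).max() < 1e-6

    @pytest.mark.parametrize("regularizer,lam", [("none", 0.0), ("l1", 0.02)])
    def test_objective_monotone_under_stable_step(self, rng, regularizer, lam):
        op = sr.random_operator(10, 4, 4, seed=8)
        rec = sr.measure(op, sr.ImageScene(rng.random((4, 4))))
        rho = 1.0 / spectral_bound(op.values)
        spec = ReconSpec(max_iters=300, step_size=rho, reg_weight=lam,
                         regularizer=regularizer, tolerance=1e-12)
        _, info = pgd_reconstruct(rec, op, spec)
        objs = np.array(info["objectives"])
        assert np.all(np.diff(objs) <= 1e-10 * (1 + np.abs(objs[:-1])))

    def test_sparse_support_recovered_and_matches_exhaustive_fit(self):
        # 3 bright pixels in a 16-pixel scene, 10 learned patterns
        truth = np.zeros(16)
        truth[[2, 7, 13]] = [1.0, 0.8, 1.2]
        scenes = [sr.gen_scene(sr.default_spec("nucleus", 4, seed=s)) for s in range(30)]
        op, _ = sr.learn_patterns(scenes, 10, 400, seed=9)
        rec = sr.measure(op, sr.ImageScene(truth.reshape(4, 4)))
        rho = 1.0 / spectral_bound(op.values)
        spec = ReconSpec(max_iters=3000, step_size=rho, reg_weight=0.002,
                         regularizer="l1", tolerance=1e-12)
        est, _ = pgd_reconstruct(rec, op, spec)
        support = set(np.argsort(np.abs(est.reshape(-1)))[-3:].tolist())
        # independent oracle: best 3-sparse least-squares fit by enumeration
        best_support, best_resid = None, np.inf
        for cols in itertools.combinations(range(16), 3):
            sub = op.values[:, cols]
            coef, *_ = np.linalg.lstsq(sub, rec.values, rcond=None)
            resid = np.linalg.norm(sub @ coef - rec.values)
            if resid < best_resid:
                best_resid, best_support = resid, set(cols)
        assert best_support == {2, 7, 13}
        assert support == best_support


class TestLeastSquaresOracle:
    def test_square_consistent_system_solved_exactly(self, rng):
        op = sr.hadamard_operator(4)
        x = rng.random((4, 4))
        rec = sr.measure(op, sr.ImageScene(x))
        assert np.allclose(least_squares_oracle(rec, op), x, atol=1e-12)

    def test_residual_orthogonal_to_row_space(self, rng):
        op = sr.random_operator(6, 4, 4, seed=10)
        y = rng.random(6)
        rec = sr.MeasurementRecord(values=y, pattern_indices=np.arange(6))
        est = least_squares_oracle(rec, op).reshape(-1)
        resid = op.values @ est - y
        # A^T resid = 0: the residual is orthogonal to the row space
        assert np.abs(op.values.T @ resid).max() < 1e-10

    def test_matches_normal_equations_on_full_rank(self, rng):
        op = sr.random_operator(16, 4, 4, seed=11)
        y = rng.random(16)
        rec = sr.MeasurementRecord(values=y, pattern_indices=np.arange(16))
        a = op.values
        normal = np.linalg.solve(a.T @ a, a.T @ y)
        assert np.allclose(least_squares_oracle(rec, op).reshape(-1), normal,
                           atol=1e-8)

    def test_size_guard(self, rng):
        op = sr.random_operator(2, 128, 128, seed=0)
        rec = sr.MeasurementRecord(values=rng.random(2), pattern_indices=np.arange(2))
        with pytest.raises(ValueError):
            least_squares_oracle(rec, op)
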