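"""Tests for the ADMM solver, rotation synchronisation and reconstruction."""

import numpy as np
import pytest

from mcmrr.linalg import PI, prox_spectral_norm
from mcmrr.solver import (
    Observation,
    SolverConfig,
    admm_solve,
    assemble_shape,
    center_observation,
    reconstruct,
    reconstruct_sequence,
    residuals,
    rotation_synchronize,
    similarity_weights,
    update_M,
    update_mu,
    update_Y,
    update_Z,
)
from mcmrr.synthetic import SyntheticSpec, generate

from .conftest import random_basis_set, random_row_orthonormal
from .oracles import z_subproblem_gradient


class TestCenterObservation:
    def test_zeros_and_single_point(self):
        obs, t = center_observation(np.zeros((2, 3)))
        np.testing.assert_allclose(obs.W, 0.0)
        np.testing.assert_allclose(t, 0.0)
        obs, t = center_observation(np.array([[3.0], [4.0]]))
        np.testing.assert_allclose(obs.W, 0.0)
        np.testing.assert_allclose(t, [3.0, 4.0])

    def test_idempotent(self, rng):
        W = rng.normal(size=(2, 7))
        once, _ = center_observation(W)
        twice, t2 = center_observation(once.W)
        np.testing.assert_allclose(once.W, twice.W)
        np.testing.assert_allclose(t2, 0.0, atol=1e-12)


class TestSimilarityWeights:
    def test_exact_match_gives_unit_weights(self, rng):
        bases = random_basis_set(rng, 3, 8)
        # observation equal to projection of basis 0; pass gamma2 explicitly
        W = PI @ bases.basis(0)
        obs = Observation(W=W - W.mean(axis=1, keepdims=True), centered=True)
        # recenter bases so the distance to basis 0 is exactly 0
        obs = Observation(W=PI @ bases.basis(0), centered=False)
        sw = similarity_weights(obs, bases, gamma2=1.0)
        assert sw.d[0] == pytest.approx(1.0)

    def test_distance_equal_to_gamma2_gives_e(self, rng):
        bases = random_basis_set(rng, 1, 6)
        W = PI @ bases.basis(0) + 0.1
        obs = Observation(W=W)
        d2 = float(np.sum((W - PI @ bases.basis(0)) ** 2))
        sw = similarity_weights(obs, bases, gamma2=d2)
        assert sw.d[0] == pytest.approx(np.e)

    def test_monotone_in_distance(self, rng):
        bases = random_basis_set(rng, 4, 10)
        obs = Observation(W=rng.normal(size=(2, 10)))
        sw = similarity_weights(obs, bases, gamma2=0.7)
        dist = [np.linalg.norm(obs.W - PI @ B) for B in bases]
        order_d = np.argsort(sw.d)
        np.testing.assert_array_equal(order_d, np.argsort(dist))

    def test_D_block_structure_and_validation(self, rng):
        bases = random_basis_set(rng, 2, 6)
        obs = Observation(W=rng.normal(size=(2, 6)))
        sw = similarity_weights(obs, bases, gamma2=1.0)
        np.testing.assert_allclose(np.diag(sw.D), np.repeat(sw.d, 3))
        with pytest.raises(ValueError):
            similarity_weights(obs, bases, gamma2=-1.0)


class TestUpdates:
    def test_update_M_alpha_zero_is_identity(self, rng):
        Z, Y = rng.normal(size=(2, 9)), rng.normal(size=(2, 9))
        np.testing.assert_allclose(update_M(Z, Y, 2.0, 0.0), Z - Y / 2.0)

    def test_update_M_blocks_match_standalone_prox(self, rng):
        Z, Y, mu, alpha = rng.normal(size=(2, 9)), rng.normal(size=(2, 9)), 1.7, 0.4
        M = update_M(Z, Y, mu, alpha)
        P = Z - Y / mu
        for i in range(3):
            np.testing.assert_allclose(
                M[:, 3 * i : 3 * i + 3],
                prox_spectral_norm(P[:, 3 * i : 3 * i + 3], alpha / mu),
            )

    def test_update_Z_stationarity(self, rng):
        for _ in range(5):
            K, p = 3, 11
            B = random_basis_set(rng, K, p).B
            W = rng.normal(size=(2, p))
            M = rng.normal(size=(2, 3 * K))
            Y = rng.normal(size=(2, 3 * K))
            D_diag = np.repeat(rng.uniform(1.0, 3.0, K), 3)
            mu, beta = rng.uniform(0.5, 5.0), rng.uniform(0.0, 1.0)
            Z, _ = update_Z(W, B, M, Y, mu, beta, D_diag)
            g = z_subproblem_gradient(Z, W, B, M, Y, mu, beta, D_diag)
            assert np.linalg.norm(g) < 1e-8 * (1.0 + np.linalg.norm(W))

    def test_update_Z_penalty_dominated_limit(self, rng):
        K, p = 2, 8
        B = random_basis_set(rng, K, p).B
        W, M, Y = rng.normal(size=(2, p)), rng.normal(size=(2, 6)), rng.normal(size=(2, 6))
        Z, _ = update_Z(W, B, M, Y, 1e8, 0.0, np.ones(6))
        np.testing.assert_allclose(Z, M + Y / 1e8, atol=1e-4)

    def test_update_Y_arithmetic(self, rng):
        Y = np.zeros((2, 6))
        M = np.ones((2, 6))
        Z = np.zeros((2, 6))
        Y1 = update_Y(Y, M, Z, 2.0)
        np.testing.assert_allclose(Y1, 2.0 * np.ones((2, 6)))
        # sequential updates compose additively
        Y2 = update_Y(Y1, M, Z, 2.0)
        np.testing.assert_allclose(Y2, Y1 + 2.0 * (M - Z))
        np.testing.assert_allclose(update_Y(Y, M, M, 3.0), Y)

    @pytest.mark.parametrize(
        "d1, d2, expected_factor",
        [(1.0, 0.05, 2.0), (0.05, 1.0, 0.5), (1.0, 1.0, 1.0)],
    )
    def test_update_mu_branches(self, d1, d2, expected_factor):
        assert update_mu(4.0, d1, d2, 10.0) == pytest.approx(4.0 * expected_factor)

    def test_residuals(self, rng):
        Z = rng.normal(size=(2, 6))
        d1, d2 = residuals(Z, Z, Z)
        assert d1 == 0.0 and d2 == 0.0
        d1, d2 = residuals(2.0 * Z, 2.0 * Z, Z)
        assert d1 == 0.0
        assert d2 == pytest.approx(1.0)
        M, Zn, Zo = rng.normal(size=(2, 6)), rng.normal(size=(2, 6)), rng.normal(size=(2, 6))
        d1, d2 = residuals(M, Zn, Zo)
        assert d1 == pytest.approx(np.linalg.norm(M - Zn) / np.linalg.norm(Zo))
        assert d2 == pytest.approx(np.linalg.norm(Zn - Zo) / np.linalg.norm(Zo))


class TestAdmmSolve:
    def test_noiseless_consistency(self, rng):
        K, p = 3, 12
        bases = random_basis_set(rng, K, p)
        R = random_row_orthonormal(rng)
        c = np.abs(rng.normal(size=K)) + 0.2
        M_star = np.hstack([ci * R for ci in c])
        W = M_star @ bases.B
        obs = Observation(W=W - W.mean(axis=1, keepdims=True), centered=True)
        cfg = SolverConfig(alpha=1e-8, beta=0.0, eps=1e-6)
        state = admm_solve(obs, bases, cfg)
        rel = np.linalg.norm(state.M_tilde @ bases.B - obs.W) / np.linalg.norm(obs.W)
        assert rel < 1e-3

    def test_huge_eps_stops_after_first_iteration(self, rng):
        bases = random_basis_set(rng, 2, 8)
        obs, _ = center_observation(rng.normal(size=(2, 8)))
        state = admm_solve(obs, bases, SolverConfig(eps=1e6))
        assert state.converged and state.iteration == 1

    def test_deterministic(self, rng):
        bases = random_basis_set(rng, 2, 8)
        obs, _ = center_observation(rng.normal(size=(2, 8)))
        s1 = admm_solve(obs, bases, SolverConfig())
        s2 = admm_solve(obs, bases, SolverConfig())
        np.testing.assert_array_equal(s1.M_tilde, s2.M_tilde)
        assert s1.iteration == s2.iteration

    def test_feasibility_at_convergence(self, rng):
        bases = random_basis_set(rng, 3, 10)
        obs, _ = center_observation(rng.normal(size=(2, 10)))
        cfg = SolverConfig(eps=1e-5)
        state = admm_solve(obs, bases, cfg)
        assert state.converged
        gap = np.linalg.norm(state.M_tilde - state.Z) / np.linalg.norm(state.Z)
        assert gap < cfg.eps

    def test_uncentered_observation_rejected(self, rng):
        bases = random_basis_set(rng, 2, 6)
        with pytest.raises(ValueError):
            admm_solve(Observation(W=rng.normal(size=(2, 6)) + 5.0), bases, SolverConfig())


class TestRotationSynchronize:
    def test_exact_recovery(self, rng):
        R_star = random_row_orthonormal(rng)
        c_star = np.array([2.0, -1.0])
        M_list = [ci * R_star for ci in c_star]
        c, R = rotation_synchronize(M_list)
        np.testing.assert_allclose(R @ R.T, np.eye(2), atol=1e-10)
        obj = sum(np.sum((M - ci * R) ** 2) for M, ci in zip(M_list, c))
        assert obj < 1e-12
        # gauge: first nonzero coefficient non-negative; truth has c_1 = 2 > 0
        np.testing.assert_allclose(c, c_star, atol=1e-8)
        np.testing.assert_allclose(R, R_star, atol=1e-8)

    def test_single_scaled_projection(self):
        c, R = rotation_synchronize([3.0 * PI])
        np.testing.assert_allclose(c, [3.0], atol=1e-12)
        np.testing.assert_allclose(R, PI, atol=1e-12)

    def test_objective_nonincreasing_on_random_input(self, rng):
        # run the alternation manually and check monotonicity
        from mcmrr.linalg import procrustes_2x3

        M_list = [rng.normal(size=(2, 3)) for _ in range(4)]
        R = procrustes_2x3(M_list[0])
        prev = np.inf
        for _ in range(50):
            c = np.array([0.5 * np.sum(M * R) for M in M_list])
            T = sum(ci * M for ci, M in zip(c, M_list))
            R = procrustes_2x3(T)
            obj = sum(np.sum((M - ci * R) ** 2) for ci, M in zip(c, M_list))
            assert obj <= prev + 1e-10
            prev = obj

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rotation_synchronize([np.zeros((2, 3))] * 2)


class TestAssembleShape:
    def test_unit_coefficient_identity_rotation(self, rng):
        bases = random_basis_set(rng, 3, 7)
        S = assemble_shape(np.array([1.0, 0.0, 0.0]), PI, bases)
        np.testing.assert_allclose(S, bases.basis(0))

    def test_zero_coefficients(self, rng):
        bases = random_basis_set(rng, 2, 5)
        np.testing.assert_allclose(assemble_shape(np.zeros(2), PI, bases), 0.0)

    def test_linearity(self, rng):
        bases = random_basis_set(rng, 3, 6)
        R = random_row_orthonormal(rng)
        c1, c2 = rng.normal(size=3), rng.normal(size=3)
        S = assemble_shape(c1 + c2, R, bases)
        np.testing.assert_allclose(
            S, assemble_shape(c1, R, bases) + assemble_shape(c2, R, bases), atol=1e-12
        )


class TestReconstruct:
    def test_single_basis_noiseless_recovery(self, rng):
        bases = random_basis_set(rng, 1, 10)
        W = PI @ bases.basis(0)
        cfg = SolverConfig(alpha=1e-8, beta=0.0, eps=1e-8)
        res = reconstruct(W, bases, cfg)
        B1 = bases.basis(0)
        flip = np.diag([1.0, 1.0, -1.0])
        err = min(
            np.linalg.norm(res.S - B1),
            np.linalg.norm(flip @ res.S - B1),
        ) / np.linalg.norm(B1)
        assert err < 1e-2

    def test_cra_variant_equals_mcmrr_with_beta_zero(self, rng):
        bases = random_basis_set(rng, 3, 10)
        W = rng.normal(size=(2, 10))
        res_cra = reconstruct(W, bases, SolverConfig(variant="cra", beta=0.5))
        res_b0 = reconstruct(W, bases, SolverConfig(variant="mcmrr", beta=0.0))
        np.testing.assert_array_equal(res_cra.S, res_b0.S)

    def test_per_frame_independence(self, rng):
        bases = random_basis_set(rng, 2, 9)
        frames = [rng.normal(size=(2, 9)) for _ in range(2)]
        seq = reconstruct_sequence(frames, bases)
        singles = [reconstruct(W, bases) for W in frames]
        for a, b in zip(seq, singles):
            np.testing.assert_array_equal(a.S, b.S)

    def test_similarity_selects_generating_basis(self, rng):
        """An observation generated from basis j with far-away distractors:
        |c_j| dominates when the similarity penalty is active."""
        gt = generate(SyntheticSpec(p=12, K_true=3, F_test=1, noise_sigma=0.0,
                                    rotation_mode="identity", seed=3))
        bases = gt.basis_set
        j = 1
        W = PI @ bases.basis(j) * 1.3
        res = reconstruct(W, bases, SolverConfig(variant="mcmrr"))
        assert np.argmax(np.abs(res.motion.c)) == j

    def test_noise_monotone_degradation(self):
        """Mean reconstruction error is non-decreasing in observation noise."""
        from mcmrr.evaluation import mean_error

        means = []
        for sigma in (0.0, 0.01, 0.05):
            errs = []
            for seed in range(10):
                gt = generate(SyntheticSpec(p=12, K_true=2, F_test=3,
                                            noise_sigma=sigma, seed=seed))
                res = reconstruct_sequence(gt.observations, gt.basis_set,
                                           SolverConfig(alpha=1e-4, beta=0.0))
                errs.append(mean_error([r.S for r in res], gt.shapes_true).xi)
            means.append(np.mean(errs))
        assert means[0] <= means[1] + 1e-6
        assert means[1] <= means[2] + 1e-6
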