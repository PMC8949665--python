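"""Solver components: u-update exactness, multipliers, Lagrangian, limits."""

import numpy as np
import pytest

from tvnls import (
    GradientField,
    Image,
    NLSParams,
    SolverConfig,
    augmented_lagrangian_value,
    denoise_image,
    gradient,
    gradient_adjoint,
    identity_operator,
    make_phantom,
    reconstruct,
    solve_u_subproblem,
    subsampled_transform_operator,
    update_multipliers,
)
from tvnls.noise import add_awgn
from tvnls.solver import SolverState, _inner_sweep

SMALL_NLS = NLSParams(block_size=4, group_size=4, search_window=12, step=2)


def random_state(rng, shape, f, tau=1.0, lam=5.0, nls=SMALL_NLS):
    n = shape[0] * shape[1]
    return SolverState(
        u=rng.normal(size=n),
        w=GradientField(rng.normal(size=shape), rng.normal(size=shape)),
        x=rng.normal(size=n),
        gamma=GradientField(rng.normal(size=shape), rng.normal(size=shape)),
        phi=rng.normal(size=n),
        shape=shape,
        tau=tau,
        lambda_nls=lam,
    )


def objective_gradient(u, f, A, w, gamma, x, phi, cfg, shape):
    """Gradient of the quadratic u-subproblem objective."""
    g = A.adjoint(A.apply(u) - f)
    Du = gradient(u.reshape(shape))
    g = g + gradient_adjoint(cfg.rho_tv * (Du - w) - gamma).ravel()
    g = g + cfg.rho_nls * (u - x) - phi
    return g


class TestUSubproblem:
    @pytest.mark.parametrize("kind", ["identity", "subsampled"])
    def test_first_order_optimality_random_instances(self, rng, kind):
        shape = (16, 16)
        n = 256
        A = (
            identity_operator(n)
            if kind == "identity"
            else subsampled_transform_operator(n, 100, seed=0)
        )
        cfg = SolverConfig(rho_tv=1.3, rho_nls=0.7, u_solver="auto")
        for _ in range(5):
            f = rng.normal(size=A.n_rows)
            w = GradientField(rng.normal(size=shape), rng.normal(size=shape))
            gamma = GradientField(rng.normal(size=shape), rng.normal(size=shape))
            x = rng.normal(size=n)
            phi = rng.normal(size=n)
            u = solve_u_subproblem(f, A, w, gamma, x, phi, cfg, shape)
            g = objective_gradient(u, f, A, w, gamma, x, phi, cfg, shape)
            assert np.linalg.norm(g) <= 1e-6 * (1 + np.linalg.norm(u))

    def test_normal_equation_relative_residual(self, rng):
        shape = (16, 16)
        A = subsampled_transform_operator(256, 128, seed=1)
        cfg = SolverConfig(rho_tv=1.0, rho_nls=1.0)
        f = rng.normal(size=128)
        w = GradientField(rng.normal(size=shape), rng.normal(size=shape))
        gamma = GradientField.zeros(shape)
        x = rng.normal(size=256)
        phi = rng.normal(size=256)
        u = solve_u_subproblem(f, A, w, gamma, x, phi, cfg, shape)

        def M(v):
            return (
                A.adjoint(A.apply(v))
                + cfg.rho_tv * gradient_adjoint(gradient(v.reshape(shape))).ravel()
                + cfg.rho_nls * v
            )

        rhs = (
            A.adjoint(f)
            + gradient_adjoint(cfg.rho_tv * w + gamma).ravel()
            + cfg.rho_nls * x
            + phi
        )
        assert np.linalg.norm(M(u) - rhs) / np.linalg.norm(rhs) <= 1e-8

    def test_spectral_matches_dense_direct_solve(self, rng):
        """8x8, A = identity: Fourier solve vs assembled dense normal equations."""
        shape = (8, 8)
        n = 64
        A = identity_operator(n)
        cfg = SolverConfig(rho_tv=2.0, rho_nls=0.5, u_solver="spectral")
        f = rng.normal(size=n)
        w = GradientField(rng.normal(size=shape), rng.normal(size=shape))
        gamma = GradientField(rng.normal(size=shape), rng.normal(size=shape))
        x = rng.normal(size=n)
        phi = rng.normal(size=n)
        u = solve_u_subproblem(f, A, w, gamma, x, phi, cfg, shape)

        # dense oracle
        D = np.zeros((2 * n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            g = gradient(e.reshape(shape))
            D[:n, j] = g.horizontal.ravel()
            D[n:, j] = g.vertical.ravel()
        M = np.eye(n) + cfg.rho_tv * (D.T @ D) + cfg.rho_nls * np.eye(n)
        rhs = (
            f
            + D.T @ np.concatenate(
                [
                    (cfg.rho_tv * w + gamma).horizontal.ravel(),
                    (cfg.rho_tv * w + gamma).vertical.ravel(),
                ]
            )
            + cfg.rho_nls * x
            + phi
        )
        assert np.max(np.abs(u - np.linalg.solve(M, rhs))) <= 1e-8

    def test_cg_matches_spectral_on_identity(self, rng):
        shape = (8, 8)
        A = identity_operator(64)
        f = rng.normal(size=64)
        w = GradientField(rng.normal(size=shape), rng.normal(size=shape))
        gamma = GradientField.zeros(shape)
        x = rng.normal(size=64)
        phi = np.zeros(64)
        u_sp = solve_u_subproblem(
            f, A, w, gamma, x, phi, SolverConfig(u_solver="spectral"), shape
        )
        u_cg = solve_u_subproblem(
            f, A, w, gamma, x, phi, SolverConfig(u_solver="conjugate_gradient"), shape
        )
        assert np.allclose(u_sp, u_cg, atol=1e-7)

    def test_penalty_dominated_limit_pins_u_to_x(self, rng):
        shape = (8, 8)
        A = identity_operator(64)
        x = rng.uniform(0, 255, size=64)
        cfg = SolverConfig(rho_tv=1.0, rho_nls=1e6)
        u = solve_u_subproblem(
            rng.normal(size=64), A, GradientField.zeros(shape), GradientField.zeros(shape),
            x, np.zeros(64), cfg, shape,
        )
        assert np.max(np.abs(u - x)) <= 1e-3 * np.max(np.abs(x))


class TestMultipliers:
    def test_feasible_point_leaves_multipliers_unchanged(self, rng):
        shape = (8, 8)
        u = rng.normal(size=64)
        st = SolverState(
            u=u,
            w=gradient(u.reshape(shape)),
            x=u.copy(),
            gamma=GradientField(rng.normal(size=shape), rng.normal(size=shape)),
            phi=rng.normal(size=64),
            shape=shape,
        )
        g0, p0 = st.gamma, st.phi.copy()
        update_multipliers(st, SolverConfig())
        assert np.allclose(st.gamma.horizontal, g0.horizontal, atol=1e-12)
        assert np.allclose(st.phi, p0, atol=1e-12)

    def test_constant_residual_arithmetic(self):
        shape = (4, 4)
        u = np.zeros(16)
        w = GradientField(np.full(shape, -2.0), np.full(shape, -2.0))  # Du - w = 2
        st = SolverState(
            u=u, w=w, x=None, gamma=GradientField.zeros(shape), phi=None, shape=shape
        )
        update_multipliers(st, SolverConfig(rho_tv=1.0))
        assert np.all(st.gamma.horizontal == -2.0)
        assert np.all(st.gamma.vertical == -2.0)

    def test_two_updates_accumulate_linearly(self):
        shape = (4, 4)
        st = SolverState(
            u=np.zeros(16),
            w=GradientField(np.full(shape, 1.0), np.zeros(shape)),
            x=np.full(16, 3.0),
            gamma=GradientField.zeros(shape),
            phi=np.zeros(16),
            shape=shape,
        )
        cfg = SolverConfig(rho_tv=2.0, rho_nls=0.5)
        update_multipliers(st, cfg)
        update_multipliers(st, cfg)
        assert np.all(st.gamma.horizontal == 2 * 2.0)  # -2*rho*(0 - 1)
        assert np.all(st.phi == 2 * 0.5 * 3.0)  # -2*rho*(0 - 3)


class TestAugmentedLagrangian:
    def test_feasible_zero_state_has_zero_value(self):
        shape = (8, 8)
        st = SolverState(
            u=np.zeros(64),
            w=GradientField.zeros(shape),
            x=np.zeros(64),
            gamma=GradientField.zeros(shape),
            phi=np.zeros(64),
            shape=shape,
            tau=1.0,
            lambda_nls=1.0,
        )
        cfg = SolverConfig(nls=SMALL_NLS)
        assert augmented_lagrangian_value(st, np.zeros(64), identity_operator(64), cfg) == 0.0

    def test_linearity_in_tau(self, rng):
        shape = (8, 8)
        st = random_state(rng, shape, None)
        cfg = SolverConfig(nls=SMALL_NLS)
        f = rng.normal(size=64)
        A = identity_operator(64)
        v1 = augmented_lagrangian_value(st, f, A, cfg)
        st.tau += 0.7
        v2 = augmented_lagrangian_value(st, f, A, cfg)
        assert np.isclose(v2 - v1, 0.7 * st.w.l1(), rtol=1e-9)

    def test_inner_sweep_never_increases_exact_prox_config(self, rng):
        """Alternating minimization decreases L_A when every step is an
        exact minimizer: disjoint single-block groups with threshold scale
        chosen so the group shrinkage is the exact proximal map."""
        shape = (16, 16)
        n_pix = 256
        nls = NLSParams(block_size=8, group_size=1, search_window=8, step=8,
                        threshold_scale=n_pix / 64)  # c*K/N = 1
        cfg = SolverConfig(nls=nls, rho_tv=1.2, rho_nls=0.8)
        A = identity_operator(n_pix)
        for trial in range(50):
            trng = np.random.default_rng(trial)
            f = trng.uniform(0, 255, size=n_pix)
            st = random_state(trng, shape, f, tau=3.0, lam=40.0, nls=nls)
            scale = 1 + abs(augmented_lagrangian_value(st, f, A, cfg))
            before = augmented_lagrangian_value(st, f, A, cfg)
            _inner_sweep(st, f, A, cfg)
            after = augmented_lagrangian_value(st, f, A, cfg)
            assert after <= before + 1e-9 * scale

    def test_inner_sweep_decreases_under_overlap_most_trials(self):
        """With overlapping groups the x-step is only approximately proximal;
        the Lagrangian still decreases in >= 95% of random trials."""
        shape = (16, 16)
        cfg = SolverConfig(nls=SMALL_NLS, rho_tv=1.0, rho_nls=1.0)
        A = identity_operator(256)
        wins = 0
        trials = 40
        for trial in range(trials):
            trng = np.random.default_rng(1000 + trial)
            f = trng.uniform(0, 255, size=256)
            st = random_state(trng, shape, f, tau=2.0, lam=10.0)
            before = augmented_lagrangian_value(st, f, A, cfg)
            _inner_sweep(st, f, A, cfg)
            if augmented_lagrangian_value(st, f, A, cfg) <= before + 1e-9:
                wins += 1
        assert wins >= 0.95 * trials


class TestReconstructLimits:
    def test_no_regularization_returns_measurement_exactly(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        A = identity_operator(256)
        out, st = reconstruct(
            img.ravel(), A, (16, 16), SolverConfig(tau=0.0, lambda_nls=0.0, nls=SMALL_NLS)
        )
        assert np.array_equal(out.pixels.ravel(), img.ravel())
        assert st.outer_iter == 1

    def test_disabled_flags_equal_zero_weights(self, rng):
        img = rng.uniform(0, 255, size=(16, 16))
        A = identity_operator(256)
        out1, _ = reconstruct(
            img.ravel(), A, (16, 16),
            SolverConfig(enable_tv=False, enable_nls=False, sigma=5.0, nls=SMALL_NLS),
        )
        out2, _ = reconstruct(
            img.ravel(), A, (16, 16),
            SolverConfig(tau=0.0, lambda_nls=0.0, sigma=5.0, nls=SMALL_NLS),
        )
        assert np.array_equal(out1.pixels, out2.pixels)

    def test_weight_continuity_as_epsilon_vanishes(self):
        img = make_phantom(32, 32, seed=1)
        noisy = add_awgn(img, 5.0, seed=1)
        A = identity_operator(noisy.n_pixels)
        base_cfg = dict(
            sigma=5.0, nls=SMALL_NLS, max_outer=300,
            tol_rel_change=1e-10, tol_residual=1e-9,
        )
        u0, _ = reconstruct(
            noisy.pixels.ravel(), A, (32, 32),
            SolverConfig(tau=0.0, lambda_nls=0.0, **base_cfg),
        )
        errs = []
        for eps in (1e-3, 1e-6):
            ue, _ = reconstruct(
                noisy.pixels.ravel(), A, (32, 32),
                SolverConfig(tau=eps, lambda_nls=eps, **base_cfg),
            )
            errs.append(np.max(np.abs(ue.pixels - u0.pixels)))
        assert errs[1] <= errs[0]
        assert errs[1] <= 1e-4

    def test_end_to_end_determinism(self):
        img = make_phantom(48, 48, seed=2)
        noisy = add_awgn(img, 10.0, seed=2)
        cfg = SolverConfig(sigma=10.0, nls=SMALL_NLS, max_outer=8)
        out1, _ = denoise_image(noisy, cfg)
        out2, _ = denoise_image(noisy, cfg)
        assert np.array_equal(out1.pixels, out2.pixels)

    def test_color_channels_processed_independently(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(0, 255, size=(32, 32, 3))
        img = Image(arr)
        cfg = SolverConfig(sigma=5.0, nls=SMALL_NLS, max_outer=5)
        out, _ = denoise_image(img, cfg)
        single, _ = denoise_image(Image(arr[..., 1]), cfg)
        assert np.allclose(out.pixels[..., 1], single.pixels, atol=1e-12)

    def test_nonmatching_operator_rejected(self):
        with pytest.raises(ValueError):
            reconstruct(np.zeros(64), identity_operator(64), (16, 16), SolverConfig())


class TestCSRecovery:
    def test_full_sampling_noiseless_recovery(self, rng):
        """M = N orthonormal measurements recover the image exactly (no reg)."""
        img = make_phantom(32, 32, seed=3)
        A = subsampled_transform_operator(1024, 1024, seed=0)
        f = A.apply(img.pixels.ravel())
        out, _ = reconstruct(
            f, A, (32, 32), SolverConfig(tau=0.0, lambda_nls=0.0, nls=SMALL_NLS)
        )
        assert np.allclose(out.pixels, img.pixels, atol=1e-6)

    def test_half_sampling_regularized_beats_backprojection(self):
        """50% measurements: TV+NLS reconstruction improves on A^T f."""
        from tvnls import psnr

        img = make_phantom(64, 64, seed=4)
        n = img.n_pixels
        A = subsampled_transform_operator(n, n // 2, seed=1)
        f = A.apply(img.pixels.ravel())
        back = Image(A.adjoint(f).reshape(64, 64))
        cfg = SolverConfig(sigma=10.0, nls=SMALL_NLS, max_outer=15)
        out, _ = reconstruct(f, A, (64, 64), cfg)
        assert psnr(img, out) > psnr(img, back) + 3.0
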