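"""Covariance kernels, pivoted Cholesky KL expansion and deformation sampling."""

import numpy as np
import pytest

from ecguq.shape_field import (AdmissibilityError, CovarianceModel, build_kl,
                               covariance_entry, deformed_points, pivoted_cholesky,
                               sample_deformation, shape_std, spatial_kernel,
                               temporal_kernel)


class TestSpatialKernel:
    def test_variance_at_zero_distance(self):
        assert spatial_kernel(0.0, 2.5) == pytest.approx(4.0 / 3.0)
        assert spatial_kernel(0.0, np.inf) == pytest.approx(4.0 / 3.0)

    def test_vanishes_at_far_range(self):
        assert spatial_kernel(1e6 * 50.0, 2.5) <= 1e-30
        assert spatial_kernel(1e3 * 50.0, np.inf) <= 1e-30

    def test_gaussian_limit_value(self):
        got = spatial_kernel(50.0, np.inf, rho=50.0)
        assert got == pytest.approx(4.0 / 3.0 * np.exp(-0.5), rel=1e-12)
        assert got == pytest.approx(0.8087, abs=5e-5)

    def test_matern_52_closed_form(self):
        d, rho = 20.0, 50.0
        q = np.sqrt(5) * d / rho
        assert spatial_kernel(d, 2.5, rho) == pytest.approx(
            4.0 / 3.0 * (1 + q + q ** 2 / 3) * np.exp(-q), rel=1e-14)

    def test_unsupported_smoothness_rejected(self):
        with pytest.raises(ValueError):
            spatial_kernel(1.0, 1.5)


class TestTemporalKernel:
    def test_unit_at_zero_lag(self):
        assert temporal_kernel(123.0, 123.0, 690.0) == pytest.approx(1.0)

    def test_zero_at_half_period(self):
        assert temporal_kernel(0.0, 345.0, 690.0) == pytest.approx(0.0, abs=1e-14)

    def test_periodicity(self):
        t = np.linspace(0, 690, 13)
        assert np.allclose(temporal_kernel(t, 100.0, 690.0),
                           temporal_kernel(t, 100.0 + 690.0, 690.0))

    def test_positive_semidefinite_on_random_time_subsets(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            t = rng.uniform(0, 690, 40)
            gram = temporal_kernel(t[:, None], t[None, :], 690.0)
            eigs = np.linalg.eigvalsh(gram)
            assert eigs.min() >= -1e-10 * np.trace(gram)


class TestCovarianceEntry:
    def test_diagonal_at_coincident_points(self):
        block = covariance_entry((np.zeros(2), 0.0), (np.zeros(2), 0.0))
        assert np.allclose(block, np.diag([4.0 / 3.0, 4.0 / 3.0]))

    def test_components_uncorrelated(self):
        block = covariance_entry((np.zeros(2), 0.0), (np.array([30.0, 10.0]), 200.0))
        assert block[0, 1] == 0.0 and block[1, 0] == 0.0

    def test_symmetry(self):
        z1, z2 = (np.array([1.0, 2.0]), 50.0), (np.array([-3.0, 4.0]), 400.0)
        assert np.allclose(covariance_entry(z1, z2), covariance_entry(z2, z1).T)


class TestPivotedCholesky:
    def test_rank_one_terminates_in_one_step(self):
        v = np.array([1.0, -2.0, 3.0, 0.5])
        C = np.outer(v, v)
        L, piv, res = pivoted_cholesky(lambda j: C[:, j], np.diag(C), 1e-12)
        assert L.shape[1] == 1
        assert res <= 1e-12
        assert np.allclose(L @ L.T, C, atol=1e-12)

    def test_identity_is_incompressible(self):
        n = 17
        C = np.eye(n)
        L, _, res = pivoted_cholesky(lambda j: C[:, j], np.ones(n), 1e-4)
        assert L.shape[1] == n
        assert res <= 1e-12

    def test_matches_dense_eigendecomposition_residual(self):
        # trace residual reported by the factorisation equals the directly
        # computed trace of C - L L^T
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (80, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        C = spatial_kernel(d, 2.5)
        L, _, res = pivoted_cholesky(lambda j: C[:, j], np.diag(C).copy(), 1e-4)
        direct = np.trace(C - L @ L.T) / np.trace(C)
        assert res <= 1e-4
        assert abs(res - direct) <= 1e-10
        # the residual matrix is (numerically) PSD: pivoted Cholesky cannot
        # beat the optimal eigenvalue tail, which is itself below tol here
        tail = np.sort(np.linalg.eigvalsh(C))[: C.shape[0] - L.shape[1]]
        assert tail.sum() / np.trace(C) <= res + 1e-12

    def test_residual_monotone_in_rank(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (40, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        C = spatial_kernel(d, 2.5)
        residuals = []
        for k in range(1, 12):
            _, _, res = pivoted_cholesky(lambda j: C[:, j], np.diag(C).copy(),
                                         0.0, max_rank=k)
            residuals.append(res)
        assert np.all(np.diff(residuals) <= 1e-14)

    def test_indefinite_matrix_rejected(self):
        C = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(np.linalg.LinAlgError):
            pivoted_cholesky(lambda j: C[:, j], np.diag(C).copy(), 1e-12)


class TestKLExpansion:
    def test_trace_residual_below_tolerance(self, small_kl):
        assert small_kl.trace_residual <= 1e-4

    def test_covariance_reconstruction_against_dense_factor(self, torso_single_instant):
        # rebuild the component covariances densely and compare traces
        kl = build_kl(torso_single_instant, tol=1e-4, n_sigma=48)
        pts = kl.positions[0]
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        for comp, nu in ((0, 2.5), (1, np.inf)):
            C = spatial_kernel(d, nu)
            modes = kl.modes[:, 0, :, comp]
            active = modes[np.abs(modes).max(axis=1) > 0]
            resid = np.trace(C - active.T @ active) / np.trace(C)
            assert resid <= 1e-4
            assert resid >= -1e-10

    def test_psd_on_random_subsets(self, torso):
        rng = np.random.default_rng(2)
        s = np.arange(64) / 64
        model = CovarianceModel()
        for _ in range(3):
            t_idx = rng.integers(0, torso.n_times, 10)
            s_idx = rng.integers(0, 64, 5)
            pts = np.array([torso.pericardium[tj].point(s[sj])[0]
                            for tj in t_idx for sj in s_idx])
            tt = np.repeat(torso.times[t_idx], 5)
            kt = temporal_kernel(tt[:, None], tt[None, :], model.period)
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            C = kt * spatial_kernel(d, 2.5)
            eigs = np.linalg.eigvalsh(C)
            assert eigs.min() >= -1e-10 * np.trace(C)

    def test_zero_parameter_gives_reference(self, small_kl):
        curve = sample_deformation(small_kl, np.zeros(small_kl.n_modes), 0)
        pts = curve.point(np.arange(64) / 64)
        assert np.abs(pts - small_kl.positions[0]).max() < 1e-10

    def test_affinity_in_xi(self, small_kl):
        rng = np.random.default_rng(3)
        xi = rng.uniform(-1, 1, small_kl.n_modes)
        base = deformed_points(small_kl, np.zeros(small_kl.n_modes), 0)
        full = deformed_points(small_kl, xi, 0) - base
        half = deformed_points(small_kl, 0.5 * xi, 0) - base
        assert np.allclose(half, 0.5 * full, atol=1e-12)

    def test_sampled_displacement_variance_matches_closed_form(self, small_kl):
        # QMC average over 1e4 uniform parameter samples vs (1/3) sum m_k^2
        from ecguq.quadrature import halton_rule

        rule = halton_rule(small_kl.n_modes, 10_000)
        acc = np.zeros((64, 2))
        base = small_kl.positions[0]
        for xi in rule.nodes:
            acc += (deformed_points(small_kl, xi, 0) - base) ** 2
        empirical = acc / rule.size
        analytic = np.sum(small_kl.modes[:, 0] ** 2, axis=0) / 3.0
        rel = np.abs(empirical - analytic).max() / analytic.max()
        assert rel < 0.05

    def test_shape_std_closed_form(self, small_kl):
        std = shape_std(small_kl)
        assert std.shape == (1, 64, 2)
        analytic = np.sqrt(np.sum(small_kl.modes ** 2, axis=0) / 3.0)
        assert np.array_equal(std, analytic)

    def test_std_invariant_under_mode_permutation(self, small_kl):
        from dataclasses import replace

        rng = np.random.default_rng(5)
        perm = rng.permutation(small_kl.n_modes)
        shuffled = replace(small_kl, modes=small_kl.modes[perm],
                           pivot_values=small_kl.pivot_values[perm])
        assert np.allclose(shape_std(shuffled), shape_std(small_kl))

    def test_inadmissible_deformation_raises(self, small_kl):
        from dataclasses import replace

        # blow up the modes so the deformation self-intersects or escapes
        huge = replace(small_kl, modes=small_kl.modes * 200.0)
        xi = np.ones(huge.n_modes)
        with pytest.raises(AdmissibilityError, match="instant 0"):
            sample_deformation(huge, xi, 0)

    def test_xi_outside_cube_rejected(self, small_kl):
        xi = np.zeros(small_kl.n_modes)
        xi[0] = 1.5
        with pytest.raises(ValueError):
            deformed_points(small_kl, xi, 0)
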