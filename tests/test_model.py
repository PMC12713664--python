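"""Vertex GLM, AR(p) machinery and the structured parcel spline fit."""

import numpy as np
import pytest
from scipy.linalg import toeplitz

from splash.hrf import StimulusTrain, build_basis, build_design
from splash.model import (
    NoiseModel,
    ParcelDesign,
    ar_whiten,
    bic_score,
    default_m_grid,
    estimate_noise,
    fit_splash,
    fit_vertex_glm,
    select_basis_dim,
    yule_walker_ar,
)
from splash.tps import ParcelGeometry, SplineBasis, build_tprs


class TestVertexGLM:
    def test_noiseless_recovery(self, small_design, rng):
        beta = rng.normal(size=(10, 2))
        Y = small_design.X @ beta.T
        bh, resid, s2 = fit_vertex_glm(Y, small_design)
        np.testing.assert_allclose(bh, beta, atol=1e-10)
        np.testing.assert_allclose(resid, 0, atol=1e-10)
        np.testing.assert_allclose(s2, 0, atol=1e-18)

    def test_textbook_normal_equations_oracle(self, small_design, rng):
        Y = rng.normal(size=(120, 1))
        bh, _, s2 = fit_vertex_glm(Y, small_design)
        X = small_design.X
        expect = np.linalg.solve(X.T @ X, X.T @ Y[:, 0])
        np.testing.assert_allclose(bh[0], expect, atol=1e-10)
        r = Y[:, 0] - X @ expect
        assert s2[0] == pytest.approx(r @ r / (120 - 2))

    def test_null_data_estimates_center_on_zero(self, small_design, rng):
        reps = 200
        means = np.zeros(2)
        for _ in range(reps):
            Y = rng.normal(size=(120, 1))
            bh, _, _ = fit_vertex_glm(Y, small_design)
            means += bh[0]
        means /= reps
        X = small_design.X
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) / reps)
        assert np.all(np.abs(means) < 4 * se)

    def test_rank_deficient_design_names_columns(self, rng):
        stims = [
            StimulusTrain("a", np.array([0.0]), np.array([15.0])),
            StimulusTrain("acopy", np.array([0.0]), np.array([15.0])),
        ]
        basis = build_basis("canonical", 1, 1.0)
        with pytest.warns(UserWarning):
            d = build_design(stims, basis, 100, 1.0)
        with pytest.raises(np.linalg.LinAlgError, match="acopy"):
            fit_vertex_glm(rng.normal(size=(100, 3)), d)

    def test_nuisance_projected_from_both_sides(self, rng):
        stims = [StimulusTrain("a", np.arange(0.0, 110.0, 30.0), np.full(4, 15.0))]
        basis = build_basis("canonical", 1, 1.0)
        trend = np.column_stack([np.ones(120), np.arange(120.0)])
        d = build_design(stims, basis, 120, 1.0, nuisance=trend)
        beta_true = np.array([[1.5]])
        drift = 0.4 + 0.02 * np.arange(120.0)
        Y = d.X @ beta_true.T + drift[:, None]
        bh, _, _ = fit_vertex_glm(Y, d)
        np.testing.assert_allclose(bh, beta_true, atol=1e-8)


class TestYuleWalker:
    def test_ar1_consistency(self):
        rng = np.random.default_rng(11)
        x = np.zeros(5000)
        e = rng.normal(size=5000)
        for t in range(1, 5000):
            x[t] = 0.5 * x[t - 1] + e[t]
        phi, s2 = yule_walker_ar(x, 1)
        assert 0.45 <= phi[0] <= 0.55
        assert 0.9 <= s2 <= 1.1

    def test_white_noise_coefficient_shrinks(self):
        rng = np.random.default_rng(3)
        small = [abs(yule_walker_ar(rng.normal(size=4000), 1)[0][0]) for _ in range(5)]
        assert np.median(small) < 0.05

    def test_order_zero_returns_sample_variance(self, rng):
        x = rng.normal(size=200) * 2.0
        phi, s2 = yule_walker_ar(x, 0)
        assert phi.size == 0
        assert s2 == pytest.approx(np.mean(x**2))

    def test_constant_series_degenerate(self):
        phi, s2 = yule_walker_ar(np.ones(100), 1)
        np.testing.assert_array_equal(phi, [0.0])
        assert s2 == 0.0

    def test_estimated_models_are_stationary(self, rng):
        for _ in range(10):
            phi, _ = yule_walker_ar(rng.normal(size=300), 3)
            roots = np.roots(np.concatenate([[1.0], -phi]))
            assert np.all(np.abs(roots) < 1.0)


class TestWhitening:
    def test_order_zero_is_scaling(self, rng):
        x = rng.normal(size=50)
        np.testing.assert_allclose(ar_whiten(x, np.empty(0), 4.0), x / 2.0)

    @pytest.mark.parametrize("phi", [[0.5], [-0.7], [0.4, -0.3]])
    def test_whitened_covariance_is_identity(self, phi):
        # brute force: build dense Toeplitz Sigma and check L Sigma L' = I
        phi = np.array(phi)
        T = 6
        nm = NoiseModel(
            p=phi.size, ar_coeffs=phi[None, :], innovation_var=np.array([1.7]), T=T
        )
        Sigma = nm.covariance(0)
        L = np.column_stack(
            [ar_whiten(np.eye(T)[:, j], phi, 1.7) for j in range(T)]
        )
        np.testing.assert_allclose(L @ Sigma @ L.T, np.eye(T), atol=1e-10)

    def test_ar1_precision_is_tridiagonal(self):
        phi = np.array([0.6])
        T = 8
        L = np.column_stack(
            [ar_whiten(np.eye(T)[:, j], phi, 1.0) for j in range(T)]
        )
        P = L.T @ L
        mask = np.abs(np.subtract.outer(np.arange(T), np.arange(T))) > 1
        np.testing.assert_allclose(P[mask], 0.0, atol=1e-12)

    def test_non_stationary_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            ar_whiten(np.zeros(10), np.array([1.05]), 1.0)

    def test_matrix_columns_whitened_independently(self, rng):
        X = rng.normal(size=(30, 3))
        phi = np.array([0.4])
        W = ar_whiten(X, phi, 2.0)
        for j in range(3):
            np.testing.assert_allclose(W[:, j], ar_whiten(X[:, j], phi, 2.0))


def _tiny_instance(seed, T=20, V=12, M=4, phi=0.5):
    """Small parcel with AR(1) noise and a dense-solvable design."""
    rng = np.random.default_rng(seed)
    onsets = np.arange(0.0, T - 1.0, 8.0)
    stims = [StimulusTrain("a", onsets, np.full(onsets.size, 4.0))]
    basis = build_basis("canonical", 1, 1.0)
    X = build_design(stims, basis, T, 1.0)
    coords = rng.normal(size=(V, 2))
    geom = ParcelGeometry("tiny", np.arange(V), coords)
    S = build_tprs(geom, M)
    design = ParcelDesign(X=X, S=S)
    gamma = rng.normal(size=M)
    beta = (S.S @ gamma)[:, None]  # V x 1
    E = np.empty((T, V))
    for v in range(V):
        e = rng.normal(size=T)
        for t in range(1, T):
            e[t] += phi * e[t - 1]
        E[:, v] = e
    Y = X.X @ beta.T + 0.5 * E
    return design, Y, beta


class TestFitSplash:
    def test_noiseless_in_span_is_exact(self, rng):
        design, _, beta = _tiny_instance(0)
        Y = design.X.X @ beta.T
        for est in ("ols", "fgls"):
            fit = fit_splash(Y, design, estimator=est, ar_order=0)
            np.testing.assert_allclose(fit.beta_sp, beta, atol=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_structured_solver_matches_dense_oracle(self, seed):
        design, Y, _ = _tiny_instance(seed)
        A = design.materialize_A()
        y = Y.T.reshape(-1)  # stacked location-major [y_1; ...; y_V]
        # dense OLS oracle
        fit = fit_splash(Y, design, estimator="ols")
        expect = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(fit.gamma_hat, expect, atol=1e-8)
        # dense FGLS oracle with explicit block-diagonal covariance
        noise = estimate_noise(fit_vertex_glm(Y, design.X)[1], 1)
        fit_g = fit_splash(Y, design, estimator="fgls", noise=noise)
        T, V = Y.shape
        Wd = np.zeros((T * V, T * V))
        for v in range(V):
            Lv = np.column_stack(
                [
                    ar_whiten(np.eye(T)[:, j], noise.ar_coeffs[v], noise.innovation_var[v])
                    for j in range(T)
                ]
            )
            Wd[v * T : (v + 1) * T, v * T : (v + 1) * T] = Lv
        expect_g = np.linalg.lstsq(Wd @ A, Wd @ y, rcond=None)[0]
        np.testing.assert_allclose(fit_g.gamma_hat, expect_g, atol=1e-8)

    def test_permutation_maps_are_inverse(self):
        design, _, _ = _tiny_instance(0)
        perm = design.permutation()
        inv = np.empty_like(perm)
        inv[perm] = np.arange(perm.size)
        np.testing.assert_array_equal(perm[inv], np.arange(perm.size))

    def test_full_dimension_reduces_to_vertex_glm(self, rng):
        design, Y, _ = _tiny_instance(4)
        V = design.V
        full = ParcelDesign(X=design.X, S=build_tprs(design.S.geometry, V))
        fit = fit_splash(Y, full, estimator="ols")
        beta_glm, _, _ = fit_vertex_glm(Y, design.X)
        np.testing.assert_allclose(fit.beta_sp, beta_glm, atol=1e-9)

    def test_minimal_dimension_is_best_affine_field(self, rng):
        design, Y, _ = _tiny_instance(5)
        geom = design.S.geometry
        aff = ParcelDesign(X=design.X, S=build_tprs(geom, geom.null_dim))
        fit = fit_splash(Y, aff, estimator="ols")
        beta_glm, _, _ = fit_vertex_glm(Y, design.X)
        P = np.column_stack([np.ones(geom.V), geom.coords])
        proj = P @ np.linalg.lstsq(P, beta_glm, rcond=None)[0]
        np.testing.assert_allclose(fit.beta_sp, proj, atol=1e-8)

    def test_variance_estimates_positive_and_consistent_shapes(self):
        design, Y, _ = _tiny_instance(6)
        fit = fit_splash(Y, design, estimator="fgls")
        assert fit.var_beta_sp.shape == fit.beta_sp.shape
        assert np.all(fit.var_beta_sp >= 0)
        assert np.all(np.diag(fit.var_gamma) > 0)

def test_overparameterized_model_rejected():
    with pytest.raises(ValueError):
        _tiny_instance(7, T=3, V=2, M=3)


class TestFGLSConsistency:
    def test_bias_shrinks_with_replicates(self):
        # averaging the FGLS estimate over growing numbers of independent
        # replicate datasets should converge to the true coefficients
        rng = np.random.default_rng(77)
        design, _, _ = _tiny_instance(10, T=30, V=8, M=4, phi=0.4)
        gamma_true = rng.normal(size=design.M)
        beta = (design.S.S @ gamma_true)[:, None]
        signal = design.X.X @ beta.T
        errs = []
        for N in (10, 100, 1000):
            acc = np.zeros(design.M)
            for _ in range(N):
                T, V = signal.shape
                E = rng.normal(size=(T, V))
                for t in range(1, T):
                    E[t] += 0.4 * E[t - 1]
                fit = fit_splash(signal + E, design, estimator="fgls", ar_order=1)
                acc += fit.gamma_hat
            errs.append(np.linalg.norm(acc / N - gamma_true))
        assert errs[2] < errs[1] < errs[0]


class TestBIC:
    def test_penalty_monotone_in_dimension(self):
        design, Y, _ = _tiny_instance(8)
        geom = design.S.geometry
        f_small = fit_splash(Y, design, estimator="ols")
        big = ParcelDesign(X=design.X, S=build_tprs(geom, 9))
        f_big = fit_splash(Y, big, estimator="ols")
        # force identical residual likelihood to isolate the penalty
        f_big.rss = f_small.rss
        assert bic_score(Y, big, f_big) > bic_score(Y, design, f_small)

    def test_hand_computed_toy(self):
        # 3 observations, one location, one regressor, one spline function
        X = build_design(
            [StimulusTrain("a", np.array([0.0]), np.array([0.0]))],
            build_basis("fir", 1, 1.0, window=1.0),
            3,
            1.0,
        )
        S = SplineBasis(
            S=np.array([[1.0]]), M=1, null_dim=1, eigen_spectrum=np.empty(0),
            geometry=None,
        )
        design = ParcelDesign(X=X, S=S)
        Y = np.array([[1.0], [0.5], [-0.5]])
        fit = fit_splash(Y, design, estimator="ols")
        # by hand: X = e_0, beta_hat = 1, rss = 0.5, n = 3, k = 1
        assert fit.rss == pytest.approx(0.5)
        n, k, rss = 3, 1, 0.5
        expect = n * (np.log(2 * np.pi * rss / n) + 1.0) + k * np.log(n)
        assert bic_score(Y, design, fit) == pytest.approx(expect)

    def test_noiseless_data_selects_smallest_sufficient_dimension(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(20, 2))
        geom = ParcelGeometry("p", np.arange(20), coords)
        X = build_design(
            [StimulusTrain("a", np.arange(0.0, 50.0, 16.0), np.full(4, 8.0))],
            build_basis("canonical", 1, 1.0),
            60,
            1.0,
        )
        S6 = build_tprs(geom, 6)
        gamma = rng.normal(size=6)
        Y = X.X @ ((S6.S @ gamma)[:, None]).T  # T x V
        M_star, fits = select_basis_dim(
            [Y], lambda M: ParcelDesign(X=X, S=build_tprs(geom, M)), [4, 6, 9, 14]
        )
        assert M_star == 6
        assert fits[0].M == 6

    def test_singleton_grid_returned(self):
        design, Y, _ = _tiny_instance(11)
        geom = design.S.geometry
        M_star, _ = select_basis_dim(
            [Y], lambda M: ParcelDesign(X=design.X, S=build_tprs(geom, M)), [5]
        )
        assert M_star == 5

    def test_empty_grid_rejected(self):
        design, Y, _ = _tiny_instance(12)
        with pytest.raises(ValueError):
            select_basis_dim([Y], lambda M: design, [])


def test_default_m_grid_bounds():
    grid = default_m_grid(100, 4)
    assert grid[0] >= 5 and grid[-1] == 100
    assert all(g1 < g2 for g1, g2 in zip(grid, grid[1:]))
    assert default_m_grid(6, 4) == [5, 6]
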