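import numpy as np
import pytest

from hbdot.geometry import extinction_matrix
from hbdot.reconstruct import (DotImage, HBPrior, ReconConfig, build_smoother,
                               compute_lambda0, depth_weights, evidence_alpha,
                               hb_m_step, hb_reconstruct, mn_operator,
                               mn_reconstruct, smooth_image, unmix_hemoglobin)
from hbdot.simulate import make_phantom


def tikhonov_oracle(S, L, alpha, y):
    """Direct normal-equation solution of the depth-weighted problem."""
    St = S / L
    V = S.shape[1]
    xt = np.linalg.solve(St.T @ St + alpha * np.eye(V), St.T @ y)
    return xt / L[:, None]


class TestDepthWeights:
    def test_uniform_columns_give_uniform_weights(self, small_sensitivity):
        rho2 = small_sensitivity.rho2()
        L, beta = depth_weights(small_sensitivity, "MN_WU")
        assert beta == 0.1
        np.testing.assert_allclose(L, np.sqrt(rho2 + 0.1))

    def test_mn_beta_from_20mm_band(self, small_sensitivity):
        L, beta = depth_weights(small_sensitivity, "MN")
        rho2 = small_sensitivity.rho2()
        band = (small_sensitivity.grid.depth >= 18) & (small_sensitivity.grid.depth <= 22)
        assert beta == pytest.approx(rho2[band].mean())

    def test_smaller_rho2_gives_smaller_weight(self, small_sensitivity):
        L, _ = depth_weights(small_sensitivity, "MN_WU")
        rho2 = small_sensitivity.rho2()
        order = np.argsort(rho2)
        assert (np.diff(L[order]) >= 0).all()


class TestEvidenceAlpha:
    def test_self_consistency_on_ill_conditioned_system(self, rng):
        C, V, T = 96, 300, 2000
        St = rng.standard_normal((C, V)) * np.logspace(0, -3, V)[None, :]
        alpha_true = 1e-2
        X = rng.standard_normal((V, T))
        Y = St @ X + rng.standard_normal((C, T)) * np.sqrt(alpha_true)
        alpha, info = evidence_alpha(Y, St)
        # within one grid step (factor 10**(1/6)) of the truth
        assert abs(np.log10(alpha) - np.log10(alpha_true)) <= 1.0 / 6 + 1e-9

    def test_argmax_contract(self, rng):
        St = rng.standard_normal((10, 20))
        Y = St @ rng.standard_normal((20, 50))
        alpha, info = evidence_alpha(Y, St)
        i = np.argmin(np.abs(info["grid"] - alpha))
        assert info["log_evidence"][i] == info["log_evidence"].max()

    def test_pure_noise_selects_heavy_regularization(self, rng):
        """Spatially structureless data pushes alpha to the top of the
        grid (relative to the design scale)."""
        St = rng.standard_normal((30, 100)) * np.logspace(0, -2, 100)[None, :]
        Y = rng.standard_normal((30, 3000))
        alpha, info = evidence_alpha(Y, St)
        g0 = np.trace(St @ St.T) / 30
        signal_fit, _ = evidence_alpha(St @ np.random.default_rng(0).standard_normal((100, 3000)), St)
        assert alpha / g0 > signal_fit / g0

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError):
            evidence_alpha(np.zeros((4, 10)), np.eye(4))


class TestMinimumNorm:
    def test_identity_system_halves_data(self):
        S = np.eye(3)
        A = mn_operator(S, np.ones(3), 1.0)
        y = np.array([[2.0], [4.0], [-6.0]])
        np.testing.assert_allclose(A @ y, y / 2.0, atol=1e-12)

    def test_matches_tikhonov_oracle(self, rng):
        for _ in range(5):
            S = rng.standard_normal((10, 50))
            nn = (S ** 2).sum(axis=0)
            L = np.sqrt(nn / nn.max() + 0.1)
            y = rng.standard_normal((10, 3))
            x = mn_operator(S, L, 0.1) @ y
            ref = tikhonov_oracle(S, L[None, :] * np.ones((10, 1)) if False else L, 0.1, y)
            np.testing.assert_allclose(x, ref, rtol=1e-8, atol=1e-10)

    def test_residual_monotone_in_alpha(self, rng):
        S = rng.standard_normal((12, 40))
        nn = (S ** 2).sum(axis=0)
        L = np.sqrt(nn / nn.max() + 0.1)
        y = rng.standard_normal((12, 1))
        resid = []
        for alpha in np.logspace(-4, 2, 13):
            x = mn_operator(S, L, alpha) @ y
            resid.append(np.linalg.norm(y - S @ x))
        assert (np.diff(resid) >= -1e-10).all()

    def test_zero_alpha_rejected(self):
        with pytest.raises(ValueError):
            mn_operator(np.eye(2), np.ones(2), 0.0)


class TestLambda0:
    def test_constant_solution(self):
        img = np.full((5, 20), 2.0)
        np.testing.assert_allclose(compute_lambda0(img), 4.0)

    def test_zero_solution_floored(self):
        lam0 = compute_lambda0(np.zeros((5, 10)), eps=1e-12)
        np.testing.assert_allclose(lam0, 1e-12)

    def test_matches_loop_oracle(self, rng):
        X = rng.standard_normal((7, 31))
        ref = np.array([np.mean([X[v, t] ** 2 for t in range(31)])
                        for v in range(7)])
        np.testing.assert_allclose(compute_lambda0(X), ref, atol=1e-12)


class TestHierarchicalBayes:
    def test_infinite_confidence_recovers_lambda0_ridge(self, rng):
        V, C, T = 40, 15, 200
        S = rng.standard_normal((C, V))
        lam0 = rng.uniform(0.5, 2.0, V)
        sigma2 = 0.3
        Y = S @ rng.standard_normal((V, T)) + np.sqrt(sigma2) * rng.standard_normal((C, T))
        prior = HBPrior(lambda0=lam0, gamma0=1e12 * T)
        cfg = ReconConfig(algorithm="HB", sigma2=sigma2, update_noise=False)
        img = hb_reconstruct(Y, S, compartments=np.full(V, "cortex"),
                             prior=prior, config=cfg)
        ridge = np.diag(lam0) @ S.T @ np.linalg.solve(
            S @ np.diag(lam0) @ S.T + sigma2 * np.eye(C), Y)
        err = np.abs(img.data - ridge).max() / np.abs(ridge).max()
        assert err < 1e-6

    def test_zero_confidence_mstep_is_pure_ard(self, rng):
        T = 100
        Ex2 = rng.uniform(0.1, 5.0, 30) * T
        lam0 = rng.uniform(0.5, 2.0, 30)
        np.testing.assert_allclose(hb_m_step(Ex2, lam0, 0.0, T), Ex2 / T,
                                   atol=1e-15)
        # and the infinite limit pins the prior mean
        big = hb_m_step(Ex2, lam0, 1e14 * T, T)
        np.testing.assert_allclose(big, lam0, rtol=1e-10)

    def test_inactive_voxels_shrink_on_sparse_phantom(self, rng):
        """With a noise-free sparse source, the variances of truly silent
        voxels decrease over the first iterations of the data-driven
        update."""
        V, C, T = 30, 20, 400
        S = rng.standard_normal((C, V))
        X = np.zeros((V, T))
        X[3] = rng.standard_normal(T)
        Y = S @ X
        lam_hist = []
        lam = np.full(V, 1.0)
        sigma2 = 1e-4
        Cyy = Y @ Y.T
        for _ in range(20):
            Fl = S * lam[None, :]
            M = Fl @ S.T + sigma2 * np.eye(C)
            A = np.linalg.solve(M, Fl).T
            Ex2 = np.einsum("vc,vc->v", A @ Cyy, A) + T * np.maximum(
                lam - np.einsum("vc,cv->v", A, Fl), 0)
            lam = hb_m_step(Ex2, np.zeros(V), 0.0, T)
            lam_hist.append(lam.copy())
        lam_hist = np.array(lam_hist)
        silent = np.ones(V, dtype=bool)
        silent[3] = False
        assert (np.diff(lam_hist[:, silent], axis=0) <= 1e-12).all()
        assert lam_hist[-1, 3] > 100 * lam_hist[-1, silent].max()

    def test_gamma0_sweep_values_accepted(self, rng):
        V, C, T = 10, 6, 50
        S = rng.standard_normal((C, V))
        Y = S @ rng.standard_normal((V, T))
        for scale in (0.1, 0.01, 0.001, 0.0001):
            cfg = ReconConfig(algorithm="HB", gamma0=scale * T, max_iter=5,
                              sigma2=0.1, update_noise=False)
            img = hb_reconstruct(Y, S, compartments=np.full(V, "cortex"),
                                 prior=HBPrior(np.ones(V), scale * T),
                                 config=cfg)
            assert img.diagnostics["gamma0"] == scale * T

    def test_phantom_localization_beats_minimum_norm(self):
        (layout, grid, S), Y, truth, X = make_phantom(seed=0)
        from hbdot.simulate import cortical_peak_error

        T = Y.shape[1]
        img_hb = hb_reconstruct(Y, S, config=ReconConfig(
            algorithm="HB", max_iter=200, tol=1e-3, gamma0=0.1 * T))
        img_mn = mn_reconstruct(Y, S, ReconConfig(algorithm="MN"))
        err_hb = cortical_peak_error(img_hb.data, grid, truth)
        err_mn = cortical_peak_error(img_mn.data, grid, truth)
        assert err_hb <= 4.0
        assert err_hb < err_mn


class TestUnmixing:
    def test_round_trip(self):
        E = extinction_matrix()
        oxy = np.array([[1.0, 2.0]])
        deoxy = np.array([[-1.0, 0.5]])
        dmua = {w: E.E[i, 0] * oxy + E.E[i, 1] * deoxy
                for i, w in enumerate(E.wavelengths)}
        o, d = unmix_hemoglobin(dmua, E)
        np.testing.assert_allclose(o, oxy, atol=1e-12)
        np.testing.assert_allclose(d, deoxy, atol=1e-12)

    def test_matches_normal_equation_oracle(self, rng):
        E = extinction_matrix()
        dmua = rng.standard_normal((3, 6, 11))
        o, d = unmix_hemoglobin({w: dmua[i] for i, w in enumerate(E.wavelengths)}, E)
        flat = dmua.reshape(3, -1)
        ref = np.linalg.solve(E.E.T @ E.E, E.E.T @ flat).reshape(2, 6, 11)
        np.testing.assert_allclose(o, ref[0], atol=1e-12)
        np.testing.assert_allclose(d, ref[1], atol=1e-12)

    def test_zero_in_zero_out(self):
        E = extinction_matrix()
        o, d = unmix_hemoglobin({w: np.zeros((4, 5)) for w in E.wavelengths}, E)
        assert not o.any() and not d.any()


class TestSmoothing:
    def test_delta_profile_half_maximum_near_4mm(self, small_grid):
        K = build_smoother(small_grid, fwhm=8.0)
        # pick an interior cortical voxel
        cm = np.flatnonzero(small_grid.cortex_mask)
        center = small_grid.centers[cm].mean(axis=0)
        v = cm[np.argmin(np.linalg.norm(small_grid.centers[cm] - center, axis=1))]
        delta = np.zeros(small_grid.n_voxels)
        delta[v] = 1.0
        out = K.T @ delta  # response profile of a delta source
        d = np.linalg.norm(small_grid.centers - small_grid.centers[v], axis=1)
        prof = out / out[v]
        # half maximum reached between 4 mm and the next voxel shell
        inside = (d <= 4.0) & small_grid.cortex_mask
        outside = (d >= 8.0) & small_grid.cortex_mask
        assert prof[inside].min() >= 0.5 - 1e-9
        assert prof[outside].max() < 0.5

    def test_constant_image_preserved(self, small_grid):
        img = np.ones((small_grid.n_voxels, 3))
        out = smooth_image(img, small_grid, fwhm=8.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_compartments_do_not_mix(self, small_grid):
        img = np.zeros((small_grid.n_voxels, 1))
        img[small_grid.scalp_mask] = 1.0
        out = smooth_image(img, small_grid, fwhm=8.0)
        np.testing.assert_allclose(out[small_grid.cortex_mask], 0.0, atol=1e-15)

    def test_small_fwhm_warns(self, small_grid):
        with pytest.warns(UserWarning):
            smooth_image(np.ones((small_grid.n_voxels, 1)), small_grid, fwhm=2.0)
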