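"""EM core: densities, regularization, E/M steps against brute-force
references, likelihood ascent and structural invariants."""

import numpy as np
import pytest

import oracles
from pairvox import (
    AnchorMap,
    EMTrace,
    Hyperparams,
    build_grid,
    e_step,
    features_from_frames,
    gaussian_logdensity,
    init_params,
    log_likelihood,
    m_step,
    regularize_covariance,
    run_em,
)
from pairvox.vrgmm import ParamSet, _m_step, density_evals
from conftest import random_pair


def random_params(rng, grid, spread=30.0):
    """Valid random parameters on a grid (SPD covariances, means in frame)."""
    K = grid.K

    def spd(d, scale):
        A = rng.normal(size=(K, d, d))
        return A @ np.swapaxes(A, 1, 2) + scale * np.eye(d)

    return ParamSet(
        mu_s=rng.uniform(0, [grid.W, grid.H], size=(K, 2)),
        Sigma_s=spd(2, 4.0),
        mu_s_hat=rng.uniform(0, [grid.W, grid.H], size=(K, 2)),
        Sigma_s_hat=spd(2, 4.0),
        mu_c=rng.uniform(0, spread, size=(K, 3)),
        Sigma_c=spd(3, 25.0),
    )


class TestGaussianLogdensity:
    def test_at_mode(self, rng):
        for D in (2, 3, 5):
            A = rng.normal(size=(D, D))
            S = A @ A.T + np.eye(D)
            mu = rng.normal(size=D)
            expected = -0.5 * D * np.log(2 * np.pi) - 0.5 * np.log(np.linalg.det(S))
            assert gaussian_logdensity(mu, mu, S) == pytest.approx(expected, rel=1e-12)

    def test_unit_isotropic_closed_form(self):
        val = gaussian_logdensity([1.0, 0.0], [0.0, 0.0], np.eye(2))
        assert val == pytest.approx(-np.log(2 * np.pi) - 0.5, rel=1e-14)

    def test_block_diagonal_splits(self, rng):
        """5-D density with block-diagonal covariance = spatial + color parts."""
        As = rng.normal(size=(2, 2))
        Ac = rng.normal(size=(3, 3))
        Ss = As @ As.T + np.eye(2)
        Sc = Ac @ Ac.T + np.eye(3)
        S5 = np.zeros((5, 5))
        S5[:2, :2], S5[2:, 2:] = Ss, Sc
        mu = rng.normal(size=5)
        z = rng.normal(size=5)
        full = gaussian_logdensity(z, mu, S5)
        split = gaussian_logdensity(z[:2], mu[:2], Ss) + gaussian_logdensity(z[2:], mu[2:], Sc)
        assert full == pytest.approx(split, rel=1e-12)
        assert full == pytest.approx(np.log(oracles.dense_gaussian(z, mu, S5)), rel=1e-10)


class TestRegularizeCovariance:
    def test_inactive_floor_identity(self, rng):
        A = rng.normal(size=(3, 3))
        S = A @ A.T + 10.0 * np.eye(3)
        np.testing.assert_allclose(regularize_covariance(S, 1e-3), S, atol=1e-10)

    def test_isotropic_flooring(self):
        np.testing.assert_allclose(
            regularize_covariance(np.eye(2), 2.0), 2.0 * np.eye(2), atol=1e-12
        )

    def test_eigenvectors_preserved(self, rng):
        q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        S = q @ np.diag([10.0, 0.5]) @ q.T
        out = regularize_covariance(S, 2.0)
        expected = q @ np.diag([10.0, 2.0]) @ q.T
        np.testing.assert_allclose(out, expected, atol=1e-10)
        np.testing.assert_allclose(out, oracles.floor_eigenvalues(S, 2.0), atol=1e-10)

    def test_result_spd_above_floor(self, rng):
        S = rng.normal(size=(5, 3, 3))
        out = regularize_covariance(S, 0.7)
        w = np.linalg.eigvalsh(out)
        assert np.all(w >= 0.7 - 1e-9)
        np.testing.assert_allclose(out, np.swapaxes(out, 1, 2))

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            regularize_covariance(np.array([[np.nan, 0], [0, 1.0]]), 1.0)


class TestInitParams:
    def test_covariance_initialization(self, grid_5x5, hp, rng):
        f0, f1 = random_pair(rng, 20, 20)
        p = init_params(f0, f1, grid_5x5, hp)
        np.testing.assert_allclose(p.Sigma_s, np.broadcast_to(np.diag([16.0, 16.0]), (25, 2, 2)))
        np.testing.assert_allclose(p.Sigma_s_hat, p.Sigma_s)
        np.testing.assert_allclose(p.Sigma_c, np.broadcast_to(100.0 * np.eye(3), (25, 3, 3)))

    def test_spatial_means_at_centroids(self, grid_5x5, hp, rng):
        f0, f1 = random_pair(rng, 20, 20)
        p = init_params(f0, f1, grid_5x5, hp)
        np.testing.assert_allclose(p.mu_s[0], [1.5, 1.5])
        np.testing.assert_allclose(p.mu_s[24], [17.5, 17.5])
        np.testing.assert_allclose(p.mu_s_hat, p.mu_s)

    def test_color_mean_is_center_voxel_average(self, grid_5x5, hp, rng):
        f0, f1 = random_pair(rng, 20, 20)
        p = init_params(f0, f1, grid_5x5, hp)
        # anchor region 0 covers rows/cols 0..3; centre voxel = floor(1.5) -> (1, 1)
        np.testing.assert_allclose(p.mu_c[0], 0.5 * (f0[1, 1] + f1[1, 1]))

    def test_frame_mismatch_rejected(self, grid_5x5, hp, rng):
        f0, _ = random_pair(rng, 20, 20)
        with pytest.raises(ValueError):
            init_params(f0, f0[:10], grid_5x5, hp)


class TestEStep:
    def test_single_candidate_gets_full_mass(self, hp, rng):
        g = build_grid(4, 4, 4, 4, 1, 1)  # K = 1
        am = AnchorMap(g)
        f0, f1 = random_pair(rng, 4, 4)
        p = init_params(f0, f1, g, hp)
        resp = e_step(features_from_frames(f0, f1), p, am)
        np.testing.assert_array_equal(resp.R.sum(axis=1), 1.0)
        assert np.all(resp.R.max(axis=1) == 1.0)

    def test_identical_components_split_evenly(self, hp):
        g = build_grid(8, 4, 4, 4, 1, 0)  # two cells in a row
        am = AnchorMap(g)
        f0 = np.full((4, 8, 3), 50.0)
        p = init_params(f0, f0, g, hp)
        p.mu_s[:] = [3.5, 1.5]  # same spatial mean for both components
        p.mu_s_hat[:] = [3.5, 1.5]
        resp = e_step(features_from_frames(f0, f0), p, am)
        valid = am.voxel_candidates >= 0
        np.testing.assert_allclose(resp.R[valid], 0.5, atol=1e-12)
        np.testing.assert_array_equal(resp.R[~valid], 0.0)

    def test_matches_brute_force(self, rng, hp):
        g = build_grid(8, 8, 4, 4, 1, 1)
        am = AnchorMap(g)
        f0, f1 = random_pair(rng, 8, 8)
        p = random_params(rng, g)
        resp = e_step(features_from_frames(f0, f1), p, am)
        R_ref, Rh_ref = oracles.brute_e_step(f0, f1, p, g)
        for i in range(64):
            for j, k in enumerate(am.voxel_candidates[i]):
                if k >= 0:
                    assert resp.R[i, j] == pytest.approx(R_ref[i][k], abs=1e-10)
                    assert resp.R_hat[i, j] == pytest.approx(Rh_ref[i][k], abs=1e-10)
                else:
                    assert resp.R[i, j] == 0.0

    def test_normalization_under_extreme_underflow(self, hp):
        """Densities far below double-precision range still normalize."""
        g = build_grid(8, 8, 4, 4, 1, 1)
        am = AnchorMap(g)
        f0 = np.full((8, 8, 3), 50.0)
        f1 = np.full((8, 8, 3), 5000.0)  # ~500 sigma from any color mean
        p = init_params(f0, f0, g, hp)
        resp = e_step(features_from_frames(f0, f1), p, am)
        np.testing.assert_allclose(resp.R.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(resp.R_hat.sum(axis=1), 1.0, atol=1e-10)


class TestMStep:
    def test_constant_color_floors_color_covariance(self, grid_5x5, anchors_5x5, hp):
        f = np.full((20, 20, 3), 42.0)
        feats = features_from_frames(f, f)
        p0 = init_params(f, f, grid_5x5, hp)
        resp = e_step(feats, p0, anchors_5x5)
        p = m_step(feats, resp, anchors_5x5, hp, prev=p0)
        np.testing.assert_allclose(p.mu_c, 42.0)
        np.testing.assert_allclose(p.Sigma_c, np.broadcast_to(8.0 * np.eye(3), (25, 3, 3)), atol=1e-9)

    def test_all_weight_on_one_voxel(self, hp):
        g = build_grid(4, 4, 4, 4, 1, 1)
        am = AnchorMap(g)
        f = np.full((4, 4, 3), 10.0)
        feats = features_from_frames(f, f)
        R = np.zeros((16, am.n_slots))
        R[:, am.n_slots // 2] = 0.0  # K=1: only the centre slot is valid
        valid_slot = int(np.argmax(am.voxel_candidates[0] >= 0))
        R[5, valid_slot] = 1.0
        from pairvox.vrgmm import Responsibilities

        resp = Responsibilities(R=R, R_hat=R.copy())
        p = m_step(feats, resp, am, hp, prev=init_params(f, f, g, hp))
        np.testing.assert_allclose(p.mu_s[0], feats.spatial[5])
        # rank-0 spatial scatter floors to lambda_s * I
        np.testing.assert_allclose(p.Sigma_s[0], hp.lambda_s * np.eye(2), atol=1e-10)

    def test_matches_brute_force(self, rng, hp):
        g = build_grid(8, 8, 4, 4, 1, 1)
        am = AnchorMap(g)
        f0, f1 = random_pair(rng, 8, 8)
        p0 = random_params(rng, g)
        feats = features_from_frames(f0, f1)
        resp = e_step(feats, p0, am)
        p = m_step(feats, resp, am, hp, prev=p0)
        R_ref, Rh_ref = oracles.brute_e_step(f0, f1, p0, g)
        ref = oracles.brute_m_step(f0, f1, R_ref, Rh_ref, g, hp)
        for name in ref:
            np.testing.assert_allclose(getattr(p, name), ref[name], atol=1e-8, err_msg=name)

    def test_empty_component_without_fallback_raises(self, hp):
        g = build_grid(8, 4, 4, 4, 1, 0)
        am = AnchorMap(g)
        f = np.full((4, 8, 3), 10.0)
        feats = features_from_frames(f, f)
        from pairvox.vrgmm import Responsibilities

        R = np.zeros((32, am.n_slots))
        # all mass on the first valid slot -> the other component starves
        first_valid = np.argmax(am.voxel_candidates >= 0, axis=1)
        R[np.arange(32), first_valid] = 1.0
        resp = Responsibilities(R=R, R_hat=R.copy())
        with pytest.raises(ValueError):
            m_step(feats, resp, am, hp, prev=None)
        p_prev = init_params(f, f, g, hp)
        p = m_step(feats, resp, am, hp, prev=p_prev)
        starved = 1  # component with no mass keeps its previous parameters
        np.testing.assert_allclose(p.mu_s[starved], p_prev.mu_s[starved])
        np.testing.assert_allclose(p.Sigma_c[starved], p_prev.Sigma_c[starved])


class TestLogLikelihood:
    def test_matches_brute_force(self, rng):
        g = build_grid(8, 8, 4, 4, 1, 1)
        am = AnchorMap(g)
        f0, f1 = random_pair(rng, 8, 8)
        p = random_params(rng, g)
        ll = log_likelihood(features_from_frames(f0, f1), p, am)
        assert ll == pytest.approx(oracles.brute_log_likelihood(f0, f1, p, g), rel=1e-10)

    def test_single_voxel_at_mode(self, hp):
        g = build_grid(1, 1, 1, 1, 1, 1)
        am = AnchorMap(g)
        f = np.full((1, 1, 3), 7.0)
        p = init_params(f, f, g, hp)
        ll = log_likelihood(features_from_frames(f, f), p, am)
        mode = gaussian_logdensity([0.0, 0.0], p.mu_s[0], p.Sigma_s[0]) + gaussian_logdensity(
            [7.0] * 3, p.mu_c[0], p.Sigma_c[0]
        )
        assert ll == pytest.approx(2 * mode, rel=1e-12)


class TestRunEM:
    def test_zero_iterations_returns_init(self, grid_5x5, rng):
        f0, f1 = random_pair(rng, 20, 20)
        hp0 = Hyperparams(n_iter=0)
        p = run_em(f0, f1, grid_5x5, hp0)
        p_init = init_params(f0, f1, grid_5x5, hp0)
        for name in ("mu_s", "Sigma_s", "mu_c", "Sigma_c"):
            np.testing.assert_array_equal(getattr(p, name), getattr(p_init, name))

    def test_deterministic(self, grid_5x5, hp, rng):
        f0, f1 = random_pair(rng, 20, 20)
        p1 = run_em(f0, f1, grid_5x5, hp)
        p2 = run_em(f0.copy(), f1.copy(), grid_5x5, hp)
        for name in ("mu_s", "Sigma_s", "mu_s_hat", "Sigma_s_hat", "mu_c", "Sigma_c"):
            np.testing.assert_array_equal(getattr(p1, name), getattr(p2, name))

    def test_identical_frames_give_symmetric_parameters(self, grid_5x5, hp, rng):
        f0, _ = random_pair(rng, 20, 20)
        p = run_em(f0, f0.copy(), grid_5x5, hp)
        np.testing.assert_array_equal(p.mu_s, p.mu_s_hat)
        np.testing.assert_array_equal(p.Sigma_s, p.Sigma_s_hat)

    def test_one_iteration_matches_brute_force_em(self, rng, hp):
        """Full E+M sweep against the dense-loop reference on a 12x12 pair."""
        g = build_grid(12, 12, 4, 4, 1, 1)
        f0, f1 = random_pair(rng, 12, 12)
        hp1 = Hyperparams(n_iter=1)
        p = run_em(f0, f1, g, hp1)
        p0 = init_params(f0, f1, g, hp1)
        R_ref, Rh_ref = oracles.brute_e_step(f0, f1, p0, g)
        ref = oracles.brute_m_step(f0, f1, R_ref, Rh_ref, g, hp1)
        for name in ref:
            np.testing.assert_allclose(getattr(p, name), ref[name], atol=1e-8, err_msg=name)

    def test_shared_color_parameters_are_single_objects(self, grid_5x5, hp, rng):
        """Both frames' densities read the very same color arrays."""
        f0, f1 = random_pair(rng, 20, 20)
        p = run_em(f0, f1, grid_5x5, hp)
        assert p.mu_c is p.mu_c and p.Sigma_c.shape == (25, 3, 3)
        # ParamSet holds exactly one color block: nothing frame-specific exists
        assert not hasattr(p, "mu_c_hat") and not hasattr(p, "Sigma_c_hat")

    def test_responsibilities_normalized_every_iteration(self, grid_5x5, anchors_5x5, hp, rng):
        f0, f1 = random_pair(rng, 20, 20)
        feats = features_from_frames(f0, f1)
        p = init_params(f0, f1, grid_5x5, hp)
        for _ in range(hp.n_iter):
            resp = e_step(feats, p, anchors_5x5)
            np.testing.assert_allclose(resp.R.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(resp.R_hat.sum(axis=1), 1.0, atol=1e-10)
            assert resp.R.min() >= 0.0 and resp.R_hat.min() >= 0.0
            p = m_step(feats, resp, anchors_5x5, hp, prev=p)

    def test_likelihood_ascends_when_floors_inactive(self, rng):
        grid = build_grid(20, 20, 4, 4, 2, 2)
        hp_free = Hyperparams(lambda_s=1e-8, lambda_c=1e-8)
        f0, f1 = random_pair(rng, 20, 20)
        trace = EMTrace()
        run_em(f0, f1, grid, hp_free, trace=trace)
        assert not any(trace.floors_active)
        ll = np.asarray(trace.loglik)
        assert np.all(np.diff(ll) >= -1e-6 * np.abs(ll[:-1]))

    def test_likelihood_finite_when_floors_active(self, grid_5x5, hp):
        f = np.full((20, 20, 3), 33.0)  # constant color: floors must fire
        trace = EMTrace()
        run_em(f, f, grid_5x5, hp, trace=trace)
        assert any(trace.floors_active)
        assert np.all(np.isfinite(trace.loglik))

    def test_density_evaluation_budget(self, hp):
        """Per-iteration 5-D density evaluations stay within
        2 * |I| * (2*eta_x+1) * (2*eta_y+1) at two frame sizes."""
        for W, H in [(20, 20), (24, 36)]:
            grid = build_grid(W, H, 4, 4, 2, 2)
            f = np.linspace(0, 100, W * H * 3).reshape(H, W, 3)
            density_evals.reset()
            run_em(f, f[::-1].copy(), grid, hp)
            budget = hp.n_iter * 2 * W * H * (2 * grid.eta_x + 1) * (2 * grid.eta_y + 1)
            assert 0 < density_evals.count <= budget
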