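import numpy as np
import pytest

from petdeconv import (
    ActivityImage,
    BinaryMask,
    DomainError,
    ImageGrid,
    ReconstructedPET,
    build_noise_model,
    build_operator,
    empirical_semivariogram,
    estimate_kernel_width,
    estimate_level_stds,
    fit_gaussian_covariance,
    log_residual,
    simulate_latent,
    simulate_noise,
)
from petdeconv.calibration import gaussian_semivariogram, moving_average


class TestLogResidual:
    def test_self_consistency_gives_zero(self, grid8, random_activity):
        op = build_operator(2.0, grid8)
        obs = ReconstructedPET(grid8, op.apply(random_activity).values)
        resid, norm = log_residual(obs, random_activity, op)
        assert np.allclose(resid, 0, atol=1e-12)
        assert norm == pytest.approx(0, abs=1e-20)

    def test_constant_ratio_gives_constant_residual(self, grid8, random_activity):
        op = build_operator(2.0, grid8)
        obs = ReconstructedPET(grid8, np.e * op.apply(random_activity).values)
        resid, _ = log_residual(obs, random_activity, op)
        assert np.allclose(resid, 1.0, atol=1e-12)

    def test_norm_matches_direct_summation(self, rng):
        g = ImageGrid(4, 4, 2.0)
        ref = ActivityImage(g, rng.uniform(0.5, 2, g.shape))
        obs = ReconstructedPET(g, rng.uniform(0.5, 2, g.shape))
        op = build_operator(1.5, g)
        _, norm = log_residual(obs, ref, op)
        brute = np.sum((np.log(obs.values) - np.log(op.apply(ref).values)) ** 2)
        assert norm == pytest.approx(brute, rel=1e-12)


class TestKernelWidthSearch:
    def test_noise_free_recovery_is_exact_on_grid(self, rng):
        g = ImageGrid(24, 24, 2.08)
        ref = ActivityImage(g, rng.uniform(0.4, 3.0, g.shape))
        true_op = build_operator(3.0, g)
        obs = ReconstructedPET(g, true_op.apply(ref).values)
        fit = estimate_kernel_width(obs, ref, 0.0, 6.0, 0.1)
        assert fit.a_mm == pytest.approx(3.0)

    def test_identity_observation_selects_smallest_a(self, rng):
        g = ImageGrid(12, 12, 2.0)
        ref = ActivityImage(g, rng.uniform(0.4, 3.0, g.shape))
        obs = ReconstructedPET(g, ref.values)
        fit = estimate_kernel_width(obs, ref, 0.0, 4.0, 0.5)
        assert fit.a_mm == 0.0

    def test_empty_grid_rejected(self, grid8, random_activity, random_obs):
        with pytest.raises(ValueError):
            estimate_kernel_width(random_obs, random_activity, 2.0, 1.0, 0.1)


class TestSemivariogram:
    def test_white_noise_flat_at_variance(self, rng):
        field = rng.normal(0, 0.2, (64, 64))
        sv = empirical_semivariogram(field, max_lag=5)
        assert np.allclose(sv.gamma, 0.04, rtol=0.15)

    def test_constant_field_is_zero(self):
        sv = empirical_semivariogram(np.full((16, 16), 3.3), max_lag=4)
        assert np.allclose(sv.gamma, 0.0, atol=1e-25)

    def test_grf_matches_closed_form_model(self):
        g = ImageGrid(128, 128, 1.0)
        sigma = 0.2
        field = sigma * simulate_latent(g, 3.0, seed=11)
        sv = empirical_semivariogram(field, max_lag=10)
        model = gaussian_semivariogram(sv.lags, 3.0, sigma**2)
        assert np.abs(sv.gamma - model).max() < 0.012

    def test_mask_too_small_rejected(self):
        with pytest.raises(ValueError):
            empirical_semivariogram(np.ones((4, 4)), np.zeros((4, 4), bool), max_lag=2)


class TestGaussianCovarianceFit:
    def test_noiseless_model_values_recovered(self):
        lags = np.arange(1.0, 9.0)
        sv_gamma = gaussian_semivariogram(lags, 2.0, 0.01)
        from petdeconv import SemivariogramEstimate

        sv = SemivariogramEstimate(lags, sv_gamma, np.full(lags.size, 1000))
        r, sill = fit_gaussian_covariance(sv)
        assert r == pytest.approx(2.0, abs=1e-6)
        assert sill == pytest.approx(0.01, abs=1e-8)

    def test_simulated_grf_recovery_within_15pct(self):
        g = ImageGrid(128, 128, 1.0)
        field = 0.2 * simulate_latent(g, 3.0, seed=5)
        sv = empirical_semivariogram(field, max_lag=10)
        r, sill = fit_gaussian_covariance(sv)
        assert abs(r - 3.0) / 3.0 < 0.15
        assert abs(sill - 0.04) / 0.04 < 0.15

    def test_too_few_bins_rejected(self):
        from petdeconv import SemivariogramEstimate

        sv = SemivariogramEstimate(np.array([1.0, 2.0]), np.array([0.1, 0.2]), np.array([5, 5]))
        with pytest.raises(ValueError):
            fit_gaussian_covariance(sv)


class TestLevelStds:
    def test_constant_region_flags_degenerate(self, grid8):
        obs = ReconstructedPET(grid8, np.full(grid8.shape, 0.43))
        mask = BinaryMask(grid8, np.ones(grid8.shape, bool))
        with pytest.warns(UserWarning, match="degenerate"):
            out = estimate_level_stds(obs, [mask])
        assert out[0][0] == pytest.approx(0.43)
        assert out[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_lognormal_region_std_recovered(self):
        g = ImageGrid(50, 40, 2.0)
        rng = np.random.default_rng(3)
        vals = 10 ** (np.log10(0.43) + 0.1060 * rng.standard_normal(g.shape))
        obs = ReconstructedPET(g, vals)
        mask = BinaryMask(g, np.ones(g.shape, bool))
        (_, std), = estimate_level_stds(obs, [mask])
        assert std == pytest.approx(0.1060, abs=0.005)


class TestNoiseModel:
    def test_std_at_level_floor_anchor_and_midpoint(self, grid8):
        obs = ReconstructedPET(grid8, np.full(grid8.shape, 1.0))
        nm = build_noise_model(obs)
        assert nm.std_at_level(0.20) == pytest.approx(0.1060)
        assert nm.std_at_level(0.43) == pytest.approx(0.1060)
        assert nm.std_at_level(2.77) == pytest.approx(0.0402)
        assert nm.std_at_level(10.0) == pytest.approx(0.0402)
        mid = 0.5 * (0.43 + 2.77)
        assert nm.std_at_level(mid) == pytest.approx(0.5 * (0.1060 + 0.0402), abs=1e-4)
        assert nm.std_at_level(1.60) == pytest.approx(0.0731, abs=5e-5)

    def test_std_monotone_non_increasing(self, grid8):
        obs = ReconstructedPET(grid8, np.full(grid8.shape, 1.0))
        nm = build_noise_model(obs)
        levels = np.linspace(0.1, 5.0, 50)
        stds = nm.std_at_level(levels)
        assert np.all(np.diff(stds) <= 1e-12)

    def test_diagonal_when_range_zero(self, grid8, random_obs):
        nm = build_noise_model(random_obs, range_px=0.0)
        C = nm.covariance()
        assert np.allclose(C, np.diag(np.diag(C)))

    def test_constant_obs_gives_stationary_covariance(self, grid8):
        obs = ReconstructedPET(grid8, np.full(grid8.shape, 0.43))
        nm = build_noise_model(obs, range_px=1.85)
        C = nm.covariance()
        assert np.allclose(np.diag(C), C[0, 0])

    def test_covariance_equals_brute_force_construction(self):
        g = ImageGrid(6, 6, 2.0)
        rng = np.random.default_rng(8)
        obs = ReconstructedPET(g, rng.uniform(0.3, 3.0, g.shape))
        nm = build_noise_model(obs, range_px=1.5, inflation=1.2, window=4)
        # independent brute-force: smoothed level -> stds -> D^1/2 R D^1/2
        level = moving_average(obs.values, 4)
        std = np.interp(level, [0.43, 2.77], [0.1060, 0.0402]) * np.sqrt(1.2)
        s = std.ravel()
        ii, jj = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        pos = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
        d2 = ((pos[:, None] - pos[None, :]) ** 2).sum(-1)
        R_ref = 0.95 * np.exp(-d2 / 1.5**2) + 0.05 * np.eye(36)
        C_ref = R_ref * np.outer(s, s)
        assert np.abs(nm.covariance() - C_ref).max() < 1e-12

    def test_moving_average_truncates_at_edges(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 2.0, (6, 6))
        ma = moving_average(vals, 3)
        # odd window: plain local means with edge truncation
        assert ma[2, 2] == pytest.approx(vals[1:4, 1:4].mean())
        assert ma[0, 0] == pytest.approx(vals[:2, :2].mean())
        # constant field is a fixed point regardless of window parity
        assert np.allclose(moving_average(np.full((5, 5), 0.43), 4), 0.43)
        # every value lies between the local extremes (convex averaging)
        assert ma.min() >= vals.min() and ma.max() <= vals.max()

    def test_non_positive_obs_rejected(self, grid8):
        vals = np.ones(grid8.shape)
        vals[0, 0] = -1.0
        with pytest.raises(DomainError):
            ReconstructedPET(grid8, vals)


class TestSimulateNoise:
    def test_zero_variance_returns_mean(self, grid8):
        mean = ReconstructedPET(grid8, np.full(grid8.shape, 0.7))
        nm = build_noise_model(mean, inflation=0.0)
        out = simulate_noise(nm, mean, seed=1)
        assert np.array_equal(out.values, mean.values)

    def test_marginal_std_includes_inflation(self):
        g = ImageGrid(64, 64, 2.08)
        mean = ReconstructedPET(g, np.full(g.shape, 0.43))
        nm = build_noise_model(mean, range_px=1.85)
        rng = np.random.default_rng(17)
        draws = [nm.simulate(mean, rng).values for _ in range(60)]
        pooled = np.std(np.log10(np.stack(draws)))
        assert pooled == pytest.approx(0.1060 * np.sqrt(1.2), rel=0.03)

    def test_simulated_field_semivariogram_matches_model(self):
        g = ImageGrid(64, 64, 2.08)
        mean = ReconstructedPET(g, np.full(g.shape, 0.43))
        nm = build_noise_model(mean, range_px=2.0)
        rng = np.random.default_rng(23)
        sill = (0.1060**2) * 1.2
        fields = [
            np.log10(nm.simulate(mean, rng).values) - np.log10(0.43) for _ in range(4)
        ]
        gammas = []
        for field in fields:
            sv = empirical_semivariogram(field, max_lag=6)
            gammas.append(sv.gamma)
        gamma = np.mean(gammas, axis=0)
        model = gaussian_semivariogram(sv.lags, 2.0, sill)
        assert np.abs(gamma - model).max() < 0.25 * sill
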