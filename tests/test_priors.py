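import numpy as np
import pytest
from scipy.special import ndtri
from scipy.stats import kstest, norm

from petdeconv import (
    GaussianRandomField,
    ImageGrid,
    TissueMixture,
    TransformedGaussianPrior,
    TrimodalTissuePrior,
    TruncatedBimodalPrior,
    perturb_latent,
    realize_rho1,
    realize_rho2,
    simulate_latent,
)
from petdeconv.priors import block_conditional_resample, perturb_white


class TestGaussianRandomField:
    def test_zero_range_is_white_noise(self):
        g = ImageGrid(40, 40, 1.0)
        f = simulate_latent(g, 0.0, seed=1)
        # no spatial correlation at lag 1
        c = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert abs(c) < 0.06
        assert f.std() == pytest.approx(1.0, abs=0.05)

    def test_same_seed_reproduces_field(self):
        g = ImageGrid(16, 16, 1.0)
        a = simulate_latent(g, 5.0, seed=42)
        b = simulate_latent(g, 5.0, seed=42)
        assert np.array_equal(a, b)

    def test_marginal_moments_and_lag_correlation(self):
        g = ImageGrid(64, 64, 1.0)
        grf = GaussianRandomField(g, 10.0)
        rng = np.random.default_rng(7)
        fields = np.stack([grf.sample(rng) for _ in range(200)])
        assert fields.mean() == pytest.approx(0.0, abs=0.03)
        assert fields.var() == pytest.approx(1.0, abs=0.05)
        # closed form: corr at lag 5 is exp(-25/100)
        cs = [np.corrcoef(f[:, :-5].ravel(), f[:, 5:].ravel())[0, 1] for f in fields]
        assert np.mean(cs) == pytest.approx(np.exp(-0.25), abs=0.05)

    def test_negative_range_rejected(self):
        with pytest.raises(ValueError):
            GaussianRandomField(ImageGrid(8, 8, 1.0), -1.0)


class TestPerturbation:
    def test_small_step_keeps_field_close(self):
        g = ImageGrid(32, 32, 1.0)
        grf = GaussianRandomField(g, 4.0)
        rng = np.random.default_rng(0)
        z = grf.sample(rng)
        w = grf.sample(rng)
        for step in (0.1, 0.01, 0.001):
            d = np.abs(perturb_latent(z, w, step) - z).max()
            assert d <= step * np.abs(w).max() + step**2 * np.abs(z).max()

    def test_step_one_is_independent_draw(self):
        g = ImageGrid(32, 32, 1.0)
        grf = GaussianRandomField(g, 4.0)
        rng = np.random.default_rng(1)
        cors = []
        for _ in range(50):
            z, w = grf.sample(rng), grf.sample(rng)
            zp = perturb_latent(z, w, 1.0)
            cors.append(np.corrcoef(z.ravel(), zp.ravel())[0, 1])
        assert abs(np.mean(cors)) < 0.05

    @pytest.mark.parametrize("step", [0.0, -0.1, 1.5])
    def test_invalid_step_rejected(self, step):
        z = np.zeros((4, 4))
        with pytest.raises(ValueError):
            perturb_latent(z, z, step)
        with pytest.raises(ValueError):
            perturb_white(z, step, rng=0)

    def test_white_kernel_preserves_iid_law(self):
        """A long exploration-only walk on the white field conserves mean,
        variance, and independence of components."""
        rng = np.random.default_rng(5)
        w = rng.standard_normal((24, 24))
        samples = []
        for _ in range(600):
            w = perturb_white(w, 0.3, rng)
            samples.append(w.copy())
        pool = np.stack(samples[100:])
        assert pool.mean() == pytest.approx(0.0, abs=0.02)
        assert pool.var() == pytest.approx(1.0, abs=0.03)
        lag1 = np.corrcoef(pool[:, :, :-1].ravel(), pool[:, :, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.02

    def test_block_conditional_resample_preserves_moments(self):
        """Dense sequential-Gibbs oracle: chain of block redraws keeps the
        latent field stationary (mean 0, var 1, correct lag-1 correlation)."""
        g = ImageGrid(10, 10, 1.0)
        r = 3.0
        z = simulate_latent(g, r, seed=2)
        rng = np.random.default_rng(3)
        samples = []
        for k in range(300):
            i = int(rng.integers(0, 6))
            j = int(rng.integers(0, 6))
            z = block_conditional_resample(z, g, r, (slice(i, i + 4), slice(j, j + 4)), rng)
            samples.append(z.copy())
        # the whole 10x10 field is one correlated patch at range 3, so chain
        # averages have few effective degrees of freedom; tolerances reflect that
        pool = np.stack(samples[50:])
        assert pool.mean() == pytest.approx(0.0, abs=0.35)
        assert pool.var() == pytest.approx(1.0, abs=0.25)
        lag1 = np.corrcoef(pool[:, :, :-1].ravel(), pool[:, :, 1:].ravel())[0, 1]
        assert lag1 == pytest.approx(np.exp(-1.0 / r**2), abs=0.15)


class TestTruncatedBimodalPrior:
    def test_threshold_is_exact_normal_quantile(self):
        p = TruncatedBimodalPrior(ImageGrid(8, 8, 1.0))
        assert p.threshold == pytest.approx(ndtri(0.09))
        assert round(p.threshold, 2) == -1.34

    def test_realization_is_two_valued_in_intervals(self):
        g = ImageGrid(32, 32, 1.0)
        p = TruncatedBimodalPrior(g)
        state = p.initial(np.random.default_rng(0))
        img = p.activity(state)
        vals = np.unique(img.values)
        assert vals.size <= 2
        for v in vals:
            assert (0.1 <= v <= 1.1) or (2.1 <= v <= 3.2)

    def test_all_positive_latent_gives_constant_low_image(self):
        g = ImageGrid(8, 8, 1.0)
        p = TruncatedBimodalPrior(g)
        high, img = realize_rho1(np.abs(np.random.default_rng(1).standard_normal(g.shape)), p)
        assert not high.any()
        assert np.unique(img.values).size == 1
        assert 0.1 <= img.values[0, 0] <= 1.1

    def test_expected_high_fraction_is_nine_percent(self):
        g = ImageGrid(64, 64, 1.0)
        p = TruncatedBimodalPrior(g, range_px=10.0)
        rng = np.random.default_rng(9)
        fracs = [p.high_mask(p.initial(rng)).mean() for _ in range(200)]
        # per-field fractions fluctuate strongly (long-range field on a small
        # grid); the mean over 200 fields has a standard error around 0.0035
        assert np.mean(fracs) == pytest.approx(0.09, abs=0.01)

    def test_level_random_walk_stays_inside_intervals(self):
        g = ImageGrid(8, 8, 1.0)
        p = TruncatedBimodalPrior(g, p_level=1.0)
        rng = np.random.default_rng(3)
        s = p.initial(rng)
        for _ in range(500):
            s = p.perturb(s, 0.5, rng)
            assert 0.1 <= s.low <= 1.1
            assert 2.1 <= s.high <= 3.2

    def test_invalid_intervals_rejected(self):
        g = ImageGrid(8, 8, 1.0)
        with pytest.raises(ValueError):
            TruncatedBimodalPrior(g, low_interval=(0.1, 2.5), high_interval=(2.1, 3.2))
        with pytest.raises(ValueError):
            TruncatedBimodalPrior(g, high_fraction=1.5)


class TestTissueMixture:
    def test_median_maps_to_mixture_median(self):
        g = ImageGrid(4, 4, 1.0)
        p = TrimodalTissuePrior(g)
        img = realize_rho2(np.zeros(g.shape), p)
        med = p.mixture.ppf(0.5)
        assert np.allclose(img.values, med)
        assert p.mixture.cdf(med) == pytest.approx(0.5, abs=1e-4)

    def test_lesion_weight_equals_high_activity_tail(self):
        # components t2/t3 have negligible mass above 1.5 kBq/ml, so the
        # fraction above 1.5 converges to the lesion weight w1
        g = ImageGrid(64, 64, 1.0)
        p = TrimodalTissuePrior(g, range_px=8.0)
        rng = np.random.default_rng(21)
        fracs = [(p.activity(p.initial(rng)).values > 1.5).mean() for _ in range(200)]
        assert np.mean(fracs) == pytest.approx(0.10, abs=0.01)

    def test_marginal_matches_mixture_cdf(self):
        g = ImageGrid(64, 64, 1.0)
        p = TrimodalTissuePrior(g)
        rng = np.random.default_rng(2)
        vals = np.concatenate(
            [p.activity(p.initial(rng)).values.ravel() for _ in range(100)]
        )
        # ~0.008 typical at this grid size: each range-8 field carries only
        # ~60 effectively independent pixels
        stat = kstest(vals, p.mixture.cdf).statistic
        assert stat < 0.02

    def test_transform_is_monotone(self):
        p = TrimodalTissuePrior(ImageGrid(4, 4, 1.0))
        z = np.linspace(-4, 4, 101).reshape(1, -1)
        out = p.mixture.ppf(norm.cdf(z)).ravel()
        assert np.all(np.diff(out) >= 0)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            TissueMixture(weights=(0.5, 0.5, 0.5))


class TestPriorPreservation:
    def test_exploration_only_chain_keeps_prior_statistics(self):
        """Iterating only the exploration step must sample the prior: the
        high-activity fraction stays at 9% and the latent variance at 1."""
        g = ImageGrid(48, 48, 1.0)
        p = TruncatedBimodalPrior(g, range_px=10.0)
        rng = np.random.default_rng(11)
        s = p.initial(rng)
        fracs, moments = [], []
        for k in range(3000):
            s = p.perturb(s, 0.7, rng)
            if k % 5 == 0:
                z = p.latent(s)
                fracs.append((z < p.threshold).mean())
                moments.append((z**2).mean())
        assert np.mean(fracs) == pytest.approx(0.09, abs=0.01)
        assert np.mean(moments) == pytest.approx(1.0, abs=0.05)
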