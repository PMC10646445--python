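"""Density estimation, data-consistent weights and the JSD estimator."""

import numpy as np
import pytest
from scipy import integrate, stats

from sipsolve import (
    NonlinearSystem,
    PriorSpec,
    TargetSpec,
    consistent_weight,
    estimate_jsd,
    nonlinear_uniform_prior,
    fit_density,
    make_target_nonlinear,
)


class TestFitDensity:
    def test_single_gaussian_recovers_moments(self, rng):
        s = rng.normal(0.0, 1.0, size=(5000, 1))
        dens = fit_density(s, n_components=1, seed=0)
        assert dens.means[0, 0] == pytest.approx(0.0, abs=0.05)
        assert np.sqrt(dens.covariances[0].ravel()[0]) == pytest.approx(
            1.0, abs=0.05
        )

    def test_two_clusters_get_balanced_weights(self, rng):
        s = np.vstack(
            [
                rng.normal(-5, 0.3, size=(1000, 1)),
                rng.normal(5, 0.3, size=(1000, 1)),
            ]
        )
        dens = fit_density(s, n_components=2, seed=1)
        assert np.allclose(sorted(dens.weights), [0.5, 0.5], atol=0.03)

    def test_density_integrates_to_one(self, rng):
        s = rng.normal(size=(2000, 1))
        dens = fit_density(s, n_components="auto", max_components=5, seed=2)
        total, _ = integrate.quad(
            lambda v: dens.pdf(np.array([[v]]))[0], -10, 10
        )
        assert total == pytest.approx(1.0, abs=1e-6)
        # weights form a distribution and the fit covers its own samples
        assert np.all(dens.weights >= 0)
        assert dens.weights.sum() == pytest.approx(1.0)
        assert np.all(np.isfinite(dens.logpdf(s)))

    def test_auto_order_beats_single_gaussian_on_bimodal_data(self, rng):
        s = np.vstack(
            [
                rng.normal(-3, 0.5, size=(2000, 1)),
                rng.normal(3, 0.5, size=(2000, 1)),
            ]
        )
        auto = fit_density(s, n_components="auto", max_components=8, seed=3)
        single = fit_density(s, n_components=1, seed=3)
        assert auto.n_components >= 2
        assert auto.logpdf(s).mean() > single.logpdf(s).mean()

    def test_too_few_samples_for_requested_order(self, rng):
        with pytest.raises(ValueError, match="at least"):
            fit_density(rng.normal(size=(30, 1)), n_components=5)

    def test_collapsed_samples_warn_but_fit(self):
        s = np.full((200, 1), 2.0)
        with pytest.warns(RuntimeWarning, match="collapsed"):
            dens = fit_density(s, n_components=1)
        assert np.isfinite(dens.logpdf(s)).all()


class TestConsistentWeight:
    def test_self_target_gives_unit_ratio(self, rng):
        prior = PriorSpec.uniform_box([0.0], [1.0])
        x = prior.sample(4000, seed=0)
        y = 2.0 * x  # push-forward U(0, 2)
        dens = fit_density(y, n_components=1, seed=0)
        # target equal to the fitted push-forward estimate itself
        mu = float(dens.means[0, 0])
        sd = float(np.sqrt(dens.covariances[0].ravel()[0]))
        target = TargetSpec(truncnorm_params=(mu, sd, (-50.0, 50.0)))
        w = consistent_weight(x, y, prior, dens, target)
        assert np.median(np.abs(w - 1.0)) < 0.05

    def test_zero_outside_target_support(self, rng):
        prior = PriorSpec.uniform_box([0.0], [1.0])
        x = prior.sample(500, seed=1)
        y = 2.0 * x
        dens = fit_density(y, n_components=1, seed=1)
        target = TargetSpec(truncnorm_params=(0.5, 0.05, (0.25, 0.75)))
        w = consistent_weight(x, y, prior, dens, target)
        assert np.all(w[(y[:, 0] > 0.8)] == 0.0)

    def test_invertible_model_reproduces_change_of_variables(self, rng):
        """Weighted resample of x under M(x)=2x matches the pullback of the
        target, which for an invertible affine map is the target rescaled."""
        prior = PriorSpec.uniform_box([0.0], [1.0])
        x = prior.sample(30000, seed=2)
        y = 2.0 * x
        dens = fit_density(y, n_components="auto", max_components=5, seed=2)
        target = TargetSpec(truncnorm_params=(1.0, 0.1, (0.5, 1.5)))
        w = consistent_weight(x, y, prior, dens, target)
        idx = rng.choice(len(x), size=5000, p=w / w.sum())
        resampled = x[idx, 0]
        a, b = (0.5 - 1.0) / 0.1, (1.5 - 1.0) / 0.1
        ref = stats.truncnorm(a, b, loc=1.0, scale=0.1).rvs(
            size=5000, random_state=4
        ) / 2.0
        assert stats.ks_2samp(resampled, ref).pvalue > 0.01

    def test_floor_engages_rarely_on_benchmark_pool(self):
        """At default floors the ratio cap touches < 1% of a benchmark pool."""
        prior = nonlinear_uniform_prior()
        model = NonlinearSystem()
        x = prior.sample(20000, seed=3)
        y = model.evaluate(x)
        dens = fit_density(y, n_components="auto", seed=3)
        p_hat = dens.pdf(y)
        floor = 1e-3 * np.median(p_hat)
        assert np.mean(p_hat < floor) < 0.01


class TestEstimateJSD:
    def test_split_halves_of_one_distribution_near_zero(self, rng):
        s = rng.normal(size=(10000, 1))
        est = estimate_jsd(s[:5000], s[5000:], seed=1)
        assert est.value < 0.02

    def test_disjoint_uniforms_near_one_bit(self, rng):
        p = rng.uniform(0, 1, size=(5000, 1))
        q = rng.uniform(2, 3, size=(5000, 1))
        assert estimate_jsd(p, q, seed=2).value > 0.95

    def test_gaussian_pair_matches_quadrature_oracle(self, rng):
        p = rng.normal(0, 1, size=(10000, 1))
        q = rng.normal(1, 1, size=(10000, 1))
        est = estimate_jsd(p, q, seed=3).value

        def integrand(v):
            fp = stats.norm.pdf(v, 0, 1)
            fq = stats.norm.pdf(v, 1, 1)
            m = 0.5 * (fp + fq)
            out = 0.0
            if fp > 0:
                out += 0.5 * fp * np.log2(fp / m)
            if fq > 0:
                out += 0.5 * fq * np.log2(fq / m)
            return out

        oracle, _ = integrate.quad(integrand, -12, 13)
        assert est == pytest.approx(oracle, abs=0.03)

    def test_symmetry_within_estimator_noise(self, rng):
        p = rng.normal(0, 1, size=(8000, 1))
        q = rng.normal(0.5, 1, size=(8000, 1))
        a = estimate_jsd(p, q, seed=5).value
        b = estimate_jsd(q, p, seed=5).value
        assert abs(a - b) < 0.03

    def test_minimum_class_size_enforced(self, rng):
        with pytest.raises(ValueError, match="at least"):
            estimate_jsd(rng.normal(size=(30, 1)), rng.normal(size=(30, 1)))

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="dimensionality"):
            estimate_jsd(rng.normal(size=(500, 1)), rng.normal(size=(500, 2)))
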