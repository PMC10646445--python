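"""Rejection solvers: acceptance law, reductions, MCMC stage, oracles."""

import numpy as np
import pytest
from scipy import stats

from sipsolve import (
    NoiseSpec,
    PriorSpec,
    TargetSpec,
    mh_sample,
    solve_algorithm1,
    solve_algorithm2,
    solve_mcmc_boosted,
)
from sipsolve.models import ForwardModel, NonlinearSystem, Tiltmeter
from sipsolve.rejection import MCMCConfig, RejectionConfig, RejectionError


class Times2(ForwardModel):
    dim_x = 1
    dim_y = 1
    differentiable = True

    def _evaluate(self, x, eps):
        return 2.0 * x

    def jac_x(self, x, eps=None):
        return np.full((len(np.atleast_2d(x)), 1, 1), 2.0)


@pytest.fixture()
def times2_setup():
    prior = PriorSpec.uniform_box([0.0], [1.0])
    params = (1.0, 0.1, (0.5, 1.5))
    target = TargetSpec(
        samples=TargetSpec(truncnorm_params=params).sample(4000, seed=11),
        truncnorm_params=params,
    )
    return prior, target, params


def closed_form_pullback(params, n, seed):
    mu, sd, (lo, hi) = params
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd).rvs(
        size=n, random_state=seed
    ) / 2.0


class TestAlgorithm1:
    def test_self_target_accepts_with_unit_ratios(self, rng):
        """When the target equals the prior push-forward the density ratio is
        about 1 everywhere and the acceptance rate is about 1/B*."""
        prior = PriorSpec.uniform_box([0.0], [1.0])
        model = Times2()
        pool = prior.sample(4000, seed=1)
        y = 2.0 * pool
        from sipsolve.density import fit_density

        dens = fit_density(y, n_components=1, seed=1)
        mu = float(dens.means[0, 0])
        sd = float(np.sqrt(dens.covariances[0].ravel()[0]))
        target = TargetSpec(
            samples=y, truncnorm_params=(mu, sd, (-60.0, 60.0))
        )
        sol = solve_algorithm1(model, prior, target, n_initial=4000, seed=2,
                               n_components=1)
        # ratios near 1 -> acceptance rate near 1/max-ratio, well above zero
        assert sol.diagnostics["acceptance_rate"] > 0.3

    def test_matches_closed_form_pullback(self, times2_setup):
        prior, target, params = times2_setup
        sol = solve_algorithm1(
            Times2(), prior, target, n_initial=30000, seed=3
        )
        ref = closed_form_pullback(params, 5000, seed=4)
        ks = stats.ks_2samp(sol.x[:5000, 0], ref)
        assert ks.pvalue > 0.01

    def test_zero_acceptance_raises_helpful_error(self):
        prior = PriorSpec.uniform_box([0.0], [1.0])
        # target far outside the push-forward support
        target = TargetSpec(truncnorm_params=(10.0, 0.01, (9.9, 10.1)))
        target = TargetSpec(
            samples=target.sample(500, seed=0),
            truncnorm_params=(10.0, 0.01, (9.9, 10.1)),
        )
        with pytest.raises(RejectionError):
            solve_algorithm1(Times2(), prior, target, n_initial=500, seed=1)


class TestAlgorithm2:
    def test_reduces_to_algorithm1_with_shared_seed(self, times2_setup):
        """N_I=1 with B equal to the max observed ratio executes the exact
        same acceptance law: identical accepted index sets."""
        prior, target, _ = times2_setup
        s1 = solve_algorithm1(Times2(), prior, target, n_initial=8000, seed=9)
        s2 = solve_algorithm2(
            Times2(), prior, target,
            RejectionConfig(B="max", n_iterations=1, n_initial=8000, seed=9),
        )
        np.testing.assert_array_equal(s1.accepted_indices, s2.accepted_indices)

    def test_matches_closed_form_pullback(self, times2_setup):
        prior, target, params = times2_setup
        sol = solve_algorithm2(
            Times2(), prior, target,
            RejectionConfig(B=1.0, n_iterations=10, n_initial=30000, seed=5),
        )
        ref = closed_form_pullback(params, 5000, seed=6)
        assert stats.ks_2samp(sol.x[:5000, 0], ref).pvalue > 0.01

    def test_budget_consumed_exactly(self, times2_setup):
        prior, target, _ = times2_setup
        model = Times2()
        solve_algorithm2(
            model, prior, target,
            RejectionConfig(n_initial=12345, seed=1),
        )
        assert model.n_simulations == 12345

    def test_grid_oracle_total_variation(self, times2_setup):
        """Accepted histogram matches direct evaluation of the
        data-consistent update on a 1000-point grid (TV < 0.05)."""
        prior, target, params = times2_setup
        sol = solve_algorithm2(
            Times2(), prior, target,
            RejectionConfig(B=1.0, n_iterations=8, n_initial=400000,
                            max_components=8, seed=7),
        )
        edges = np.linspace(0.0, 1.0, 1001)
        centers = 0.5 * (edges[:-1] + edges[1:])
        # q_X(x) = q_Y(2x) * p_X(x) / p_Y(2x); p_X and p_Y constant here
        qx = TargetSpec(truncnorm_params=params).pdf(2.0 * centers)
        qx = qx / qx.sum()
        hist, _ = np.histogram(sol.x[:, 0], bins=edges)
        hist = hist / hist.sum()
        tv = 0.5 * np.abs(hist - qx).sum()
        assert tv < 0.05

    def test_survivor_floor_reports_iteration(self, times2_setup):
        prior, target, _ = times2_setup
        with pytest.raises(RejectionError) as exc:
            solve_algorithm2(
                Times2(), prior, target,
                RejectionConfig(
                    B=1.0, n_iterations=10, n_initial=400,
                    min_survivors=390, seed=1,
                ),
            )
        assert exc.value.iteration is not None

    def test_jsd_non_increasing_across_iterations(self, times2_setup):
        """Iterative rejection drives the surviving push-forward toward the
        target: the estimated divergence decreases from the first to the
        last iteration in most seeded replicates."""
        prior, target, _ = times2_setup
        wins = 0
        for seed in range(10):
            sol = solve_algorithm2(
                Times2(), prior, target,
                RejectionConfig(
                    B=1.0, n_iterations=3, n_initial=4000,
                    track_jsd=True, seed=seed, min_survivors=20,
                ),
            )
            hist = sol.diagnostics["jsd_history"]
            if hist[-1] <= hist[0] + 0.01:
                wins += 1
        assert wins >= 8

    def test_equivalence_class_of_proposals(self, times2_setup):
        """Two priors with identical within-fiber ratio structure (any two,
        for an invertible map) give the same accepted distribution."""
        _, target, params = times2_setup
        sols = []
        for prior in (
            PriorSpec.uniform_box([0.0], [1.0]),
            PriorSpec.scaled_beta([2.0], [2.0], [0.0], [1.0]),
        ):
            sols.append(
                solve_algorithm2(
                    Times2(), prior, target,
                    RejectionConfig(B=1.0, n_iterations=10,
                                    n_initial=20000, seed=8),
                )
            )
        ks = stats.ks_2samp(sols[0].x[:, 0], sols[1].x[:, 0])
        assert ks.pvalue > 0.01


class TestMHSample:
    def test_standard_normal_moments(self):
        logp = lambda x: -0.5 * np.sum(x**2, axis=1)
        draws, rate = mh_sample(
            logp, n_chains=16, n_steps=2000, step_scale=1.0, seed=1,
            x0=np.random.default_rng(0).normal(size=(16, 1)),
        )
        assert 0.0 < rate < 1.0
        assert draws.mean() == pytest.approx(0.0, abs=0.05)
        assert draws.std() == pytest.approx(1.0, abs=0.05)

    def test_box_support_respected(self):
        def logp(x):
            inside = np.all((x > 0) & (x < 1), axis=1)
            return np.where(inside, 0.0, -np.inf)

        draws, _ = mh_sample(
            logp, n_chains=8, n_steps=500, step_scale=0.3, seed=2,
            x0=np.full((8, 2), 0.5),
        )
        assert np.all((draws > 0) & (draws < 1))

    def test_all_initial_states_outside_support_raise(self):
        logp = lambda x: np.full(len(x), -np.inf)
        with pytest.raises(ValueError):
            mh_sample(logp, 4, 10, 0.1, seed=0, x0=np.zeros((4, 1)))


class TestMCMCBoosted:
    def test_matches_closed_form_pullback(self, times2_setup):
        prior, target, params = times2_setup
        sol = solve_mcmc_boosted(
            Times2(), prior, target,
            RejectionConfig(B=1.0, n_iterations=10, n_initial=30000, seed=3),
        )
        ref = closed_form_pullback(params, 5000, seed=13)
        assert stats.ks_2samp(sol.x[:5000, 0], ref).pvalue > 0.01
        assert sol.n_simulations <= 30000

    def test_agrees_with_algorithm2_on_benchmark(
        self, uniform_prior, nonlinear_target
    ):
        """Cross-method agreement: the two solvers' push-forward means and
        spreads coincide on the nonlinear-system benchmark."""
        cfg = RejectionConfig(B=1.0, n_iterations=10, n_initial=20000, seed=4)
        s_rej = solve_algorithm2(
            NonlinearSystem(), uniform_prior, nonlinear_target, cfg
        )
        s_mc = solve_mcmc_boosted(
            NonlinearSystem(), uniform_prior, nonlinear_target, cfg
        )
        assert s_mc.y.mean() == pytest.approx(s_rej.y.mean(), abs=0.005)
        assert s_mc.y.std() == pytest.approx(s_rej.y.std(), abs=0.005)

    def test_stochastic_pool_carries_noise_draws(self):
        model = Tiltmeter(stochastic=True)
        prior = PriorSpec.uniform_box([0, 0], [2, 2])
        noise = NoiseSpec(sd=np.full(model.dim_eps, 0.0825))
        from sipsolve.distributions import make_target_tiltmeter

        target = make_target_tiltmeter(True, 3000, seed=5)
        sol = solve_mcmc_boosted(
            model, prior, target,
            RejectionConfig(B=1.0, n_iterations=3, n_initial=8000, seed=6,
                            min_survivors=20),
            noise=noise,
            mcmc=MCMCConfig(n_chains=16),
        )
        assert sol.eps is not None
        assert sol.eps.shape == (len(sol.x), model.dim_eps)
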