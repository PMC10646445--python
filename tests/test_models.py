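"""Forward-model contracts: closed forms, Jacobians, simulation accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from sipsolve import (
    NonlinearSystem,
    Rosenbrock,
    SurrogateModel,
    Tiltmeter,
    TiltmeterSpec,
    eval_avg_pool,
    eval_nonlinear_system,
    eval_tiltmeter,
    fit_surrogate,
    make_model,
    PriorSpec,
)
from sipsolve.models import DomainError, ForwardModel


class TestNonlinearSystem:
    @pytest.mark.parametrize(
        "x1,x2,expected",
        [
            (0.0, 0.0, 1.0),  # radicand (1-0)/(1+0)
            (1.0, 0.3, 0.0),  # numerator vanishes
            (1.0, 2.0, 0.0),
        ],
    )
    def test_closed_form_values(self, x1, x2, expected):
        assert eval_nonlinear_system(x1, x2) == pytest.approx(expected)

    def test_matches_numerical_root_find(self):
        """Closed form agrees with a 2-D numerical solve of the system."""
        x1, x2 = 0.79, 2.423

        def system(v):
            y1, y2 = v
            return [x1 * y1**2 + y2**2 - 1.0, y1**2 - x2 * y2**2 - 1.0]

        sol = optimize.fsolve(system, [1.0, 0.5], full_output=True)
        root, _, ier, _ = sol
        assert ier == 1
        assert eval_nonlinear_system(x1, x2) == pytest.approx(
            abs(root[1]), abs=1e-8
        )

    def test_solves_both_equations_over_prior(self, uniform_prior):
        """Substituting the closed-form output back into both equations
        leaves residuals at machine level across 10^4 prior draws."""
        x = uniform_prior.sample(10000, seed=3)
        model = NonlinearSystem()
        y2 = model.evaluate(x)[:, 0]
        y1sq = 1.0 + x[:, 1] * y2**2
        r1 = x[:, 0] * y1sq + y2**2 - 1.0
        r2 = y1sq - x[:, 1] * y2**2 - 1.0
        assert np.max(np.abs(r1)) < 1e-10
        assert np.max(np.abs(r2)) < 1e-10

    @pytest.mark.parametrize("x1,x2", [(2.0, 0.0), (0.5, -3.0)])
    def test_domain_violations_raise(self, x1, x2):
        with pytest.raises(DomainError):
            eval_nonlinear_system(x1, x2)

    @given(
        x1=st.floats(0.0, 1.0),
        x2=st.floats(-0.4230, 2.4230),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_output_is_valid_root_anywhere_in_domain(self, x1, x2):
        """Anywhere the preconditions hold, the returned value is the
        non-negative root and solves both equations."""
        y2 = eval_nonlinear_system(x1, x2)
        assert y2 >= 0.0
        y1sq = 1.0 + x2 * y2**2
        assert x1 * y1sq + y2**2 == pytest.approx(1.0, abs=1e-9)

    def test_jacobian_matches_finite_differences(self, uniform_prior):
        model = NonlinearSystem()
        x = uniform_prior.sample(50, seed=5)
        jac = model.jac_x(x)
        h = 1e-6
        for j in range(2):
            xp = x.copy()
            xp[:, j] += h
            fd = (model.evaluate(xp) - model.evaluate(x)) / h
            assert np.allclose(jac[:, :, j], fd, atol=1e-4)


class TestTiltmeter:
    def test_height_at_origin_slopes_zero(self):
        spec = TiltmeterSpec()
        np.testing.assert_allclose(
            eval_tiltmeter(spec, [0.0, 0.0]), [3.0, 3.0]
        )

    def test_plain_arithmetic(self):
        spec = TiltmeterSpec(positions=((0.6, 0.6),))
        assert eval_tiltmeter(spec, [1.0, 1.0])[0] == pytest.approx(4.2)
        assert eval_tiltmeter(spec, [1.0, 0.0], [0.1, 0.0])[0] == pytest.approx(3.7)

    def test_noise_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="pair per position"):
            eval_tiltmeter(TiltmeterSpec(), [1.0, 1.0], [0.1, 0.2, 0.3])

    def test_affine_in_parameters(self, rng):
        """M(a x + b x') - y0 is the same combination of M(x)-y0, M(x')-y0."""
        model = Tiltmeter()
        x = rng.uniform(0, 2, size=(20, 2))
        xp = rng.uniform(0, 2, size=(20, 2))
        a, b = 0.3, 1.4
        y0 = model.spec.y0
        lhs = model.evaluate(a * x + b * xp) - y0
        rhs = a * (model.evaluate(x) - y0) + b * (model.evaluate(xp) - y0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_stochastic_jacobians(self, rng):
        model = Tiltmeter(stochastic=True)
        x = rng.uniform(0, 2, size=(10, 2))
        eps = rng.normal(0, 0.1, size=(10, model.dim_eps))
        h = 1e-6
        jx = model.jac_x(x, eps)
        je = model.jac_eps(x, eps)
        for j in range(2):
            xp = x.copy()
            xp[:, j] += h
            fd = (model.evaluate(xp, eps) - model.evaluate(x, eps)) / h
            assert np.allclose(jx[:, :, j], fd, atol=1e-5)
        for j in range(model.dim_eps):
            ep = eps.copy()
            ep[:, j] += h
            fd = (model.evaluate(x, ep) - model.evaluate(x, eps)) / h
            assert np.allclose(je[:, :, j], fd, atol=1e-5)


class TestAvgPool:
    def test_constant_image(self):
        out = eval_avg_pool(np.full((10, 12), 3.7))
        assert out.shape == (4, 6)
        np.testing.assert_allclose(out, 3.7)

    def test_output_shape_28x28(self):
        assert eval_avg_pool(np.zeros((28, 28))).shape == (22, 22)

    def test_single_pixel_spreads_one_over_49(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        out = eval_avg_pool(img)
        np.testing.assert_allclose(out, 1.0 / 49)

    def test_commutes_with_transposition(self, rng):
        img = rng.random((15, 15))
        np.testing.assert_allclose(
            eval_avg_pool(img.T), eval_avg_pool(img).T
        )

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="smaller"):
            eval_avg_pool(np.zeros((5, 9)))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linearity(self, seed):
        """Pooling is linear: pool(a*A + B) = a*pool(A) + pool(B)."""
        r = np.random.default_rng(seed)
        a_img, b_img = r.random((2, 9, 9))
        np.testing.assert_allclose(
            eval_avg_pool(2.5 * a_img + b_img),
            2.5 * eval_avg_pool(a_img) + eval_avg_pool(b_img),
            atol=1e-12,
        )


class TestAccounting:
    def test_counter_increases_by_batch_and_never_decreases(self, rng):
        model = Tiltmeter()
        assert model.n_simulations == 0
        model.evaluate(rng.uniform(0, 2, size=(7, 2)))
        assert model.n_simulations == 7
        model.evaluate(rng.uniform(0, 2, size=(13, 2)))
        assert model.n_simulations == 20

    def test_deterministic_model_is_reproducible(self, uniform_prior):
        model = NonlinearSystem()
        x = uniform_prior.sample(100, seed=1)
        np.testing.assert_array_equal(model.evaluate(x), model.evaluate(x))

    def test_registry_constructs_models(self):
        assert isinstance(make_model("nonlinear_system"), NonlinearSystem)
        m = make_model("tiltmeter", positions=((0.5, 0.5),))
        assert m.dim_y == 1
        assert isinstance(make_model("rosenbrock", a=2.0), Rosenbrock)
        with pytest.raises(KeyError):
            make_model("nope")


class TestSurrogate:
    def test_linear_model_learned_to_tolerance(self):
        class Linear(ForwardModel):
            dim_x = 1
            dim_y = 1

            def _evaluate(self, x, eps):
                return 2.0 * x

        prior = PriorSpec.uniform_box([0.0], [1.0])
        surr = fit_surrogate(Linear(), prior, n_train=1000, n_epochs=100,
                             seed=0)
        assert surr.differentiable
        assert surr.diagnostics["heldout_relative_rmse"] < 0.05
        x = prior.sample(200, seed=9)
        np.testing.assert_allclose(
            surr.evaluate(x), 2.0 * x, atol=0.05
        )
        # gradient of the learned map is close to the true slope
        jac = surr.jac_x(prior.sample(50, seed=2))
        assert np.allclose(jac, 2.0, atol=0.3)

    def test_constant_model_gives_constant_predictor(self):
        class Const(ForwardModel):
            dim_x = 2
            dim_y = 1

            def _evaluate(self, x, eps):
                return np.full((len(x), 1), 5.0)

        prior = PriorSpec.uniform_box([0, 0], [1, 1])
        surr = fit_surrogate(Const(), prior, n_train=500, n_epochs=30, seed=1)
        pred = surr.evaluate(prior.sample(100, seed=3))
        assert np.allclose(pred, 5.0, atol=0.05)

    def test_training_draws_count_against_mechanistic_budget(self):
        class Linear(ForwardModel):
            dim_x = 1
            dim_y = 1

            def _evaluate(self, x, eps):
                return 2.0 * x

        model = Linear()
        prior = PriorSpec.uniform_box([0.0], [1.0])
        surr = fit_surrogate(model, prior, n_train=300, n_epochs=5, seed=0)
        assert model.n_simulations == 300
        surr.evaluate(prior.sample(50, seed=1))
        assert model.n_simulations == 300  # surrogate evals don't count
        assert surr.n_simulations == 50
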