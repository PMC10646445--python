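# Methods

## The problem

Given a forward model `y = M(x)` (or `y = M(x, ε)` with embedded noise ε), a
prior `P_X` over parameters and a target distribution `Q_Y` of observations,
the stochastic inverse problem (SIP, also called data-consistent inversion)
asks for a parameter distribution `Q_X` whose push-forward through `M`
reproduces `Q_Y`.  `M` is typically non-invertible, so infinitely many
distributions push forward to the target; the prior resolves the ambiguity
*within fibers* `M⁻¹(y)` without biasing the distribution of outputs — the
defining difference from a Bayesian posterior, whose push-forward generally
does not match the data distribution.

The density-level solution is the data-consistent update

    q_X(x) = q_Y(M(x)) · p_X(x) / p_Y(M(x)),

where `p_Y` is the push-forward density of the prior ("model-induced
prior").  For stochastic models the same update applies to the joint `(x, ε)`
with prior `p_X(x) p_E(ε)`; marginal parameter samples drop ε.  Everything in
this package is a way of sampling from (or optimizing toward) this solution.

## Solvers

### Iterative rejection (`solve_algorithm1`, `solve_algorithm2`)

The classic scheme draws a pool from the prior, pushes it through `M`, fits
`p̂_Y` (a Gaussian mixture) on the pool outputs, forms ratios
`r_i = q_Y(y_i)/p̂_Y(y_i)` and accepts sample `i` with probability
`r_i / max_j r_j`.  A poorly estimated `p̂_Y` can make the bound enormous and
the acceptance rate collapse, because the estimate sits in a denominator.

The iterative variant replaces the bound with an algorithm parameter `B`
(default 1) and runs `N_I` rounds (default 10): each round refits `p̂_t` on
the *surviving* outputs and retains sample `i` with probability
`min(1, r_i/B)` where `r_i = q_Y(y_i)/p̂_t(y_i)`.  As the survivors approach
the target the ratios approach 1 and rejection pressure vanishes, so the
target distribution is a fixed point.  With `N_I = 1` and `B` set to the
maximum observed ratio the iteration is exactly the classic algorithm; both
entry points share one code path and one RNG stream, so the reduction is
bit-exact and tested as such.  The refit-then-retain rule is the package's
formulation of the iterative scheme; its defining properties — exact
reduction to the classic algorithm and convergence of the survivors to the
target at `B = 1`, `N_I = 10` — are both under test.

### MCMC-boosted rejection (`solve_mcmc_boosted`)

Any proposal whose within-fiber density ratios equal the prior's yields the
same data-consistent solution; the density ∝ `q_Y(M(x)) p_X(x)` is in this
equivalence class and usually much closer to the answer than the prior.
Random-walk Metropolis (gaussian proposals, vectorized over chains, step
scale adapted to a 20–40% acceptance rate during a 25% burn-in, proposals
outside the prior support rejected without spending a simulation) samples
that density to build the pool; the iterative rejection kernel then corrects
the pool, refitting `p̂_t` on pool outputs.  For stochastic models the chain
state is the joint `(x, ε)`.

### Conditional GAN (`cgan` module)

A conditional generator `x = G(y, z)` is trained adversarially on pairs
`(x_i, y_i = M(x_i))` with `x_i` from the prior, against a discriminator
scoring `(x, y)` pairs.  Inference is amortized: condition on target rows,
resample the latent, never touch the simulator again.  For deterministic
models the conditional law of `x` given `y` is degenerate (supported on the
fiber); the generator represents it implicitly and no density of `G` is ever
evaluated.

### Regularized GAN (`rgan` module)

The SIP is recast as constrained optimization:

    minimize  D_f(Q_Xg ‖ P_X)
    s.t.      supp(X_g) ⊆ supp(X),   D_f(Q_Yg ‖ Q_Y) = 0,

with `x_g = G(z)`, `y_g = M(x_g)`.  The penalty method turns this into
minimizing `w_Y·L_DY + w_X·L_DX` where `L_DX`, `L_DY` are non-saturating GAN
losses against a prior discriminator `D_X` (the objective) and an
observation discriminator `D_Y` (the constraint).  Training starts with
`(w_X, w_Y) = (1, 0)` — pure prior matching, which needs no simulations —
and linearly ramps to `(0.1, 1.0)` over the first 30% of
simulation-consuming steps, then stays fixed; the linear interpolation
between those endpoints is this package's schedule choice.  The generator update
backpropagates through `D_Y`, then through the model's analytic Jacobian,
into `G`; non-differentiable simulators are first replaced by a trained
feed-forward surrogate (`fit_surrogate`), whose held-out relative RMSE is
reported.

For stochastic models the generated noise is `ε_g = σ·ζ`, `ζ ~ N(0, I)`,
with a single trainable scale σ (log-parameterized for positivity, one scale
shared across noise dimensions, matching the single-instrument-noise
setting).  A third discriminator `D_N` compares `ε_g` with draws from the
assumed noise prior and regularizes σ toward it with weight `w_N`
(default 0.1, a package choice), while the push-forward
constraint lets the observed data pull σ toward the true noise level.

**Support constraint.**  For box-supported priors the generator output
passes through `center + half·tanh(u)`, so 100% of generated parameters lie
in the prior box by construction; for unbounded priors the constraint is
dropped and only `D_X` regularizes.

**Stabilization.**  GAN training at small simulation budgets is noisy.  Three
measures keep it reliable, all free of simulation cost: (i) several
discriminator updates per generator update — `D_X`/`D_N` see fresh prior and
noise draws, `D_Y` replays recently simulated push-forward batches; (ii)
two-timescale learning rates (`lr_d = 2e-3 > lr_g = 1e-3`); (iii) the final
parameter sample is an ensemble over eight generator snapshots taken in the
last 40% of training, which averages out the oscillation of the adversarial
equilibrium without shrinking the sampled distribution (weight-space
averaging was tried and systematically narrows the push-forward; sample-space
ensembling does not).  Spectral normalization of discriminators is
implemented and available (`spectral_norm=True`) but off by default: at
these network sizes it weakens the observation discriminator enough to leave
a visible push-forward mismatch.

## Budget accounting

Every `ForwardModel` counts evaluations; solvers are compared at a fixed
simulation budget.  Rejection spends the whole budget on the prior pool;
MCMC spends it on chain proposals (in-support ones); the c-GAN spends
`budget − n_out` on training pairs and `n_out` on the final push-forward of
inferred parameters; the r-GAN spends `budget − n_out` on training batches
(one forward evaluation plus one Jacobian per generated sample; Jacobians
and pretraining are not counted as simulations) and `n_out` on the final
sample.  Surrogate evaluations count against the surrogate's own counter,
not the mechanistic model's — only the surrogate's training draws hit the
mechanistic budget.

## Density estimation and divergences

Push-forward densities are Gaussian mixtures (sklearn), with the mixture
order chosen by held-out log-density over 1..20 components (selection on at
most 20,000 rows, final fit on everything).  The data-consistent ratio
floors its denominator at `10⁻³ ×` the batch median of `p̂_Y` — the estimate
sits in a denominator and unfloored tails produce unbounded weights; the
floor engages on well under 1% of benchmark samples.

JSD between two sample sets is estimated with a small MLP classifier
(one hidden layer of 64, weight decay 1e-4, trained to tolerance) through the
optimal-discriminator identity
`JSD = 1 + ½·E_P[log₂ D] + ½·E_Q[log₂(1−D)]`, evaluated on a held-out split
and clipped to [0, 1] bits.  The identity is a variational *lower* bound
attained only by the optimal discriminator, so undertraining or
regularization biases the estimate toward zero, never upward; the defaults
were fixed by a calibration battery (split halves of one sample ≈ 0 bits;
disjoint uniforms ≈ 1 bit; N(0,1) vs N(1,1) within 0.03 bits of the
quadrature value ≈ 0.161).

## Benchmarks and the synthetic-data generator

* **Nonlinear system** (`nonlinear_*`): `x1·y1² + y2² = 1`, `y1² − x2·y2² = 1`,
  output `y2 = sqrt((1−x1)/(1+x1·x2))` — the non-negative root, consistent
  with the target supported on (0, 0.6).  Priors: `x1 ~ U(0.79, 0.99)`,
  `x2 ~ U(1 ± 4.5·√0.1)`, or Beta(2, 5) rescaled to the same intervals (the
  four-parameter location–scale reading of the beta notation).  Target:
  N(0.3, 0.025²) truncated to (0, 0.6), sampled by inverse CDF (exact, no
  rejection loop).
* **Tiltmeter** (`tiltmeter_*`): `y = y0 + x1(p1+ε1) + x2(p2+ε2)` with
  `y0 = 3.0`, measured at `P_A = (0.6, 0.6)` and `P_B = (0.8, 0.6)`; prior
  `x1, x2 ~ U(0, 2)`.  Observations are synthesized from the "true" box
  `(U(0.85, 1.6), U(1.45, 1.85))`; the stochastic variant adds location
  noise with true sd 0.075 per component while inference assumes a noise
  prior of sd 0.0825 — the mis-specification the trainable σ must overcome.
* **Rosenbrock** (`rosenbrock`): standard 2-D form `(1−x1)² + 100(x2−x1²)²`
  with configurable constants; the target (a truncated normal band over
  moderate outputs, prior box (−2, 2)²) is this package's own benchmark
  choice, exercising a multi-modal pullback.
* **Average pooling** (`avg_pool`): 7×7 window, stride 1, no padding —
  the exact forward model of the super-resolution setting.  Full image-GAN
  training on an external image dataset is outside the test surface; the
  model itself is exact and unit-tested.

What the generator emulates — and does not.  Targets are synthesized from
known ground truth, so tests can score recovery (means, true-box coverage,
learned σ) exactly.  Real data would add model misspecification (no
parameter distribution reproduces the target exactly), non-gaussian and
parameter-dependent noise, and higher-dimensional observation spaces with
feature extraction; passing these tests demonstrates correctness of the
solvers under the stated conditions, not robustness to those complications.

## Problem sizes

Benchmark runs in the tests and the acceptance script use a 50,000-simulation
budget per solver (30,000 for the stochastic-tiltmeter comparison), with
10,000-sample targets; these desk-scale sizes are the package's chosen test
conditions — the solvers themselves accept any budget, and a 2,000,000
default mirrors the full-scale setting (`experiments.FULL_BUDGET`).  GAN
defaults at this scale: generator/discriminators 2×64 (c-GAN 3×128), latent
dimension 5, batch 32 (c-GAN 128), Adam(β₁ = 0.5), 3000 pretraining steps at
batch 128.  Network sizes and schedules are package choices.

## Numerical choices, ties and degenerate inputs

* Acceptance draws use `u < p` with `u ~ U[0, 1)`, so `p = 1` always keeps
  a sample and `p = 0` never does.
* The closed-form nonlinear system raises an explicit domain error (naming
  the offending input) when `1 + x1·x2 ≤ 0` or the radicand is negative;
  its Jacobian guards the `y → 0` edge with a 1e-12 floor (outside both
  benchmark priors).
* Collapsed sample sets get a covariance regularization bump plus a warning
  rather than a GMM failure.
* σ collapse below `10⁻⁴ ×` its initialization aborts with the recorded
  trajectory; zero survivors or survivors below `min_survivors` abort with
  the iteration reached and a remedy (larger pool or more iterations).
* Mode-collapse detection: a warning when the pretrained generator's spread
  falls below 10% of the prior's.

## Known limitations

* Rejection-family solvers scale poorly with observation dimension (density
  estimation in the denominator); this is intrinsic and is the motivation
  for the optimization formulation.
* Sample-based solvers on stochastic models couple one noise draw to each
  parameter sample; resampling noise at prediction time biases their
  push-forward.  This is expected behaviour, surfaced in experiment reports,
  and is exactly what the trainable-noise r-GAN removes.
* GAN solvers give no density values, only samples, and their equilibria are
  stochastic: results carry seed-to-seed spread of a few hundredths of a bit
  of JSD at the default budgets.
* The JSD estimator is biased toward zero by design (variational bound);
  comparisons between solvers use the same estimator and seed so the bias
  largely cancels.
* Sequential Monte Carlo / particle-perturbation solvers are out of scope.
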