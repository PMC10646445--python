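"""Iterative rejection on the nonlinear-system benchmark.

Builds the two-parameter nonlinear model, the uniform prior and the
truncated-normal observation target, runs the iterative rejection solver
(B = 1, ten iterations) at a 50,000-simulation budget, and prints summary
statistics of the accepted parameter distribution and its push-forward.
"""

import warnings

from sipsolve import (
    NonlinearSystem,
    nonlinear_uniform_prior,
    estimate_jsd,
    make_target_nonlinear,
    solve_algorithm2,
)
from sipsolve.rejection import RejectionConfig

warnings.simplefilter("ignore")

model = NonlinearSystem()
prior = nonlinear_uniform_prior()
target = make_target_nonlinear(10000, seed=7)

cfg = RejectionConfig(B=1.0, n_iterations=10, n_initial=50000, seed=1)
sol = solve_algorithm2(model, prior, target, cfg)
jsd = estimate_jsd(target.samples, sol.y, seed=1)

print(f"accepted samples      : {sol.n_accepted} of {cfg.n_initial}")
print(f"survivors per iteration: {sol.iteration_counts}")
print(f"push-forward mean     : {sol.y.mean():.4f}   (target mean 0.3)")
print(f"push-forward sd       : {sol.y.std():.4f}   (target sd 0.025)")
print(f"JSD(Q_Y || Q_Yg)      : {jsd.value:.4f} bits (0 = exact match)")
# The accepted parameter samples are the data-consistent solution: their
# push-forward through the model reproduces the target observation
# distribution, while the prior resolves the model's non-invertibility.
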