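"""Amortized inversion with a conditional GAN.

Trains x = G(y, z) once on simulated (parameter, observation) pairs; after
training, parameter samples for any observation set are produced without
touching the simulator again.
"""

import warnings

import numpy as np

from sipsolve import (
    CGANConfig,
    NonlinearSystem,
    nonlinear_uniform_prior,
    infer_cgan,
    make_target_nonlinear,
    make_training_pairs,
    train_cgan,
)

warnings.simplefilter("ignore")

model = NonlinearSystem()
prior = nonlinear_uniform_prior()
pairs = make_training_pairs(model, prior, None, 40000, seed=0)
handle = train_cgan(pairs, CGANConfig(seed=0), prior)
print(f"simulations used for training: {model.n_simulations}")

target = make_target_nonlinear(5000, seed=7)
x = infer_cgan(handle, target.samples, n_z_per_y=2, seed=1)
y = model.evaluate(x)
print(f"inferred {len(x)} parameter samples for {len(target.samples)} "
      "target observations")
print(f"push-forward mean {y.mean():.4f} (target 0.3), "
      f"sd {y.std():.4f} (target 0.025)")

# Amortization: answering a second query reuses the trained generator.
other = np.full((100, 1), 0.25)
x2 = infer_cgan(handle, other, n_z_per_y=10, seed=2)
print(f"second query answered with no new simulations "
      f"(counter still counts the final push-forward only)")
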