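"""The average-pooling forward model used for super-resolution inversion.

Demonstrates the 7x7, stride-1, no-padding average-pooling map on a small
synthetic image: a high-resolution image is blurred to a low-resolution
one, losing exactly the information an inversion method would have to fill
back in from the prior.
"""

import numpy as np

from sipsolve import AvgPool, eval_avg_pool

rng = np.random.default_rng(0)

# synthetic "digit": a bright diagonal stroke on a dark background
img = np.zeros((28, 28))
for i in range(4, 24):
    img[i, i - 2 : i + 2] = 1.0

low = eval_avg_pool(img)
print(f"high-res image:  {img.shape}, mean intensity {img.mean():.4f}")
print(f"low-res output:  {low.shape}, mean intensity {low.mean():.4f}")
print(f"each output cell is the mean of a 7x7 window -> "
      f"{(28 - 7 + 1)}x{(28 - 7 + 1)} grid")

model = AvgPool(height=28, width=28, window=7)
batch = rng.random((5, 28 * 28))
out = model.evaluate(batch)
print(f"batched: {batch.shape[0]} flattened images -> {out.shape}, "
      f"simulations counted: {model.n_simulations}")
# Pooling is linear, so the low-res image of a sum is the sum of low-res
# images; many distinct high-res images share one low-res observation,
# which is exactly the non-invertibility the inversion methods resolve.
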