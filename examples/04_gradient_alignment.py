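"""Principal functional gradient and spin-test alignment.

Builds a two-module FC fixture with matching spherical parcel coordinates,
derives the principal gradient by diffusion embedding, and tests the spatial
alignment of two synthetic cortical maps against it: one constructed to
follow the gradient, one random. The aligned map should give |Spearman r|
near 1 with a significant spin-test p; the random map should not.
"""

import numpy as np

import ewcomm as e

fc, coords, modules = e.make_gradient_fixture(n_regions=40, n_modules=2, seed=5)
grad = e.diffusion_gradient(fc)

sign = np.sign(grad.values)
agree = max((sign > 0).mean(), (sign < 0).mean())
split = (np.sign(grad.values[modules == 0]).mean(), np.sign(grad.values[modules == 1]).mean())
print(f"principal gradient range: [{grad.values.min():.3f}, {grad.values.max():.3f}]")
print(f"mean gradient sign per module: {split[0]:+.2f} vs {split[1]:+.2f} "
      "(opposite signs = modules separated)")

rng = np.random.default_rng(0)
aligned_map = grad.values + 0.1 * rng.standard_normal(40)
random_map = rng.standard_normal(40)

for name, m in (("gradient-following map", aligned_map), ("random map", random_map)):
    res = e.spin_test(m, grad.values, coords, n_spins=1000, seed=1)
    print(f"{name:24s} spearman r = {res.spearman_r:+.3f}   p_spin = {res.p_spin:.4f}")

print()
print("p_spin comes from re-correlating after random rotations of the parcel")
print("sphere (nearest-neighbour reassignment), which preserves each map's")
print("values and spatial smoothness, so smooth-map alignments are not")
print("over-claimed.")
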