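"""Generate a mocap-like synthetic sequence and inspect its ground truth.

The generator draws 3D shapes as sparse non-negative combinations of a few
skeleton-like bases, rotates them per frame, and projects orthographically
to 2D landmarks with optional noise.
"""

import numpy as np

from mcmrr import SyntheticSpec, generate

spec = SyntheticSpec(p=12, K_true=3, F_train=40, F_test=5, noise_sigma=0.01, seed=42)
gt = generate(spec)

print(f"training frames: {len(gt.train_shapes)}  (each 3 x {spec.p})")
print(f"test frames:     {len(gt.observations)}  (each 2 x {spec.p})")
print(f"true coefficients (frames x bases):\n{np.round(gt.coeffs_true, 3)}")
active = (gt.coeffs_true > 0).sum(axis=1)
print(f"active bases per frame: {active}")
# Each observation is the 2D shadow of a rotated sparse basis combination;
# the reconstruction task is to recover the lost depth coordinate.
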