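"""Sliding-window inference modes on a phantom, with an untrained tiny model.

Shows the mechanics: window planning at overlap 0.5, Gaussian importance
blending, and that blended outputs remain per-voxel probability simplexes.
(An untrained model segments nothing useful - see train_on_phantoms.py for
the full loop.)
"""

import numpy as np

from tctnet import (ModelConfig, PhantomSpec, TCTNet, gaussian_importance_map,
                    generate_phantom, plan_windows, sliding_window_infer)

vol, _ = generate_phantom(
    PhantomSpec(shape=(48, 32, 32), lesion_radius_range=(5.0, 7.0), seed=1)
)
roi = (32, 32, 32)

plan = plan_windows(vol.spatial_shape, roi, overlap=0.5)
print(f"volume {vol.spatial_shape}, roi {roi}, overlap 0.5 "
      f"-> {len(plan.origins)} windows at origins {plan.origins}")

weights = gaussian_importance_map(roi)
print(f"importance weights: centre {weights[15, 15, 15]:.3f}, "
      f"corner {weights[0, 0, 0]:.4f} (centre voxels dominate the blend)")

model = TCTNet(ModelConfig.tiny(seed=0))
probs = sliding_window_infer(vol, model.predict, roi, overlap=0.5, use_gaussian=True)
print(f"blended probability map {probs.shape}; per-voxel sums in "
      f"[{probs.sum(axis=0).min():.6f}, {probs.sum(axis=0).max():.6f}]")
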