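"""Segment a small synthetic scene by phase synchronization.

A bright rectangle on a dark background is encoded into per-pixel
frequencies and couplings; the oscillator grid is integrated; by the end of
the run the object's oscillators have pulled together in phase (binding)
while drifting away from the background (separation), and a 1-D gap cut of
the final phase profile recovers the object mask.
"""

import numpy as np

from oscatt import RunConfig, SceneObject, SceneSpec, run_pipeline

scene = SceneSpec(
    canvas=(12, 16), background=(30, 30, 30),
    objects=(SceneObject("rectangle", (3, 4), (6, 7), (255, 255, 230)),),
)
res = run_pipeline(scene, RunConfig(t_end=60.0, t1=2.0, span=2.0, warmup_start=0.5, seed=1),
                   attend=False)

phases = res.layer1.phases[-1]
lab_true = res.labels_true.ravel()
print(f"contrast: object {res.contrast[res.labels_true == 1].mean():.3f}, "
      f"background {res.contrast[res.labels_true == 0].mean():.3f}")
print(f"final phase: object {phases[lab_true == 1].mean():.2f} rad, "
      f"background {phases[lab_true == 0].mean():.2f} rad "
      "(higher contrast -> higher frequency -> faster phase growth)")
print(f"segmentation found {res.n_groups} groups; "
      f"pixel agreement with ground truth: {(res.labels == res.labels_true).mean():.1%}")
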