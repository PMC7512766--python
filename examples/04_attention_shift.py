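"""Attention selection and shifting on a two-object scene.

After layer 1 segments the scene, groups are ranked by phase velocity
(salience) and the central unit locks onto each group's hybrid (group-mean)
system in turn by active control.  During an epoch the control error decays
like the Mittag-Leffler function and the unit's phase tracks the attended
group; at each onset the phase slope jumps to the new group's rate.
"""

import numpy as np

from oscatt import RunConfig, SceneObject, SceneSpec, run_pipeline

scene = SceneSpec(
    canvas=(12, 16), background=(30, 30, 30),
    objects=(
        SceneObject("rectangle", (2, 2), (5, 5), (255, 255, 230)),   # bright: most salient
        SceneObject("rectangle", (6, 9), (5, 5), (85, 112, 210)),    # dimmer blue
    ),
)
res = run_pipeline(scene, RunConfig(t_end=60.0, t1=10.0, span=5.0, warmup_start=2.0, seed=1))

print(f"groups found: {res.n_groups}; salience order (fastest first): {res.ranking}")
for rep in res.attention.lock_report:
    print(f"epoch [{rep['onset']:.2f}, {rep['offset']:.2f}] -> group {rep['group']}: "
          f"locked={rep['locked']}, mean |error| over final half = {rep['mean_abs_err']:.4f}")
print(f"transitions (groups attended and locked): {res.transitions}")
print("The unit visits every group once, most salient first; a small mean error")
print("means the central oscillator is phase-locked onto that group's hybrid system.")
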