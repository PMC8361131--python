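"""Simulated difference scaling (MLDS) with a pyramid-based observer.

An observer whose decision variable is the finest-level activation A_1
judges which of two stimulus pairs differs more, across all
non-overlapping quadruples of an 11-level smoothness axis; the probit
maximum-likelihood fit recovers a perceptual scale in d-prime units.
"""

import numpy as np

from metalsense import (
    ModelObserver,
    StimulusSpaceConfig,
    build_mlds_session,
    default_noise_sd,
    enumerate_mlds_quadruples,
    fit_mlds,
    render_mlds_set,
    simulate_responses,
    smoothness_statistic,
)

config = StimulusSpaceConfig(image_size=128, n_views=8, master_seed=0)
images = render_mlds_set(config, n_levels=11)["smoothness"]
print(f"stimuli: {len(images)} images (11 levels x 8 views)")

table = {(img.smoothness_index, img.view_index): smoothness_statistic(img)
         for img in images}
quads = enumerate_mlds_quadruples(11)
session = build_mlds_session(quads, "smoothness", n_views=8, seed=1)
observer = ModelObserver("A1", noise_sd=default_noise_sd(table), seed=2)
responded = simulate_responses(session, observer, table)
scale = fit_mlds(responded)

print(f"trials: {len(responded)} quadruples; "
      f"log-likelihood {scale.log_likelihood:.1f}")
print("level | scale value (d')")
for lvl, psi in enumerate(scale.psi):
    print(f"  {lvl:2d}  |  {psi:6.2f}")
print("\nThe scale rises monotonically across the blur axis (difference"
      "\nscaling recovers the spacing of levels, not the sign of the"
      "\nunderlying statistic).  Each d' unit is one standard deviation of"
      "\nthe observer's decision noise, so adjacent levels about 1 d' apart"
      "\nare just reliably discriminable.")
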