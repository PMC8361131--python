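"""Synthesize the two-axis stimulus space and look at its basic statistics.

Builds a small 3x3 grid (blur = metal roughness, local disarray = coating
bumpiness) with 4 views per cell, and prints the mean in-object luminance
and RMS contrast per condition.
"""

import numpy as np

from metalsense import StimulusSpaceConfig, render_grid

config = StimulusSpaceConfig(
    image_size=128,
    n_smoothness_levels=3,
    n_bumpiness_levels=3,
    n_views=4,
    blur_sigmas=(0.0, 1.0, 2.0),
    disarray_amplitudes=(0.0, 3.0, 6.0),
    master_seed=0,
)
images = render_grid(config)
print(f"rendered {len(images)} images "
      f"({config.n_smoothness_levels}x{config.n_bumpiness_levels} conditions "
      f"x {config.n_views} views)\n")

print("condition (s, b) | mean luminance | RMS contrast  (view-averaged)")
for s in range(3):
    for b in range(3):
        sel = [i for i in images
               if (i.smoothness_index, i.bumpiness_index) == (s, b)]
        mean = np.mean([i.in_mask().mean() for i in sel])
        rms = np.mean([i.in_mask().std() for i in sel])
        print(f"     ({s}, {b})      |     {mean:.3f}      |    {rms:.3f}")

print("\nMean luminance is pinned near 1 across the whole grid (views emulate"
      "\nrotations of one object under one illuminant); RMS contrast falls"
      "\nwith blur (axis s) and slightly with disarray (axis b, scatter loss).")
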