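"""Simulated conjoint measurement (MLCM) and nested model comparison.

Two observers judge "which is more metallic" over all 325 pairs of the
5x5 grid, four times each (1300 trials): one uses luminance skewness, one
uses RMS contrast.  Nested likelihood-ratio tests then ask whether one or
both stimulus dimensions drive each observer's judgments.
"""

import warnings

import numpy as np

from metalsense import (
    ModelObserver,
    StimulusSpaceConfig,
    build_mlcm_session,
    default_noise_sd,
    enumerate_mlcm_pairs,
    fit_mlcm,
    lr_test,
    render_grid,
    simulate_responses,
    statistic_tables,
)
from metalsense.fitting import SeparationWarning

config = StimulusSpaceConfig(image_size=128, master_seed=0)
stats = statistic_tables(render_grid(config))
pairs = enumerate_mlcm_pairs(5, 5)
print(f"{len(pairs)} condition pairs, {len(pairs) * 4} trials per session\n")

with warnings.catch_warnings():
    warnings.simplefilter("ignore", SeparationWarning)
    for name in ("Sk", "RMS"):
        table = {(int(r.smoothness_index), int(r.bumpiness_index),
                  int(r.view_index)): getattr(r, name)
                 for r in stats.itertuples()}
        session = build_mlcm_session(pairs, n_repeats=4, n_views=8, seed=3)
        responded = simulate_responses(
            session, ModelObserver(name, default_noise_sd(table), seed=4),
            table)
        ind = fit_mlcm(responded, "independent")
        add = fit_mlcm(responded, "additive")
        test = lr_test(ind, add)
        print(f"observer statistic: {name}")
        print(f"  smoothness contributions: {np.round(add.psi_s, 2)}")
        print(f"  bumpiness  contributions: {np.round(add.psi_b, 2)}")
        print(f"  independent vs additive: chi2({test.df}) = "
              f"{test.statistic:.1f}, p = {test.p_value:.2g}\n")

print("A skewness observer is driven almost purely by smoothness (the"
      "\nbumpiness terms hover near 0); an RMS observer also picks up the"
      "\ncontrast loss caused by the bumpy coating, so both dimensions"
      "\ncontribute and the additive model wins the likelihood-ratio test.")
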