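"""Shared fixtures.

The stimulus-space fixtures run at image_size=256 with the generator's
size-relative defaults — large enough for stable image statistics, small
enough that the whole grid renders in seconds.  Expensive tables are
session-scoped and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from metalsense.config import StimulusSpaceConfig, substream_seed
from metalsense.metallicity import activation_table_from_images
from metalsense.pipeline import statistic_tables
from metalsense.stimuli import make_base_image, render_grid


@pytest.fixture(scope="session")
def space_config() -> StimulusSpaceConfig:
    """5x5x8 stimulus space at 256 px with size-relative defaults
    (blur 0..4 px, disarray 0..12 px RMS, correlation length 2 px)."""
    return StimulusSpaceConfig(image_size=256, master_seed=7)


@pytest.fixture(scope="session")
def base_images(space_config):
    """One zero-blur, zero-disarray base image per view."""
    return [
        make_base_image(substream_seed(space_config.master_seed, "base_image", v),
                        space_config)
        for v in range(space_config.n_views)
    ]


@pytest.fixture(scope="session")
def grid_images(space_config):
    """The full 5x5x8 stimulus grid (200 images)."""
    return render_grid(space_config)


@pytest.fixture(scope="session")
def grid_stats(grid_images):
    """Pyramid activations and all contrast estimators, one row per
    (condition, view)."""
    return statistic_tables(grid_images)


@pytest.fixture(scope="session")
def activation_table(grid_stats):
    """A1..A4 per (condition, view), in the layout the metallicity model
    consumes."""
    return grid_stats[
        ["smoothness_index", "bumpiness_index", "view_index",
         "A1", "A2", "A3", "A4"]
    ].copy()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
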