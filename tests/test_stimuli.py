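"""Stimulus generator: determinism, identity cases, mask invariants,
round-trip storage, and the axis-separability property."""

import dataclasses

import numpy as np
import pytest

from metalsense.config import StimulusSpaceConfig, substream_seed
from metalsense.stimuli import (
    apply_bumpiness,
    apply_smoothness,
    make_base_image,
    read_stimulus_set,
    render_condition,
    render_grid,
    render_mlds_set,
    write_stimulus_set,
)


@pytest.fixture(scope="module")
def small_config():
    return StimulusSpaceConfig(image_size=128, master_seed=3)


class TestBaseImage:
    def test_same_seed_bit_identical(self, small_config):
        a = make_base_image(42, small_config)
        b = make_base_image(42, small_config)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_different_seeds_differ(self, small_config):
        a = make_base_image(42, small_config)
        b = make_base_image(43, small_config)
        assert not np.array_equal(a.pixels, b.pixels)

    def test_nonnegative_and_zero_outside_mask(self, small_config):
        img = make_base_image(0, small_config)
        assert np.all(img.pixels >= 0)
        assert np.all(np.isfinite(img.pixels))
        assert np.all(img.pixels[~img.object_mask] == 0)

    def test_neutral_skew_setting_gives_symmetric_sample(self):
        """With the identity nonlinearity the in-object luminance
        distribution keeps the (symmetric) Gaussian shape of the base
        field."""
        cfg = StimulusSpaceConfig(image_size=128, luminance_skew=0.0, master_seed=3)
        skews = []
        for seed in range(10):
            img = make_base_image(seed, cfg)
            vals = img.in_mask()
            mu, sd = vals.mean(), vals.std()
            skews.append(np.mean((vals - mu) ** 3) / sd**3)
        assert abs(np.mean(skews)) < 0.2

    def test_default_skew_setting_gives_positive_skew(self, small_config):
        img = make_base_image(0, small_config)
        vals = img.in_mask()
        skew = np.mean((vals - vals.mean()) ** 3) / vals.std() ** 3
        assert skew > 1.0

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpaceConfig(image_size=0)


class TestApplySmoothness:
    def test_sigma_zero_identity(self, small_config):
        img = make_base_image(0, small_config)
        out = apply_smoothness(img, 0)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_negative_sigma_rejected(self, small_config):
        with pytest.raises(ValueError):
            apply_smoothness(make_base_image(0, small_config), -1)

    def test_constant_in_mask_image_unchanged(self, small_config):
        """Normalized masked blur leaves a constant surface constant —
        no darkening at the silhouette."""
        img = make_base_image(0, small_config)
        img = dataclasses.replace(
            img, pixels=np.where(img.object_mask, 2.5, 0.0))
        out = apply_smoothness(img, 4.0)
        np.testing.assert_allclose(out.pixels[out.object_mask], 2.5, rtol=1e-10)

    def test_silhouette_stays_sharp(self, small_config):
        img = make_base_image(0, small_config)
        out = apply_smoothness(img, 6.0)
        assert np.all(out.pixels[~out.object_mask] == 0)


class TestApplyBumpiness:
    def test_amplitude_zero_identity(self, small_config):
        img = make_base_image(0, small_config)
        out = apply_bumpiness(img, 0, 2.0, warp_seed=5)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_fixed_seed_deterministic(self, small_config):
        img = make_base_image(0, small_config)
        a = apply_bumpiness(img, 3.0, 2.0, warp_seed=5)
        b = apply_bumpiness(img, 3.0, 2.0, warp_seed=5)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_invalid_parameters_rejected(self, small_config):
        img = make_base_image(0, small_config)
        with pytest.raises(ValueError):
            apply_bumpiness(img, -1, 2.0, 0)
        with pytest.raises(ValueError):
            apply_bumpiness(img, 1, 0.0, 0)

    def test_mask_reapplied(self, small_config):
        img = make_base_image(0, small_config)
        out = apply_bumpiness(img, 6.0, 2.0, warp_seed=5)
        assert np.all(out.pixels[~out.object_mask] == 0)

    def test_histogram_approximately_preserved(self, space_config, base_images):
        """The near-permutation warp plus small scatter loss leaves the
        in-object mean within 5% between the extreme bumpiness levels."""
        amp = space_config.disarray_amplitudes[-1]
        for img in base_images:
            seed = substream_seed(space_config.master_seed, "warp", img.view_index)
            warped = apply_bumpiness(img, amp, space_config.disarray_scale, seed,
                                     scatter_loss=space_config.scatter_loss)
            m0, m1 = img.in_mask().mean(), warped.in_mask().mean()
            assert abs(m1 - m0) / m0 < 0.05


class TestRenderCondition:
    def test_zero_zero_equals_base(self, small_config):
        img = render_condition(0, 0, 2, small_config)
        base = make_base_image(
            substream_seed(small_config.master_seed, "base_image", 2), small_config)
        np.testing.assert_array_equal(img.pixels, base.pixels)

    def test_indices_recorded(self, small_config):
        img = render_condition(1, 2, 3, small_config)
        assert (img.smoothness_index, img.bumpiness_index, img.view_index) == (1, 2, 3)

    def test_out_of_range_rejected(self, small_config):
        with pytest.raises(IndexError):
            render_condition(5, 0, 0, small_config)
        with pytest.raises(IndexError):
            render_condition(0, 0, 8, small_config)

    def test_grid_determinism(self, small_config):
        a = render_condition(1, 1, 0, small_config)
        b = render_condition(1, 1, 0, small_config)
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestStimulusSetCounts:
    def test_conjoint_grid_has_200_images(self):
        cfg = StimulusSpaceConfig(image_size=64, blur_sigmas=(0, 0.5, 1, 1.5, 2),
                                  disarray_amplitudes=(0, 0.5, 1, 1.5, 2),
                                  disarray_scale=1.0, master_seed=0)
        images = render_grid(cfg)
        assert len(images) == 200
        keys = {(i.smoothness_index, i.bumpiness_index, i.view_index)
                for i in images}
        assert len(keys) == 200

    def test_mlds_set_has_176_images(self):
        cfg = StimulusSpaceConfig(image_size=64, blur_sigmas=(0, 1, 2),
                                  disarray_amplitudes=(0, 1, 2),
                                  n_smoothness_levels=3, n_bumpiness_levels=3,
                                  disarray_scale=1.0, master_seed=0)
        sets = render_mlds_set(cfg, n_levels=11)
        assert len(sets["smoothness"]) + len(sets["bumpiness"]) == 176


class TestStimulusSetIO:
    def test_round_trip_lossless(self, tmp_path):
        cfg = StimulusSpaceConfig(image_size=32, n_smoothness_levels=2,
                                  n_bumpiness_levels=2, blur_sigmas=(0, 1),
                                  disarray_amplitudes=(0, 1), disarray_scale=1.0,
                                  master_seed=0)
        images = render_grid(cfg)
        write_stimulus_set(images, tmp_path)
        loaded = read_stimulus_set(tmp_path)
        assert len(loaded) == len(images)
        for orig, back in zip(images, loaded):
            np.testing.assert_array_equal(
                orig.pixels.astype(np.float32), back.pixels.astype(np.float32))
            np.testing.assert_array_equal(orig.object_mask, back.object_mask)
            assert orig.seed == back.seed

    def test_empty_directory_gives_empty_set(self, tmp_path):
        assert read_stimulus_set(tmp_path) == []

    def test_missing_file_named_in_error(self, tmp_path):
        cfg = StimulusSpaceConfig(image_size=32, n_smoothness_levels=1,
                                  n_bumpiness_levels=1, n_views=2,
                                  blur_sigmas=(0,), disarray_amplitudes=(0,),
                                  disarray_scale=1.0, master_seed=0)
        images = render_grid(cfg)[:2]
        write_stimulus_set(images, tmp_path)
        victim = next(tmp_path.glob("s0_b0_v1.npy"))
        victim.unlink()
        with pytest.raises(IOError, match="s0_b0_v1.npy"):
            read_stimulus_set(tmp_path)


class TestConfigValidation:
    def test_level_lists_must_match_counts(self):
        with pytest.raises(ValueError):
            StimulusSpaceConfig(blur_sigmas=(0, 1))

    def test_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            StimulusSpaceConfig(blur_sigmas=(0, 2, 1, 3, 4))

    def test_smoothest_level_must_be_unblurred(self):
        with pytest.raises(ValueError):
            StimulusSpaceConfig(blur_sigmas=(1, 2, 3, 4, 5))

    def test_need_two_views(self):
        with pytest.raises(ValueError):
            StimulusSpaceConfig(n_views=1)
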