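"""Synthetic luminance stimuli on a smoothness x bumpiness grid.

The generator emulates the statistical structure of rendered coated-metal
objects: a positively skewed, high-dynamic-range luminance pattern with a
naturalistic 1/f amplitude spectrum, shown as an object blob on a black
void.  The smoothness axis Gaussian-blurs the in-object content (rough
metal blurs the reflected environment beneath the coating); the bumpiness
axis warps it by a smooth random displacement field (local disarray).
Viewing angles are emulated as independent content draws with identical
statistics — downstream analyses need statistical, not geometric,
equivalence across views.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .config import StimulusSpaceConfig, substream_rng, substream_seed

__all__ = [
    "StimulusImage",
    "make_base_image",
    "apply_smoothness",
    "apply_bumpiness",
    "render_condition",
    "render_grid",
    "render_mlds_set",
    "write_stimulus_set",
    "read_stimulus_set",
]


@dataclass
class StimulusImage:
    """A single synthetic luminance image plus its grid coordinates.

    ``pixels`` are nonnegative luminances in arbitrary linear units; pixels
    outside ``object_mask`` are exactly 0 (black void).
    """

    pixels: np.ndarray
    smoothness_index: int
    bumpiness_index: int
    view_index: int
    object_mask: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        self.object_mask = np.asarray(self.object_mask, dtype=bool)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square 2-D array")
        if self.pixels.shape != self.object_mask.shape:
            raise ValueError("mask shape must match pixels")

    def in_mask(self) -> np.ndarray:
        """Flat array of in-object luminances."""
        return self.pixels[self.object_mask]


def _object_mask(config: StimulusSpaceConfig) -> np.ndarray:
    """Blob-shaped boolean mask: a circle with seeded low-order radial
    harmonics, centered in the frame.  Identical for every view (the same
    object silhouette, up to the rotations the views stand in for)."""
    n = config.image_size
    rng = substream_rng(config.master_seed, "object_mask")
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)
    radius = config.mask_radius_frac * n * np.ones_like(theta)
    for k in (2, 3, 5):
        amp = 0.04 * config.mask_radius_frac * n
        phase = rng.uniform(0, 2 * np.pi)
        radius = radius + amp * np.cos(k * theta + phase)
    return r <= radius


def _masked_blur(pixels: np.ndarray, mask: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur of in-mask content with normalized (mask-aware)
    convolution, so the silhouette stays sharp and a constant in-mask image
    is unchanged away from nothing (the normalization removes the usual
    darkening at the boundary)."""
    if sigma == 0:
        return pixels.copy()
    m = mask.astype(np.float64)
    num = ndimage.gaussian_filter(pixels * m, sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma, mode="constant")
    out = np.zeros_like(pixels)
    inside = mask & (den > 1e-12)
    out[inside] = num[inside] / den[inside]
    return out


def make_base_image(view_seed: int, config: StimulusSpaceConfig) -> StimulusImage:
    """Zero-blur, zero-disarray image for one view.

    Random-phase noise with amplitude spectrum proportional to
    ``1/f**base_spectral_exponent`` is standardized and passed through the
    monotone nonlinearity ``exp(skew * z)`` (identity when skew is 0),
    producing the positively skewed, sparse-highlight luminance statistics
    of specular surfaces, then multiplied by the object mask.
    """
    n = config.image_size
    if n <= 0:
        raise ValueError("image_size must be positive")
    rng = np.random.default_rng(int(view_seed))
    white = rng.standard_normal((n, n))
    f = np.fft.fftfreq(n) * n  # cycles per image
    r = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    amp = np.zeros_like(r)
    nz = r > 0
    amp[nz] = 1.0 / r[nz] ** config.base_spectral_exponent
    # Random-phase noise with an *exact* 1/f^e amplitude spectrum: the
    # Hermitian phases come from a white-noise transform, the amplitudes
    # are imposed deterministically, so all views share one spectrum and
    # differ only in phase (content arrangement).
    F = np.fft.fft2(white)
    mod = np.abs(F)
    mod[mod == 0] = 1.0
    field = np.fft.ifft2(amp * F / mod).real
    mask = _object_mask(config)
    # Standardize within the object: views emulate rotations of one object
    # in one environment, so their in-object luminance moments must agree
    # (only the spatial arrangement differs between views).
    z = (field - field[mask].mean()) / field[mask].std()
    s = config.luminance_skew
    if s == 0:
        lum = z - z.min()  # identity nonlinearity, shifted to nonnegative
    else:
        lum = np.exp(s * z)
    lum = lum * mask
    lum /= lum[mask].mean()  # fixed overall reflected energy
    return StimulusImage(
        pixels=lum,
        smoothness_index=0,
        bumpiness_index=0,
        view_index=0,
        object_mask=mask,
        seed=int(view_seed),
    )


def apply_smoothness(img: StimulusImage, sigma: float) -> StimulusImage:
    """Gaussian-blur the in-object content by ``sigma`` pixels.

    Blur affects the reflected environment, not the object shape, so the
    mask is re-applied and the silhouette stays sharp. sigma=0 is the
    identity.
    """
    if sigma < 0:
        raise ValueError("blur sigma must be nonnegative")
    out = _masked_blur(img.pixels, img.object_mask, float(sigma))
    return dataclasses.replace(img, pixels=out)


def apply_bumpiness(
    img: StimulusImage,
    amplitude: float,
    scale: float,
    warp_seed: int,
    scatter_loss: float = 0.85,
) -> StimulusImage:
    """Distort in-object content by a smooth random displacement field.

    The displacement field is the rotated gradient (stream function) of a
    Gaussian random field smoothed to correlation length ``scale``, i.e. it
    is divergence-free (area preserving), and is rescaled so the RMS
    displacement magnitude equals ``amplitude`` pixels.  The image is
    resampled at the displaced positions with nearest-neighbour sampling, a
    near-permutation of pixel values: the warp creates the fine shear edges
    a bumpy refracting coating introduces while leaving the luminance
    histogram essentially unchanged.  On top of the warp, luminance is
    attenuated by the factor ``1 - scatter_loss * amplitude / image_size``
    (light scattered out of the specular path by the bumps), which lowers
    variance-type contrast without touching any scale-invariant statistic.

    Content outside the object is filled with the nearest in-object value
    before resampling so boundary samples stay on the surface's luminance
    distribution; the mask is re-applied afterwards.  amplitude=0 is the
    identity.
    """
    if amplitude < 0:
        raise ValueError("disarray amplitude must be nonnegative")
    if scale <= 0:
        raise ValueError("disarray scale must be positive")
    if amplitude == 0:
        return dataclasses.replace(img, pixels=img.pixels.copy())
    n = img.pixels.shape[0]
    rng = np.random.default_rng(int(warp_seed))
    psi = ndimage.gaussian_filter(rng.standard_normal((n, n)), scale, mode="wrap")
    dx = np.gradient(psi, axis=0)
    dy = -np.gradient(psi, axis=1)
    rms = np.sqrt(np.mean(dx**2 + dy**2))
    dx *= amplitude / rms
    dy *= amplitude / rms
    # Nearest-in-mask fill so warped boundary samples are surface-like.
    filled = img.pixels
    if (~img.object_mask).any():
        idx = ndimage.distance_transform_edt(
            ~img.object_mask, return_distances=False, return_indices=True
        )
        filled = img.pixels[tuple(idx)]
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    warped = ndimage.map_coordinates(
        filled, [yy + dy, xx + dx], order=0, mode="nearest"
    )
    gain = 1.0 - scatter_loss * amplitude / n
    if gain <= 0:
        raise ValueError("scatter_loss * amplitude too large: nonpositive gain")
    # Refraction redirects light without absorbing it: restore the in-object
    # mean after resampling (the only energy loss is the scatter term).
    mask = img.object_mask
    pre_mean = img.pixels[mask].mean()
    post_mean = warped[mask].mean()
    if post_mean > 0:
        warped = warped * (pre_mean / post_mean)
    warped = warped * gain * mask
    return dataclasses.replace(img, pixels=warped)


def render_condition(
    s_idx: int, b_idx: int, view_idx: int, config: StimulusSpaceConfig
) -> StimulusImage:
    """Render one cell of the grid for one view: base image, then blur,
    then disarray (the physical ordering — roughness blurs the reflection
    beneath the coating that then distorts it)."""
    if not 0 <= s_idx < config.n_smoothness_levels:
        raise IndexError(f"smoothness index {s_idx} out of range")
    if not 0 <= b_idx < config.n_bumpiness_levels:
        raise IndexError(f"bumpiness index {b_idx} out of range")
    if not 0 <= view_idx < config.n_views:
        raise IndexError(f"view index {view_idx} out of range")
    view_seed = substream_seed(config.master_seed, "base_image", view_idx)
    img = make_base_image(view_seed, config)
    img = apply_smoothness(img, config.blur_sigmas[s_idx])
    # One coating geometry per view: the displacement field depends only on
    # the view, and the bumpiness level scales its strength — as in physical
    # stimuli where the bump texture is fixed and its depth increases.
    warp_seed = substream_seed(config.master_seed, "warp", view_idx)
    img = apply_bumpiness(
        img,
        config.disarray_amplitudes[b_idx],
        config.disarray_scale,
        warp_seed,
        scatter_loss=config.scatter_loss,
    )
    return dataclasses.replace(
        img,
        smoothness_index=s_idx,
        bumpiness_index=b_idx,
        view_index=view_idx,
        seed=view_seed,
    )


def render_grid(config: StimulusSpaceConfig) -> list[StimulusImage]:
    """The full conjoint-measurement stimulus set: every (smoothness,
    bumpiness, view) cell — 5 x 5 x 8 = 200 images at the defaults."""
    return [
        render_condition(s, b, v, config)
        for s in range(config.n_smoothness_levels)
        for b in range(config.n_bumpiness_levels)
        for v in range(config.n_views)
    ]


def render_mlds_set(
    config: StimulusSpaceConfig, n_levels: int = 11
) -> dict[str, list[StimulusImage]]:
    """The difference-scaling stimulus sets: ``n_levels`` levels along each
    dimension with the other dimension fixed at its first (identity) level,
    for every view — 11 x 2 x 8 = 176 images at the defaults.

    Levels are linearly interpolated between the extremes of the configured
    per-dimension value lists.
    """
    sigmas = np.linspace(config.blur_sigmas[0], config.blur_sigmas[-1], n_levels)
    amps = np.linspace(
        config.disarray_amplitudes[0], config.disarray_amplitudes[-1], n_levels
    )
    out: dict[str, list[StimulusImage]] = {"smoothness": [], "bumpiness": []}
    for v in range(config.n_views):
        view_seed = substream_seed(config.master_seed, "base_image", v)
        base = make_base_image(view_seed, config)
        for li, sig in enumerate(sigmas):
            img = apply_smoothness(base, sig)
            out["smoothness"].append(
                dataclasses.replace(
                    img, smoothness_index=li, bumpiness_index=0, view_index=v,
                    seed=view_seed,
                )
            )
        for li, amp in enumerate(amps):
            warp_seed = substream_seed(config.master_seed, "warp", v)
            img = apply_bumpiness(
                base, amp, config.disarray_scale, warp_seed,
                scatter_loss=config.scatter_loss,
            )
            out["bumpiness"].append(
                dataclasses.replace(
                    img, smoothness_index=0, bumpiness_index=li, view_index=v,
                    seed=view_seed,
                )
            )
    return out


def write_stimulus_set(images: list[StimulusImage], directory) -> Path:
    """Store images as 32-bit float NPY arrays (lossless round-trip) plus
    16-bit PNG previews, with a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        stem = (
            f"s{img.smoothness_index}_b{img.bumpiness_index}_v{img.view_index}"
        )
        np.save(directory / f"{stem}.npy", img.pixels.astype(np.float32))
        np.save(directory / f"{stem}.mask.npy", img.object_mask)
        peak = img.pixels.max()
        preview = (img.pixels / peak * 65535).astype(np.uint16) if peak > 0 else (
            np.zeros_like(img.pixels, dtype=np.uint16)
        )
        iio.imwrite(directory / f"{stem}.png", preview)
        rows.append(
            dict(
                filename=f"{stem}.npy",
                smoothness_index=img.smoothness_index,
                bumpiness_index=img.bumpiness_index,
                view_index=img.view_index,
                seed=img.seed,
            )
        )
    manifest = directory / "manifest.csv"
    pd.DataFrame(
        rows,
        columns=["filename", "smoothness_index", "bumpiness_index", "view_index", "seed"],
    ).to_csv(manifest, index=False)
    return manifest


def read_stimulus_set(directory) -> list[StimulusImage]:
    """Load a stimulus set written by :func:`write_stimulus_set`.

    An empty directory (no manifest) yields an empty list; a manifest row
    pointing at a missing file raises an error naming it.
    """
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        return []
    df = pd.read_csv(manifest)
    images = []
    for _, row in df.iterrows():
        path = directory / str(row["filename"])
        if not path.exists():
            raise IOError(f"manifest references missing file: {row['filename']}")
        pixels = np.load(path).astype(np.float64)
        mask_path = path.parent / (path.stem + ".mask.npy")
        mask = np.load(mask_path) if mask_path.exists() else pixels > 0
        images.append(
            StimulusImage(
                pixels=pixels,
                smoothness_index=int(row["smoothness_index"]),
                bumpiness_index=int(row["bumpiness_index"]),
                view_index=int(row["view_index"]),
                object_mask=mask,
                seed=int(row["seed"]),
            )
        )
    return images
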