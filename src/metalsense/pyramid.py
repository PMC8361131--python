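"""Steerable-pyramid decomposition and scalar level activations.

A frequency-domain steerable pyramid: each level splits the current
lowpass band into oriented band-pass subbands (raised-cosine radial masks
times ``|cos|**(K-1)`` angular masks) and a lowpass residual that is
downsampled by spectrum cropping.  The masks tile the frequency plane
(``sum of squared masks = 1``), so the transform is a tight frame with
numerically exact reconstruction — which the tests exploit as an oracle.

The scalar summary used throughout the package is the level activation
``A_l = log(sum over orientations of mean |coefficient|)``, with level 1
the finest scale.  ``A_1`` tracks fine detail (blur reduces it);
``A_1 - A_4`` compares fine against coarse structure and is invariant to
global luminance scaling — the two model-observer statistics for metal
smoothness and coating bumpiness respectively.

Spectrum cropping uses the unitary convention (amplitude factor 1/2 per
downsampling), so subband energies sum to the image energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Pyramid",
    "LevelActivations",
    "build_pyramid",
    "reconstruct",
    "level_activations",
    "smoothness_statistic",
    "bumpiness_statistic",
]


@dataclass
class Pyramid:
    """Subband coefficients; ``levels[l][k]`` is orientation band k of
    level l+1 (level 1 = finest, full resolution)."""

    levels: list[list[np.ndarray]]
    high_residual: np.ndarray
    low_residual: np.ndarray
    n_levels: int
    n_orientations: int


@dataclass
class LevelActivations:
    """Per-level log activations A_l; all-zero levels are flagged as
    degenerate and carry -inf rather than propagating silently."""

    A: np.ndarray
    degenerate: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = ~np.isfinite(self.A)

    def normalized_to(self, reference_index: int) -> np.ndarray:
        """Activations minus the value at ``reference_index`` (heatmap-style
        normalization to one physical-scale reference)."""
        return self.A - self.A[reference_index]


def _polar_grid(n: int) -> tuple[np.ndarray, np.ndarray]:
    w = np.fft.fftfreq(n) * 2 * np.pi  # rad/sample
    wy, wx = np.meshgrid(w, w, indexing="ij")
    return np.hypot(wy, wx), np.arctan2(wy, wx)


def _lo_mask(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Raised-cosine lowpass: 1 below cutoff/2, 0 above cutoff, one-octave
    log-frequency transition."""
    out = np.zeros_like(r)
    out[r <= cutoff / 2] = 1.0
    band = (r > cutoff / 2) & (r < cutoff)
    out[band] = np.cos(np.pi / 2 * np.log2(2 * r[band] / cutoff))
    return out


def _angular_masks(theta: np.ndarray, n_orientations: int) -> list[np.ndarray]:
    k = n_orientations
    masks = [np.abs(np.cos(theta - np.pi * i / k)) ** (k - 1) for i in range(k)]
    norm = np.sqrt(sum(m**2 for m in masks))
    return [m / norm for m in masks]


def _crop_spectrum(F: np.ndarray) -> np.ndarray:
    """Keep the central half of the (fftshifted) spectrum — downsample by 2
    with the unitary amplitude convention."""
    n = F.shape[0]
    m = n // 2
    Fs = np.fft.fftshift(F)
    lo = n // 2 - m // 2
    Fc = Fs[lo : lo + m, lo : lo + m]
    return np.fft.ifftshift(Fc) * (m / n)


def _pad_spectrum(F: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`_crop_spectrum`."""
    m = F.shape[0]
    out = np.zeros((n, n), dtype=complex)
    lo = n // 2 - m // 2
    out[lo : lo + m, lo : lo + m] = np.fft.fftshift(F)
    return np.fft.ifftshift(out) * (n / m)


def build_pyramid(img, n_levels: int = 4, n_orientations: int = 4) -> Pyramid:
    """Decompose a square image into ``n_levels`` oriented levels plus
    high- and low-pass residuals."""
    pixels = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("image must be square")
    n = pixels.shape[0]
    if n // 2 ** (n_levels - 1) < 8:
        raise ValueError(
            f"image size {n} too small for {n_levels} levels (finest residual < 8 px)"
        )
    F = np.fft.fft2(pixels)
    r, theta = _polar_grid(n)
    lo0 = _lo_mask(r, np.pi)
    hi0 = np.sqrt(np.clip(1 - lo0**2, 0, None))
    high_residual = np.fft.ifft2(F * hi0).real
    current = F * lo0
    levels: list[list[np.ndarray]] = []
    for _ in range(n_levels):
        m = current.shape[0]
        r_l, theta_l = _polar_grid(m)
        lo = _lo_mask(r_l, np.pi / 2)
        hi = np.sqrt(np.clip(1 - lo**2, 0, None))
        ang = _angular_masks(theta_l, n_orientations)
        bands = [np.fft.ifft2(current * hi * a).real for a in ang]
        levels.append(bands)
        current = _crop_spectrum(current * lo)
    low_residual = np.fft.ifft2(current).real
    return Pyramid(
        levels=levels,
        high_residual=high_residual,
        low_residual=low_residual,
        n_levels=n_levels,
        n_orientations=n_orientations,
    )


def reconstruct(pyr: Pyramid) -> np.ndarray:
    """Invert :func:`build_pyramid`; exact up to floating-point error."""
    current = np.fft.fft2(pyr.low_residual)
    for bands in reversed(pyr.levels):
        m = bands[0].shape[0]
        current = _pad_spectrum(current, m)
        r_l, theta_l = _polar_grid(m)
        lo = _lo_mask(r_l, np.pi / 2)
        hi = np.sqrt(np.clip(1 - lo**2, 0, None))
        ang = _angular_masks(theta_l, pyr.n_orientations)
        current = current * lo
        for band, a in zip(bands, ang):
            current = current + np.fft.fft2(band) * hi * a
    n = pyr.high_residual.shape[0]
    r, _ = _polar_grid(n)
    lo0 = _lo_mask(r, np.pi)
    hi0 = np.sqrt(np.clip(1 - lo0**2, 0, None))
    F = current * lo0 + np.fft.fft2(pyr.high_residual) * hi0
    return np.fft.ifft2(F).real


def level_activations(pyr: Pyramid) -> LevelActivations:
    """A_l = log of the orientation-summed mean absolute coefficient
    (natural log; the base is immaterial but fixed)."""
    A = np.empty(pyr.n_levels)
    for i, bands in enumerate(pyr.levels):
        pooled = float(sum(np.mean(np.abs(b)) for b in bands))
        A[i] = np.log(pooled) if pooled > 0 else -np.inf
    return LevelActivations(A=A)


def smoothness_statistic(img, n_levels: int = 4, n_orientations: int = 4) -> float:
    """A_1: the finest-level activation, the model-observer statistic for
    metal smoothness (blur attenuates it)."""
    return float(level_activations(build_pyramid(img, n_levels, n_orientations)).A[0])


def bumpiness_statistic(img, n_levels: int = 4, n_orientations: int = 4) -> float:
    """A_1 - A_4: log ratio of fine to coarse activation, the (luminance-
    scale-invariant, view-robust) statistic for coating bumpiness."""
    A = level_activations(build_pyramid(img, n_levels, n_orientations)).A
    return float(A[0] - A[n_levels - 1])
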