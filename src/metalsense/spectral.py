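"""Fourier-domain image statistics.

Radially averaged power spectra (in cycles per image, cpi), band means over
the high-frequency 23-53 cpi range, log-log spectral slopes, and
amplitude-phase hybrid images.  Images are windowed (2-D Hann by default)
before transforming to minimise edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.signal import windows

__all__ = [
    "RadialSpectrum",
    "window_image",
    "radial_power_spectrum",
    "band_mean_power",
    "loglog_slope",
    "amplitude_phase_swap",
]


@dataclass
class RadialSpectrum:
    """Orientation-averaged power spectrum on integer-cpi radial bins.

    ``power[i]`` is the mean spectral power of 2-D frequency samples near
    radius ``frequencies[i]``; ``bin_areas[i]`` is the (fractional) number
    of samples contributing, so ``sum(power * bin_areas)`` recovers the
    total non-DC energy of the windowed image.
    """

    frequencies: np.ndarray  # cpi, strictly increasing, 1..Nyquist
    power: np.ndarray
    bin_areas: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.frequencies)


def _get_pixels(img) -> np.ndarray:
    return np.asarray(getattr(img, "pixels", img), dtype=np.float64)


def window_image(img, window_kind: str = "hann") -> np.ndarray:
    """Multiply by a separable 2-D taper; ``rect`` is the identity."""
    pixels = _get_pixels(img)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError("image must be square")
    n = pixels.shape[0]
    if window_kind in ("rect", "rectangular", "none"):
        return pixels.copy()
    if window_kind == "hann":
        w = windows.hann(n, sym=False)
    elif window_kind == "hamming":
        w = windows.hamming(n, sym=False)
    else:
        raise ValueError(f"unknown window kind {window_kind!r}")
    return pixels * np.outer(w, w)


def radial_power_spectrum(img, window_kind: str = "hann") -> RadialSpectrum:
    """Radially averaged power spectrum with integer-cpi bins.

    The 2-D power spectrum ``|FFT|**2 / N_pixels`` (so that its sum equals
    the windowed image's energy) is distributed onto radial bins at integer
    cpi by inverse-distance (linear) interpolation between the two
    neighbouring bins; samples beyond the Nyquist ring (the spectrum
    corners) are pooled into the Nyquist bin so total power is conserved.
    DC is excluded.
    """
    w = window_image(img, window_kind)
    n = w.shape[0]
    F = np.fft.fft2(w)
    P = (F.real**2 + F.imag**2) / w.size
    f = np.fft.fftfreq(n) * n
    r = np.hypot(*np.meshgrid(f, f, indexing="ij"))
    nyq = n // 2
    r_flat = r.ravel()
    p_flat = P.ravel()
    nz = r_flat > 0
    r_flat, p_flat = r_flat[nz], p_flat[nz]
    lo = np.floor(r_flat).astype(int)
    frac = r_flat - lo
    hi = lo + 1
    # Clamp to [1, nyq]: corner samples (r > nyq) pool into the last bin.
    lo_c = np.clip(lo, 1, nyq)
    hi_c = np.clip(hi, 1, nyq)
    w_lo = 1.0 - frac
    w_hi = frac
    n_bins = nyq
    areas = np.zeros(n_bins)
    psum = np.zeros(n_bins)
    np.add.at(areas, lo_c - 1, w_lo)
    np.add.at(areas, hi_c - 1, w_hi)
    np.add.at(psum, lo_c - 1, w_lo * p_flat)
    np.add.at(psum, hi_c - 1, w_hi * p_flat)
    power = np.zeros(n_bins)
    good = areas > 0
    power[good] = psum[good] / areas[good]
    return RadialSpectrum(
        frequencies=np.arange(1, nyq + 1, dtype=float),
        power=power,
        bin_areas=areas,
    )


def band_mean_power(
    spectrum: RadialSpectrum, lo_cpi: float = 23, hi_cpi: float = 53
) -> float:
    """Mean radial power over the inclusive band [lo_cpi, hi_cpi]."""
    sel = (spectrum.frequencies >= lo_cpi) & (spectrum.frequencies <= hi_cpi)
    if not sel.any():
        raise ValueError(f"band [{lo_cpi}, {hi_cpi}] cpi is empty for this spectrum")
    return float(spectrum.power[sel].mean())


def loglog_slope(
    spectrum: RadialSpectrum, fit_range: tuple[float, float] | None = None
) -> float:
    """Least-squares slope of log power vs log frequency.

    A pure power law ``f**-2`` (i.e. 1/f amplitude) gives -2.0 exactly.
    """
    f, p = spectrum.frequencies, spectrum.power
    if fit_range is not None:
        sel = (f >= fit_range[0]) & (f <= fit_range[1])
        f, p = f[sel], p[sel]
    pos = p > 0
    f, p = f[pos], p[pos]
    if len(f) < 3:
        raise ValueError("need at least 3 bins with positive power to fit a slope")
    res = stats.linregress(np.log(f), np.log(p))
    return float(res.slope)


def amplitude_phase_swap(img_a, img_b) -> tuple[np.ndarray, np.ndarray]:
    """Hybrid images: (amplitude of a + phase of b, amplitude of b + phase
    of a), inverse-transformed to real images."""
    a = _get_pixels(img_a)
    b = _get_pixels(img_b)
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    Fa, Fb = np.fft.fft2(a), np.fft.fft2(b)
    hybrid_ab = np.fft.ifft2(np.abs(Fa) * np.exp(1j * np.angle(Fb))).real
    hybrid_ba = np.fft.ifft2(np.abs(Fb) * np.exp(1j * np.angle(Fa))).real
    return hybrid_ab, hybrid_ba
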