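"""Global and local contrast estimators of the in-object luminance sample.

Nine candidate metallicity statistics: luminance-histogram skewness,
dynamic range (plain and robust), Michelson contrast, RMS contrast, local
image contrast against the global mean or a heavily blurred copy, and the
Meese-Summers gain-controlled contrast in both variants.  All are computed
over the object mask only — on a black void the extrema-based measures are
degenerate otherwise.

Moments are population (1/N) moments.  The summation statistics (LIC, MS
families) default to their mean (1/N) form so values are image-size
invariant; ``mean_form=False`` restores raw sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import StimulusImage, _masked_blur

__all__ = [
    "LuminanceSample",
    "extract_sample",
    "skewness",
    "dynamic_range",
    "robust_dynamic_range",
    "michelson",
    "rms",
    "lic",
    "lic_blur",
    "meese_summers",
    "meese_summers_blur",
    "CONTRAST_STATISTICS",
]


class DegenerateStatisticError(ValueError):
    """The statistic is undefined for this sample (e.g. zero variance)."""


@dataclass
class LuminanceSample:
    """In-object luminance values, optionally with a matched blurred copy.

    ``B`` holds, per pixel, the value at the same location in a heavily
    blurred version of the image (local-mean reference for the *blur*
    statistic variants).
    """

    L: np.ndarray
    B: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.float64).ravel()
        if self.L.size < 1:
            raise ValueError("empty luminance sample")
        if self.B is not None:
            self.B = np.asarray(self.B, dtype=np.float64).ravel()
            if self.B.shape != self.L.shape:
                raise ValueError("B must match L in length")

    @property
    def N(self) -> int:
        return self.L.size

    @property
    def mu(self) -> float:
        return float(self.L.mean())

    @property
    def sigma(self) -> float:
        return float(self.L.std())


def extract_sample(
    img: StimulusImage,
    with_blur: bool = False,
    blur_sigma: float | None = None,
    floor: float | None = None,
) -> LuminanceSample:
    """In-mask luminance sample of a stimulus.

    ``with_blur`` also extracts the matched heavily blurred reference;
    ``blur_sigma`` defaults to image_size/4 ("highly blurred": wide enough
    that the reference is insensitive to pixel-scale disarray).  ``floor``,
    if given, clips luminances from below (an option for ratio statistics
    on images whose mask admits zeros).
    """
    if isinstance(img, LuminanceSample):
        return img
    L = img.in_mask()
    if floor is not None:
        L = np.maximum(L, floor)
    B = None
    if with_blur:
        sigma = blur_sigma if blur_sigma is not None else img.pixels.shape[0] / 4
        blurred = _masked_blur(img.pixels, img.object_mask, sigma)
        B = blurred[img.object_mask]
        if floor is not None:
            B = np.maximum(B, floor)
    return LuminanceSample(L=L, B=B)


def _sample(img) -> LuminanceSample:
    return extract_sample(img) if not isinstance(img, LuminanceSample) else img


def skewness(img) -> float:
    """Sk: third standardized moment of the luminance histogram."""
    s = _sample(img)
    if s.sigma == 0:
        raise DegenerateStatisticError("skewness undefined for constant sample")
    return float(np.mean((s.L - s.mu) ** 3) / s.sigma**3)


def dynamic_range(img) -> float:
    """DR = L_max / L_min."""
    s = _sample(img)
    lmin = s.L.min()
    if lmin <= 0:
        raise DegenerateStatisticError(
            "dynamic range undefined: sample contains nonpositive luminance"
        )
    return float(s.L.max() / lmin)


def robust_dynamic_range(img, n: int = 10) -> float:
    """rDR: mean of the n brightest over mean of the n dimmest pixels."""
    s = _sample(img)
    if n < 1 or n > s.N:
        raise ValueError(f"n={n} out of range for sample of {s.N}")
    srt = np.sort(s.L)
    denom = srt[:n].mean()
    if denom <= 0:
        raise DegenerateStatisticError("robust dynamic range: nonpositive dim mean")
    return float(srt[-n:].mean() / denom)


def michelson(img) -> float:
    """MC = (L_max - L_min) / (L_max + L_min); in [0, 1] for nonnegative L."""
    s = _sample(img)
    lmax, lmin = s.L.max(), s.L.min()
    if lmax + lmin == 0:
        raise DegenerateStatisticError("Michelson contrast undefined for all-zero sample")
    return float((lmax - lmin) / (lmax + lmin))


def rms(img) -> float:
    """RMS contrast: population standard deviation of the luminance sample."""
    s = _sample(img)
    return s.sigma


def lic(img, mean_form: bool = True) -> float:
    """Local image contrast: (1/N) sum |L_i - mu| (raw sum with
    mean_form=False)."""
    s = _sample(img)
    total = float(np.sum(np.abs(s.L - s.mu)))
    return total / s.N if mean_form else total


def lic_blur(img, mean_form: bool = True) -> float:
    """Local image contrast against a heavily blurred copy:
    (1/N) sum |L_i - B_i|."""
    s = img if isinstance(img, LuminanceSample) else extract_sample(img, with_blur=True)
    if s.B is None:
        raise ValueError("sample has no blurred reference B")
    total = float(np.sum(np.abs(s.L - s.B)))
    return total / s.N if mean_form else total


def _meese_summers_terms(d: np.ndarray) -> np.ndarray:
    # Gain-controlled contrast: terms grow as d**0.4 for large deviations.
    return d**2.4 / (1.0 + d**2)


def meese_summers(img, mean_form: bool = True) -> float:
    """MS: sum of |L_i - mu|**2.4 / (1 + |L_i - mu|**2)."""
    s = _sample(img)
    total = float(np.sum(_meese_summers_terms(np.abs(s.L - s.mu))))
    return total / s.N if mean_form else total


def meese_summers_blur(img, mean_form: bool = True) -> float:
    """MSblur: the Meese-Summers estimator with the blurred-copy reference."""
    s = img if isinstance(img, LuminanceSample) else extract_sample(img, with_blur=True)
    if s.B is None:
        raise ValueError("sample has no blurred reference B")
    total = float(np.sum(_meese_summers_terms(np.abs(s.L - s.B))))
    return total / s.N if mean_form else total


#: Named estimators, as referenced by model-observer rosters.
CONTRAST_STATISTICS = {
    "Sk": skewness,
    "DR": dynamic_range,
    "rDR": robust_dynamic_range,
    "MC": michelson,
    "RMS": rms,
    "LIC": lic,
    "LICblur": lic_blur,
    "MS": meese_summers,
    "MSblur": meese_summers_blur,
}
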