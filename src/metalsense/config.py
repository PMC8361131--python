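"""Configuration objects and seeding utilities.

All randomness in the package flows from a single ``master_seed`` through
named substreams (:func:`substream_seed`), so that stimulus generation,
view assignment, decision noise and bootstrap resampling are independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "StimulusSpaceConfig",
    "RunConfig",
    "substream_seed",
    "substream_rng",
]

# Named substreams; the integers keep SeedSequence keys stable across runs.
_STREAMS = {
    "base_image": 11,
    "object_mask": 23,
    "warp": 37,
    "session": 53,
    "noise": 67,
    "bootstrap": 79,
}


def substream_seed(master_seed: int, stream: str, *keys: int) -> int:
    """Derive a reproducible 31-bit integer seed for a named substream.

    Parameters
    ----------
    master_seed
        The run-level seed.
    stream
        One of ``base_image, object_mask, warp, session, noise, bootstrap``.
    *keys
        Extra integer keys (view index, condition index, ...).
    """
    if stream not in _STREAMS:
        raise ValueError(f"unknown substream {stream!r}")
    ss = np.random.SeedSequence([int(master_seed), _STREAMS[stream], *map(int, keys)])
    return int(ss.generate_state(1)[0] % (2**31))


def substream_rng(master_seed: int, stream: str, *keys: int) -> np.random.Generator:
    """A :class:`numpy.random.Generator` for a named substream."""
    return np.random.default_rng(substream_seed(master_seed, stream, *keys))


@dataclass(frozen=True)
class StimulusSpaceConfig:
    """Parameters of the two-axis (smoothness x bumpiness) stimulus space.

    The smoothness axis acts as a Gaussian blur of in-object content (rough
    metal blurs the reflected environment); the bumpiness axis acts as a
    smooth random pixel-displacement warp ("local disarray", the image-level
    surrogate for a bumpy dielectric coating).

    Attributes
    ----------
    image_size
        Pixels per side of the square luminance images.
    n_smoothness_levels, n_bumpiness_levels
        Grid size of the conjoint stimulus space.
    n_views
        Statistically equivalent but pixel-wise independent "viewing angles"
        per condition.
    blur_sigmas
        Monotone nondecreasing Gaussian blur SDs in pixels, one per
        smoothness level; the smoothest level has sigma 0 (index 0 =
        smoothest metal, largest blur = roughest).
    disarray_amplitudes
        Monotone nondecreasing RMS displacement amplitudes in pixels, one
        per bumpiness level; the even-coating level has amplitude 0.
    disarray_scale
        Correlation length of the displacement field in pixels.
    base_spectral_exponent
        Amplitude-spectrum falloff exponent of the base noise (1.0 = 1/f,
        the naturalistic default).
    luminance_skew
        Strength of the point nonlinearity ``exp(skew * z)`` applied to the
        standardized Gaussian field; positive values give the sparse bright
        highlights typical of specular surfaces. 0 selects the identity
        (symmetric) nonlinearity.
    scatter_loss
        Dimensionless luminance attenuation of the disarray transform: a
        coating of RMS bump displacement ``a`` scatters a fraction
        ``scatter_loss * a / image_size`` of the reflected light out of the
        image, multiplying in-object luminance by ``1 - scatter_loss *
        a/image_size``.  This reduces variance-type contrast (RMS, local
        image contrast) with bumpiness while leaving every scale-invariant
        statistic (skewness, dynamic range, Michelson) untouched.
    mask_radius_frac
        Mean radius of the blob-shaped object mask as a fraction of
        image_size.
    master_seed
        Root of all randomness in the grid.
    """

    image_size: int = 512
    n_smoothness_levels: int = 5
    n_bumpiness_levels: int = 5
    n_views: int = 8
    blur_sigmas: tuple[float, ...] | None = None
    disarray_amplitudes: tuple[float, ...] | None = None
    disarray_scale: float | None = None
    base_spectral_exponent: float = 1.0
    luminance_skew: float = 1.0
    scatter_loss: float = 0.85
    mask_radius_frac: float = 0.38
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        if self.n_views < 2:
            raise ValueError("need at least two views")
        if self.blur_sigmas is None:
            # 0 .. image_size/64 pixels, linearly spaced: the roughest level
            # strongly attenuates the 23-53 cpi band while fine in-object
            # content still dominates the finest pyramid level (larger blurs
            # saturate A_1 at the sharp-silhouette floor).
            sig = np.linspace(0.0, self.image_size / 64.0, self.n_smoothness_levels)
            object.__setattr__(self, "blur_sigmas", tuple(float(s) for s in sig))
        if self.disarray_amplitudes is None:
            # 0 .. 3*image_size/64 pixels RMS displacement.
            amp = np.linspace(0.0, 3.0 * self.image_size / 64.0, self.n_bumpiness_levels)
            object.__setattr__(self, "disarray_amplitudes", tuple(float(a) for a in amp))
        if self.disarray_scale is None:
            object.__setattr__(self, "disarray_scale", self.image_size / 128.0)
        if len(self.blur_sigmas) != self.n_smoothness_levels:
            raise ValueError("blur_sigmas length must equal n_smoothness_levels")
        if len(self.disarray_amplitudes) != self.n_bumpiness_levels:
            raise ValueError("disarray_amplitudes length must equal n_bumpiness_levels")
        if np.any(np.diff(self.blur_sigmas) < 0) or np.any(np.diff(self.disarray_amplitudes) < 0):
            raise ValueError("level lists must be monotone nondecreasing")
        if self.blur_sigmas[0] != 0:
            raise ValueError("smoothest level must have blur sigma 0")
        if self.disarray_amplitudes[0] != 0:
            raise ValueError("even-coating level must have disarray amplitude 0")
        if self.disarray_scale <= 0:
            raise ValueError("disarray_scale must be positive")
        if self.scatter_loss < 0:
            raise ValueError("scatter_loss must be nonnegative")
        if self.scatter_loss * self.disarray_amplitudes[-1] / self.image_size >= 1:
            raise ValueError("scatter_loss too large: luminance gain would be negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSpaceConfig":
        d = dict(d)
        for k in ("blur_sigmas", "disarray_amplitudes"):
            if d.get(k) is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    ``observers`` is a roster of (statistic-name, noise_sd) pairs; the
    statistic names are resolved against the contrast estimators, the
    pyramid statistics (``A1``, ``A1_minus_A4``) or ``metallicity:a,b``.
    """

    stimulus: StimulusSpaceConfig = field(default_factory=StimulusSpaceConfig)
    observers: list[tuple[str, float]] = field(
        default_factory=lambda: [("A1", 0.0), ("A1_minus_A4", 0.0)]
    )
    n_mlcm_repeats: int = 4
    mlds_n_levels: int = 11
    compute_spectra: bool = True
    compute_pyramid: bool = True
    compute_contrast: bool = True
    make_figures: bool = True
    alpha: float = 0.001
    seed: int = 0
    output_dir: str = "metalsense_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stimulus"] = self.stimulus.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("stimulus"), dict):
            d["stimulus"] = StimulusSpaceConfig.from_dict(d["stimulus"])
        if "observers" in d:
            d["observers"] = [tuple(o) for o in d["observers"]]
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        """Short stable hash recorded in every output file; excludes the
        output directory, which does not affect any computed value."""
        d = self.to_dict()
        d.pop("output_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
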