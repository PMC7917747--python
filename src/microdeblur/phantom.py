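"""Synthetic resolution phantom and forward degradation model.

Light-microscopy acquisition is modelled as a linear shift-invariant
system: the observed image ``g`` is the clean scene ``f`` convolved with
the system point-spread function plus additive Gaussian background
noise,

    g = psf ** f + N,        N ~ Normal(mean, variance) i.i.d.

This module provides everything needed to exercise the blind
deconvolution pipeline without measured data: a Siemens-star resolution
chart (alternating bright/dark angular sectors whose spatial frequency
grows toward the center), parametric Gaussian blur kernels, and the
degradation operator itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Image2D",
    "StarPhantomSpec",
    "DegradationSpec",
    "generate_star_phantom",
    "gaussian_psf",
    "degrade",
]


@dataclass
class Image2D:
    """A single-channel intensity raster.

    Parameters
    ----------
    pixels : ndarray
        2-D float array, nominal intensity range [0, 1].  Intermediate
        results (e.g. noisy observations) may leave the nominal range;
        clipping happens only at export time.
    pixel_pitch : float, optional
        Physical pixel size in micrometres.  Only consumed by
        frequency-axis computations (noise power spectra).
    """

    pixels: np.ndarray
    pixel_pitch: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 3:
            raise ValueError("Image2D requires a rectangular array of at least 3x3")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("Image2D pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def as_image(img, pixel_pitch: Optional[float] = None) -> Image2D:
    """Coerce an ndarray (or Image2D) to :class:`Image2D`."""
    if isinstance(img, Image2D):
        return img
    return Image2D(np.asarray(img, dtype=np.float64), pixel_pitch)


@dataclass
class StarPhantomSpec:
    """Geometry and intensity levels of the Siemens-star chart.

    The defaults reproduce the simulation chart used throughout this
    package: a 2000 x 2000 frame with 36 bright/dark spoke pairs.  The
    star disc fills 90% of the frame so that the spoke pattern dominates
    global image statistics; the 1.7 um pixel pitch is carried as
    metadata for frequency axes.
    """

    image_size: int = 2000
    n_spoke_pairs: int = 36
    star_diameter: Optional[float] = None  # None -> 0.9 * image_size
    bright_level: float = 1.0
    dark_level: float = 0.0
    background_level: float = 0.5
    supersample_factor: int = 4
    pixel_pitch: float = 1.7

    def __post_init__(self):
        if self.n_spoke_pairs < 1:
            raise ValueError("n_spoke_pairs must be >= 1")
        if self.star_diameter is not None and self.star_diameter > self.image_size:
            raise ValueError("star_diameter exceeds image_size")
        if not self.bright_level > self.dark_level:
            raise ValueError("bright_level must exceed dark_level")
        if self.supersample_factor < 1:
            raise ValueError("supersample_factor must be >= 1")

    @property
    def diameter(self) -> float:
        return 0.9 * self.image_size if self.star_diameter is None else float(self.star_diameter)


@dataclass
class DegradationSpec:
    """Forward-model parameters: blur kernel plus Gaussian noise."""

    psf: "PSFKernel"
    noise_mean: float = 0.0
    noise_variance: float = 0.01
    rng_seed: int = 0

    def __post_init__(self):
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")


def generate_star_phantom(spec: StarPhantomSpec) -> Image2D:
    """Render the Siemens-star chart.

    Inside the star disc a pixel is bright iff ``sin(n * theta) > 0``
    with ``theta`` the polar angle about the frame center and ``n`` the
    number of spoke pairs, so bright and dark sectors alternate ``n``
    times per revolution and carry equal angular measure.  Outside the
    disc the frame is uniform background.  Edges are anti-aliased by
    box-averaging ``supersample_factor**2`` sub-samples per pixel.
    Fully deterministic.
    """
    n = spec.image_size
    ss = spec.supersample_factor
    radius = spec.diameter / 2.0
    center = n / 2.0
    out = np.empty((n, n), dtype=np.float64)

    # sub-pixel center coordinates on the supersampled grid
    u = (np.arange(n * ss, dtype=np.float64) + 0.5) / ss - center
    # render in row blocks to bound memory at full scale
    block = max(1, int(4_000_000 // (n * ss * ss))) if n * ss > 4096 else n
    for r0 in range(0, n, block):
        r1 = min(n, r0 + block)
        yy = u[r0 * ss : r1 * ss][:, None]
        xx = u[None, :]
        theta = np.arctan2(yy, xx)
        pattern = np.where(
            np.sin(spec.n_spoke_pairs * theta) > 0.0, spec.bright_level, spec.dark_level
        )
        inside = (xx * xx + yy * yy) < radius * radius
        vals = np.where(inside, pattern, spec.background_level)
        # box-filter downsample
        vals = vals.reshape(r1 - r0, ss, n, ss).mean(axis=(1, 3))
        out[r0:r1] = vals
    return Image2D(out, pixel_pitch=spec.pixel_pitch)


def gaussian_psf(size: int = 51, sigma: float = 1.5) -> "PSFKernel":
    """Isotropic Gaussian blur kernel, sampled at pixel centers, sum-normalized."""
    from .psf import PSFKernel

    if size % 2 == 0 or size < 1:
        raise ValueError("kernel size must be a positive odd integer")
    x = np.arange(size, dtype=np.float64) - size // 2
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    k = np.outer(g1, g1)
    return PSFKernel(k / k.sum())


def degrade(clean: Image2D, spec: DegradationSpec) -> Image2D:
    """Apply the forward model: blur then add i.i.d. Gaussian noise.

    The output is intentionally not clipped to [0, 1]; clipping would
    bias the additive-noise model.  Identical ``spec`` (including
    ``rng_seed``) produces a bit-identical observation.
    """
    from .restore import convolve_psf

    clean = as_image(clean)
    k = spec.psf.weights
    if k.shape[0] > clean.shape[0] or k.shape[1] > clean.shape[1]:
        raise ValueError("kernel larger than image")
    blurred = convolve_psf(clean, spec.psf)
    rng = np.random.default_rng(spec.rng_seed)
    noise = rng.normal(spec.noise_mean, np.sqrt(spec.noise_variance), clean.shape)
    return Image2D(blurred.pixels + noise, pixel_pitch=clean.pixel_pitch)
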