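"""Quantitative image-quality evaluation.

Full-reference scalar metrics (RMSE, PSNR, SSIM, edge-preservation
index), line-profile extraction, and the normalized noise power
spectrum (NNPS) of flat-field regions:

    NPS(u, v)  = K^2 / M^2 * < |DFT(roi - mean(roi))|^2 >_rois
    NNPS(u, v) = NPS(u, v) / S^2

with K the physical pixel size (um), M the ROI side, and S the
large-area mean signal.  The 2-D spectrum is radially averaged into a
curve against spatial frequency in line pairs per micrometre, up to the
Nyquist frequency 1/(2K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as _fft
from scipy.ndimage import map_coordinates
from skimage.metrics import structural_similarity

from .phantom import Image2D, as_image
from .psf import laplacian

__all__ = [
    "MetricsReport",
    "NPSSpec",
    "NNPSCurve",
    "LineProfile",
    "rmse",
    "epi",
    "ssim",
    "psnr",
    "compute_nnps",
    "extract_profile",
    "evaluate",
]


@dataclass
class MetricsReport:
    rmse: float
    epi: float
    ssim: float
    psnr: float

    def as_dict(self) -> dict:
        return {"rmse": self.rmse, "epi": self.epi, "ssim": self.ssim, "psnr": self.psnr}


@dataclass
class NPSSpec:
    """Noise-power-spectrum estimation protocol.

    ``pixel_size`` in micrometres; ``roi_size`` a power of two;
    ``roi_overlap`` the fractional overlap of adjacent ROIs;
    ``n_rois`` caps the ROI count (None = all that fit);
    ``large_area_signal`` the normalization signal (None = region mean).
    """

    pixel_size: float = 1.7
    roi_size: int = 128
    roi_overlap: float = 0.5
    n_rois: Optional[int] = None
    large_area_signal: Optional[float] = None

    def __post_init__(self):
        if self.roi_size < 2 or (self.roi_size & (self.roi_size - 1)) != 0:
            raise ValueError("roi_size must be a power of two")
        if not 0 <= self.roi_overlap < 1:
            raise ValueError("roi_overlap must be in [0, 1)")
        if self.n_rois is not None and self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.large_area_signal is not None and self.large_area_signal <= 0:
            raise ValueError("large_area_signal must be > 0")


@dataclass
class NNPSCurve:
    frequencies: np.ndarray  # lp/um, strictly increasing
    values: np.ndarray
    radial: bool = True
    nps_2d: Optional[np.ndarray] = None
    n_rois_used: int = 0


@dataclass
class LineProfile:
    positions: np.ndarray  # pixels along the segment
    intensities: np.ndarray  # max-normalized unless degenerate
    degenerate: bool = False


def _pair(a, b):
    a = as_image(a).pixels
    b = as_image(b).pixels
    if a.shape != b.shape:
        raise ValueError("images must have the same shape")
    return a.astype(np.float64), b.astype(np.float64)


def rmse(a, b) -> float:
    """Root-mean-square elementwise difference."""
    a, b = _pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def epi(test, ref) -> float:
    """Edge preservation index.

    Pearson correlation of the Laplacian-filtered (high-pass) test and
    reference images; 1 means edges perfectly preserved, -1 perfectly
    inverted.  Undefined for flat images.
    """
    t, r = _pair(test, ref)
    lt = laplacian(Image2D(t)).pixels.ravel()
    lr = laplacian(Image2D(r)).pixels.ravel()
    lt = lt - lt.mean()
    lr = lr - lr.mean()
    denom = np.sqrt(np.sum(lt**2) * np.sum(lr**2))
    if denom == 0:
        raise ValueError("EPI undefined: zero-variance Laplacian (flat image)")
    return float(np.sum(lt * lr) / denom)


def ssim(test, ref) -> float:
    """Mean structural similarity, 11x11 Gaussian window (sigma 1.5).

    Uses the canonical stabilizers C1 = (0.01 L)^2, C2 = (0.03 L)^2 with
    dynamic range L = 1.
    """
    t, r = _pair(test, ref)
    return float(
        structural_similarity(
            r, t, win_size=11, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0, K1=0.01, K2=0.03,
        )
    )


def psnr(test, ref) -> float:
    """Peak signal-to-noise ratio in dB (peak 1); +inf for identical images."""
    t, r = _pair(test, ref)
    mse = float(np.mean((t - r) ** 2))
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def compute_nnps(flat_region, spec: Optional[NPSSpec] = None) -> NNPSCurve:
    """Normalized noise power spectrum of a flat-field region.

    The region is tiled into overlapping ROIs, each ROI is mean-
    subtracted (first-order detrending), the squared modulus of its DFT
    is averaged over ROIs and scaled to physical NPS units, then
    normalized by the squared large-area signal and radially averaged.
    """
    img = as_image(flat_region)
    spec = spec or NPSSpec(pixel_size=img.pixel_pitch or 1.7)
    m = spec.roi_size
    h, w = img.shape
    if h < m or w < m:
        raise ValueError("region smaller than roi_size")
    stride = max(1, int(round(m * (1.0 - spec.roi_overlap))))
    ys = list(range(0, h - m + 1, stride))
    xs = list(range(0, w - m + 1, stride))
    rois = []
    for y in ys:
        for x in xs:
            rois.append(img.pixels[y : y + m, x : x + m])
            if spec.n_rois is not None and len(rois) >= spec.n_rois:
                break
        if spec.n_rois is not None and len(rois) >= spec.n_rois:
            break

    signal = spec.large_area_signal
    if signal is None:
        signal = float(img.pixels.mean())
    if signal == 0:
        raise ValueError("zero large-area signal")

    k = spec.pixel_size
    acc = np.zeros((m, m), dtype=np.float64)
    for roi in rois:
        detrended = roi - roi.mean()
        acc += np.abs(_fft.fft2(detrended)) ** 2
    nps = (k**2 / m**2) * acc / len(rois)
    nnps2d = nps / signal**2

    freqs = _fft.fftfreq(m, d=k)
    fr = np.hypot(freqs[:, None], freqs[None, :])
    nyquist = 1.0 / (2.0 * k)
    df = 1.0 / (m * k)
    edges = np.arange(0.0, nyquist + df, df)
    centers, values = [], []
    for i in range(len(edges) - 1):
        mask = (fr >= edges[i]) & (fr < edges[i + 1])
        if mask.any():
            centers.append(0.5 * (edges[i] + edges[i + 1]))
            values.append(float(nnps2d[mask].mean()))
    return NNPSCurve(
        frequencies=np.asarray(centers),
        values=np.asarray(values),
        radial=True,
        nps_2d=nnps2d,
        n_rois_used=len(rois),
    )


def extract_profile(img, start, end) -> LineProfile:
    """Bilinear line profile at unit-spaced samples, max-normalized.

    ``start`` and ``end`` are (row, col) coordinates inside the image.
    """
    img = as_image(img)
    h, w = img.shape
    for p in (start, end):
        if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
            raise ValueError("profile endpoint outside the image")
    start = np.asarray(start, dtype=np.float64)
    end = np.asarray(end, dtype=np.float64)
    length = float(np.linalg.norm(end - start))
    n = int(np.floor(length)) + 1
    t = np.arange(n, dtype=np.float64)
    if length > 0:
        direction = (end - start) / length
    else:
        direction = np.zeros(2)
    coords = start[:, None] + direction[:, None] * t[None, :]
    vals = map_coordinates(img.pixels, coords, order=1, mode="nearest")
    peak = vals.max() if n else 0.0
    if peak <= 0:
        return LineProfile(t, vals, degenerate=True)
    return LineProfile(t, vals / peak, degenerate=False)


def evaluate(test, ref) -> MetricsReport:
    """Bundle of the scalar full-reference metrics."""
    return MetricsReport(rmse=rmse(test, ref), epi=epi(test, ref), ssim=ssim(test, ref), psnr=psnr(test, ref))
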