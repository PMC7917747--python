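"""Blur-kernel estimation by conjugate gradients on Laplacian images.

Given the current sharp-image estimate ``f`` and the observation ``g``,
the kernel is the least-squares solution of

    min_k || lap(f) ** k - lap(g) ||^2        (k on a small odd support)

where ``lap`` is the discrete Laplacian.  Working on Laplacian-filtered
images concentrates the fit on edges, which carry the blur information,
and suppresses the influence of smooth shading.  The normal equations of
this linear problem are solved by conjugate gradients with FFT-based
operator applications; the solution is then projected onto the feasible
set of kernels (non-negative, unit sum, centered).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import fft as _fft
from scipy import ndimage as _ndi
from scipy.optimize import curve_fit

from . import _operators as ops
from .phantom import Image2D, as_image

__all__ = [
    "PSFKernel",
    "CGConfig",
    "laplacian",
    "estimate_psf_cg",
    "project_kernel",
    "fit_gaussian_sigma",
]

_LAPLACE_STENCIL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class PSFKernel:
    """Small odd-sized convolution kernel.

    After :func:`project_kernel` the weights are non-negative, sum to
    one (within 1e-9) and have their centroid at the central pixel.
    ``converged`` is a solver diagnostic (False when conjugate gradients
    hit the iteration cap above tolerance); ``degenerate`` flags a
    kernel that collapsed to a fallback delta during projection.
    """

    weights: np.ndarray
    converged: bool = True
    degenerate: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("kernel must be square")
        if self.weights.shape[0] % 2 == 0:
            raise ValueError("kernel side must be odd")

    @property
    def size(self) -> int:
        return self.weights.shape[0]


def delta_kernel(size: int) -> PSFKernel:
    w = np.zeros((size, size))
    w[size // 2, size // 2] = 1.0
    return PSFKernel(w)


@dataclass
class CGConfig:
    """Inner-solver control for the kernel least-squares problem."""

    max_iterations: int = 25
    residual_tolerance: float = 1e-6
    kernel_size: int = 51
    dtype: str = "float32"  # working precision of the FFT solver
    prefilter_sigma: float = 2.0
    support_threshold: float = 0.02  # of the peak; 0 disables the cleanup
    identity_tolerance: float = 0.15  # relative residual below which the kernel is a delta

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.residual_tolerance <= 0:
            raise ValueError("residual_tolerance must be > 0")
        if self.kernel_size % 2 == 0 or self.kernel_size < 1:
            raise ValueError("kernel_size must be a positive odd integer")


def laplacian(img) -> Image2D:
    """Discrete 5-point Laplacian with symmetric boundary handling."""
    img = as_image(img)
    if min(img.shape) < 3:
        raise ValueError("image smaller than the Laplacian stencil")
    out = _ndi.convolve(img.pixels, _LAPLACE_STENCIL, mode="reflect")
    return Image2D(out, pixel_pitch=img.pixel_pitch)


class _KernelOperator:
    """FFT application of k -> lap(f) ** k (periodic, padded domain) and its adjoint."""

    def __init__(self, lap_current: np.ndarray, kernel_size: int, dtype):
        n = kernel_size
        self.kshape = (n, n)
        self.pshape = ops.fast_padded_shape(lap_current.shape, n // 2)
        padded, _ = ops.pad_symmetric_to(lap_current.astype(dtype), self.pshape)
        self.fhat = _fft.rfft2(padded)
        self.fhat_sq = np.abs(self.fhat) ** 2
        self.dtype = dtype

    def forward(self, k: np.ndarray) -> np.ndarray:
        big = ops.embed_kernel(k, self.pshape, dtype=self.dtype)
        return _fft.irfft2(self.fhat * _fft.rfft2(big), self.pshape)

    def adjoint(self, img: np.ndarray) -> np.ndarray:
        corr = _fft.irfft2(np.conj(self.fhat) * _fft.rfft2(img), self.pshape)
        return ops.extract_kernel(corr, self.kshape)

    def normal(self, k: np.ndarray) -> np.ndarray:
        """A^T A k in two transforms using the precomputed |F|^2."""
        big = ops.embed_kernel(k, self.pshape, dtype=self.dtype)
        out = _fft.irfft2(self.fhat_sq * _fft.rfft2(big), self.pshape)
        return ops.extract_kernel(out, self.kshape)


def _solve_kernel_cg(
    lap_current: np.ndarray,
    lap_observed: np.ndarray,
    config: CGConfig,
    record_residuals: bool = False,
):
    """Conjugate gradients on the normal equations A^T A k = A^T b.

    Because CG on the normal equations minimizes the error in the
    A^T A-norm, the least-squares residual ||A k - b|| is non-increasing
    over iterations.  Returns (kernel, converged, ls_residual_trace).
    """
    dtype = np.dtype(config.dtype)
    op = _KernelOperator(lap_current, config.kernel_size, dtype)
    b_pad, _ = ops.pad_symmetric_to(lap_observed.astype(dtype), op.pshape)
    atb = op.adjoint(b_pad)

    x = np.zeros(op.kshape, dtype=dtype)
    r = atb.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    rs0 = max(rs, 1e-300)
    trace = []
    if record_residuals:
        trace.append(float(np.linalg.norm(op.forward(x) - b_pad)))
    converged = False
    for _ in range(config.max_iterations):
        q = op.normal(p)
        denom = float(np.vdot(p, q).real)
        if denom <= 0 or not np.isfinite(denom):
            converged = True  # reached the numerical floor of the quadratic
            break
        a = rs / denom
        x = x + a * p
        r = r - a * q
        rs_new = float(np.vdot(r, r).real)
        if record_residuals:
            trace.append(float(np.linalg.norm(op.forward(x) - b_pad)))
        if np.sqrt(rs_new / rs0) < config.residual_tolerance:
            converged = True
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return np.asarray(x, dtype=np.float64), converged, trace


def estimate_psf_cg(
    current,
    observed,
    config: Optional[CGConfig] = None,
    record_residuals: bool = False,
) -> PSFKernel:
    """Estimate the blur kernel relating ``current`` (sharp) to ``observed``.

    Deterministic.  Non-convergence of the inner conjugate-gradient loop
    is reported through ``PSFKernel.converged``, not an exception.
    """
    config = config or CGConfig()
    current = as_image(current)
    observed = as_image(observed)
    if current.shape != observed.shape:
        raise ValueError("current and observed images must have the same shape")
    if config.kernel_size >= min(current.shape):
        raise ValueError("kernel_size must be smaller than both image dimensions")

    cur_px, obs_px = current.pixels, observed.pixels

    # identity shortcut: when the delta kernel already explains the
    # observation (small relative Laplacian residual), the least-squares
    # solution IS the centered delta -- return it exactly.  This is also
    # the regime in which the low-pass prefilter below would make the
    # delta unresolvable for CG.
    lap_cur = laplacian(current).pixels
    lap_obs = laplacian(observed).pixels
    obs_norm = np.linalg.norm(lap_obs)
    if np.linalg.norm(lap_cur - lap_obs) < config.identity_tolerance * max(obs_norm, 1e-300):
        kernel = delta_kernel(config.kernel_size)
        if record_residuals:
            kernel.residual_trace = [float(np.linalg.norm(lap_cur - lap_obs))]
        return kernel

    if config.prefilter_sigma > 0:
        # Identical Gaussian pre-smoothing of both images leaves the
        # relating kernel unchanged (s**g = k**(s**f) + s**n) while
        # suppressing the noise amplification of the Laplacian, and
        # biases the under-resolved CG solution toward smooth kernels.
        cur_px = _ndi.gaussian_filter(cur_px, config.prefilter_sigma, mode="reflect")
        obs_px = _ndi.gaussian_filter(obs_px, config.prefilter_sigma, mode="reflect")
        lap_f = laplacian(Image2D(cur_px)).pixels
        lap_g = laplacian(Image2D(obs_px)).pixels
    else:
        lap_f, lap_g = lap_cur, lap_obs
    raw, converged, trace = _solve_kernel_cg(lap_f, lap_g, config, record_residuals)
    kernel = project_kernel(PSFKernel(raw, converged=converged))
    if config.support_threshold > 0:
        kernel = _clean_support(kernel, config.support_threshold)
    kernel.converged = converged
    if record_residuals:
        kernel.residual_trace = trace  # diagnostic attribute
    return kernel


def _clean_support(k: PSFKernel, fraction: float) -> PSFKernel:
    """Suppress least-squares speckle in an estimated kernel.

    The non-negative projection of LS noise appears as isolated positive
    speckle, whose high-frequency content makes the subsequent
    deconvolution amplify noise.  Entries below ``fraction`` of the peak
    are zeroed and only connected components touching the central 3x3
    block are kept (a physical PSF is centered mass; far, disconnected
    islands are fit noise), then the kernel is re-projected.  A
    Gaussian-like kernel is a single centered component and passes
    through with only its far tail (below the threshold) removed.
    """
    w = k.weights.copy()
    w[w < fraction * w.max()] = 0.0
    labels, nlab = _ndi.label(w > 0, structure=np.ones((3, 3), dtype=int))
    if nlab > 0:
        c = k.size // 2
        central = np.unique(labels[c - 1 : c + 2, c - 1 : c + 2])
        keep = np.isin(labels, central[central > 0])
        w[~keep] = 0.0
    return project_kernel(PSFKernel(w, converged=k.converged))


def project_kernel(k: PSFKernel) -> PSFKernel:
    """Project onto the feasible kernel set.

    Negative weights are zeroed, the kernel is renormalized to unit sum,
    and its centroid is moved to the central pixel by an integer shift
    (mass shifted off the support is discarded, then renormalized).
    Idempotent.  An all-zero kernel after thresholding degenerates to a
    centered delta with ``degenerate=True``.
    """
    w = np.maximum(k.weights, 0.0)
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        d = delta_kernel(k.size)
        d.degenerate = True
        return d
    # renormalize; skip the division when already at unit sum so the
    # projection is bit-exactly idempotent
    for _ in range(3):
        total = w.sum()
        if abs(total - 1.0) <= 1e-12:
            break
        w = w / total
    n = k.size
    c = n // 2
    idx = np.arange(n, dtype=np.float64)
    cy = float((w.sum(axis=1) * idx).sum())
    cx = float((w.sum(axis=0) * idx).sum())
    sy, sx = int(round(c - cy)), int(round(c - cx))
    if sy != 0 or sx != 0:
        shifted = np.zeros_like(w)
        shifted[max(0, sy) : n + min(0, sy), max(0, sx) : n + min(0, sx)] = w[
            max(0, -sy) : n - max(0, sy), max(0, -sx) : n - max(0, sx)
        ]
        w = shifted
        total = w.sum()
        if total <= 0:
            d = delta_kernel(k.size)
            d.degenerate = True
            return d
        for _ in range(3):
            total = w.sum()
            if abs(total - 1.0) <= 1e-12:
                break
            w = w / total
    return PSFKernel(w, converged=k.converged, degenerate=False)


def fit_gaussian_sigma(k: PSFKernel) -> float:
    """Least-squares Gaussian width of the central row profile.

    Fits ``a * exp(-x^2 / (2 sigma^2))`` to the kernel row through the
    center (the line profile through the kernel peak) and returns
    ``sigma`` in pixels.
    """
    w = k.weights
    if w.sum() <= 0:
        raise ValueError("kernel has non-positive mass")
    c = k.size // 2
    row = w[c, :].astype(np.float64)
    x = np.arange(k.size, dtype=np.float64) - c

    total = row.sum()
    if total <= 0:
        raise ValueError("central kernel profile is non-Gaussian-like (no mass)")
    var0 = float((row * x**2).sum() / total)
    p0 = (float(row.max()), max(np.sqrt(var0), 0.25))

    def model(xv, a, sigma):
        return a * np.exp(-0.5 * (xv / sigma) ** 2)

    try:
        popt, _ = curve_fit(model, x, row, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ValueError("central kernel profile is non-Gaussian-like") from exc
    sigma = abs(float(popt[1]))
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("central kernel profile is non-Gaussian-like")
    return sigma
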