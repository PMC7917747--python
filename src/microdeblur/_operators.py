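"""Internal FFT-domain and finite-difference operators.

All iterative solvers in this package work on a padded, periodic grid:
the image is extended by symmetric (mirror) padding up to an FFT-friendly
size, convolutions become diagonal in Fourier space, and the result is
cropped back.  The mirror margin (at least one kernel half-width) keeps
wrap-around artifacts out of the cropped region.

The forward-difference gradient and its exact adjoint (negative
divergence) live here too, so that every module penalizing ``|grad f|``
uses the same discrete operator pair.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as _fft


def fast_padded_shape(shape: tuple[int, int], margin: int) -> tuple[int, int]:
    """FFT-friendly shape at least ``margin`` larger than ``shape`` per side."""
    return tuple(_fft.next_fast_len(n + 2 * margin, real=True) for n in shape)


def pad_symmetric_to(img: np.ndarray, padded_shape: tuple[int, int]):
    """Mirror-pad ``img`` to ``padded_shape``, roughly centered.

    Returns the padded array and the (row, col) offset of the original
    image inside it.
    """
    py = padded_shape[0] - img.shape[0]
    px = padded_shape[1] - img.shape[1]
    if py < 0 or px < 0:
        raise ValueError("padded shape smaller than image")
    pads = ((py // 2, py - py // 2), (px // 2, px - px // 2))
    return np.pad(img, pads, mode="symmetric"), (pads[0][0], pads[1][0])


def crop(padded: np.ndarray, offset: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    r, c = offset
    return padded[r : r + shape[0], c : c + shape[1]]


def kernel_otf(kernel: np.ndarray, padded_shape: tuple[int, int], dtype=np.float64) -> np.ndarray:
    """Optical transfer function: kernel embedded with its center at the origin."""
    kh, kw = kernel.shape
    big = np.zeros(padded_shape, dtype=dtype)
    big[:kh, :kw] = kernel
    big = np.roll(big, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return _fft.rfft2(big)


def embed_kernel(kernel: np.ndarray, padded_shape: tuple[int, int], dtype=np.float64) -> np.ndarray:
    """Zero-embed a small kernel, center at the origin (no transform)."""
    kh, kw = kernel.shape
    big = np.zeros(padded_shape, dtype=dtype)
    big[:kh, :kw] = kernel
    return np.roll(big, (-(kh // 2), -(kw // 2)), axis=(0, 1))


def extract_kernel(big: np.ndarray, kernel_shape: tuple[int, int]) -> np.ndarray:
    """Inverse of :func:`embed_kernel`: read the origin-centered support back."""
    kh, kw = kernel_shape
    return np.roll(big, (kh // 2, kw // 2), axis=(0, 1))[:kh, :kw].copy()


def rfft2_sqnorm(spec: np.ndarray, real_shape: tuple[int, int]) -> float:
    """``sum(x**2)`` of the real field from its rFFT, via Parseval.

    The redundant half-spectrum columns are double-counted except the
    DC column and, for even widths, the Nyquist column.
    """
    ny, nx = real_shape
    power = np.abs(spec) ** 2
    total = 2.0 * np.sum(power, dtype=np.float64)
    total -= np.sum(power[:, 0], dtype=np.float64)
    if nx % 2 == 0:
        total -= np.sum(power[:, -1], dtype=np.float64)
    return float(total) / (ny * nx)


def grad_forward_raw(img: np.ndarray):
    """Forward differences; last column/row of the respective axis is zero."""
    gx = np.zeros_like(img)
    gy = np.zeros_like(img)
    gx[:, :-1] = img[:, 1:] - img[:, :-1]
    gy[:-1, :] = img[1:, :] - img[:-1, :]
    return gx, gy


def grad_adjoint_raw(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Exact adjoint of :func:`grad_forward_raw` (a negative divergence)."""
    out = np.zeros_like(gx)
    out[:, 0] -= gx[:, 0]
    out[:, 1:-1] -= gx[:, 1:-1]
    out[:, 1:] += gx[:, :-1]
    out[0, :] -= gy[0, :]
    out[1:-1, :] -= gy[1:-1, :]
    out[1:, :] += gy[:-1, :]
    return out
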