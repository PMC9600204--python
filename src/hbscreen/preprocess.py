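"""Filtering and thresholding of strip images.

The segmentation front end converts the RGB strip to grayscale,
complements it so the dark stained bands become the bright foreground,
denoises with a 5x5 Gaussian, and binarizes at the Otsu threshold (the
global threshold maximizing between-class variance of the histogram).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import StripImage, as_rgb_array
from .errors import DegenerateImageError, FormatError, ParameterError

#: ITU-R BT.601 luma weights.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(rgb) -> np.ndarray:
    """Luma-weighted grayscale conversion, rounded to uint8."""
    arr = as_rgb_array(rgb).astype(float)
    gray = (
        LUMA_WEIGHTS[0] * arr[..., 0]
        + LUMA_WEIGHTS[1] * arr[..., 1]
        + LUMA_WEIGHTS[2] * arr[..., 2]
    )
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def complement(gray: np.ndarray) -> np.ndarray:
    """Map every pixel v to 255 - v (an involution)."""
    g = _as_gray(gray)
    return (255 - g.astype(np.int16)).astype(np.uint8)


def gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    """Unit-sum 1-D Gaussian sampled at integer offsets."""
    if size % 2 == 0:
        raise ParameterError(f"kernel size must be odd, got {size}")
    if sigma <= 0:
        raise ParameterError(f"sigma must be > 0, got {sigma}")
    x = np.arange(size) - size // 2
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_blur(
    gray: np.ndarray, size: int = 5, sigma: float = 1.0
) -> np.ndarray:
    """Separable Gaussian convolution with reflected borders.

    The kernel is the normalized discrete Gaussian (outer product of
    :func:`gaussian_kernel_1d` with itself); output is rounded back to
    uint8.
    """
    g = _as_gray(gray).astype(float)
    k = gaussian_kernel_1d(size, sigma)
    out = ndimage.correlate1d(g, k, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k, axis=1, mode="reflect")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Threshold t in [0, 254] maximizing between-class variance.

    Foreground is defined as ``pixels > t``.  Between-class variance is
    ``w0 * w1 * (mu0 - mu1)^2`` over the 256-bin histogram; ties are
    broken toward the smallest maximizing threshold.  A constant image
    has no two classes to separate and raises
    :class:`DegenerateImageError`.
    """
    g = _as_gray(gray)
    hist = np.bincount(g.ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise DegenerateImageError(
            "Otsu threshold undefined for a constant image"
        )
    total = hist.sum()
    p = hist / total
    omega0 = np.cumsum(p)[:-1]  # P(value <= t), t = 0..254
    omega1 = 1.0 - omega0
    mu_t = np.cumsum(p * np.arange(256))
    mu_total = mu_t[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_t[:-1] / omega0
        mu1 = (mu_total - mu_t[:-1]) / omega1
        between = omega0 * omega1 * (mu0 - mu1) ** 2
    between = np.where(np.isfinite(between), between, -np.inf)
    return int(np.argmax(between))


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask ``gray > threshold`` as a {0,1} uint8 array."""
    g = _as_gray(gray)
    return (g > threshold).astype(np.uint8)


def preprocess_strip(
    strip: StripImage | np.ndarray,
    kernel_size: int = 5,
    sigma: float = 1.0,
    return_intermediates: bool = False,
):
    """Full front end: grayscale -> complement -> blur -> Otsu -> binary.

    The threshold is computed on the blurred complement (the filter is
    applied before thresholding so single-pixel noise cannot shift the
    histogram valley).  Returns the binary foreground mask, or a dict of
    every intermediate stage when ``return_intermediates`` is set.
    """
    gray = to_grayscale(strip)
    comp = complement(gray)
    blurred = gaussian_blur(comp, kernel_size, sigma)
    t = otsu_threshold(blurred)
    binary = binarize(blurred, t)
    if return_intermediates:
        return {
            "gray": gray,
            "complement": comp,
            "blurred": blurred,
            "threshold": t,
            "binary": binary,
        }
    return binary


def _as_gray(gray: np.ndarray) -> np.ndarray:
    arr = np.asarray(gray)
    if arr.ndim != 2:
        raise FormatError(f"expected 2-D grayscale array, got {arr.shape}")
    if arr.dtype != np.uint8:
        if arr.min() < 0 or arr.max() > 255:
            raise FormatError("grayscale values must lie in [0, 255]")
        arr = arr.astype(np.uint8)
    return arr
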