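"""Automatic image thresholding: triangle, Otsu, adaptive mean/Gaussian.

Global auto-thresholding picks one cutoff for the whole frame from the
gray-level histogram; adaptive thresholding computes a per-pixel cutoff
from the local neighbourhood, which survives illumination gradients that
defeat any single global value.

Polarity convention: ``object_type='light'`` selects pixels strictly above
the threshold, ``'dark'`` strictly below, so masks are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ThresholdResult",
    "histogram256",
    "triangle_auto_threshold",
    "otsu_auto_threshold",
    "adaptive_threshold",
    "binary_threshold",
]


@dataclass
class ThresholdResult:
    """Mask plus, for global methods, the chosen cutoff and the histogram."""

    mask: np.ndarray
    threshold_value: int
    histogram: np.ndarray | None = None


def _check_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("thresholding expects a single-channel image")
    return img.astype(np.uint8)


def histogram256(img: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram; counts sum to the pixel count."""
    return np.bincount(_check_gray(img).ravel(), minlength=256)


def _apply(img: np.ndarray, value: float, object_type: str,
           max_value: int = 255) -> np.ndarray:
    if object_type == "light":
        sel = img > value
    elif object_type == "dark":
        sel = img < value
    else:
        raise ValueError("object_type must be 'light' or 'dark'")
    return (sel * np.uint8(max_value)).astype(np.uint8)


def triangle_threshold_from_hist(hist: np.ndarray, object_type: str = "light",
                                 xstep: int = 1) -> int:
    """Triangle (Zack) threshold from a 256-bin histogram.

    A line is drawn from the histogram peak to the last occupied bin on the
    object side; the threshold is the gray level between them whose
    histogram point lies farthest (perpendicular distance) from that line.
    ``xstep`` strides the candidate levels, coarsening the search.
    """
    if xstep < 1:
        raise ValueError("xstep must be >= 1")
    hist = np.asarray(hist, dtype=np.float64)
    occupied = np.nonzero(hist)[0]
    if len(occupied) < 2:
        raise ValueError("histogram has fewer than two occupied bins")
    peak = int(np.argmax(hist))
    if object_type == "light":
        end = int(occupied[-1])
        if end <= peak:
            raise ValueError("no histogram tail above the peak for light objects")
        candidates = np.arange(peak + 1, end, xstep)
    elif object_type == "dark":
        end = int(occupied[0])
        if end >= peak:
            raise ValueError("no histogram tail below the peak for dark objects")
        candidates = np.arange(peak - 1, end, -xstep)
    else:
        raise ValueError("object_type must be 'light' or 'dark'")
    if len(candidates) == 0:
        return peak
    # perpendicular distance from (x, h[x]) to the peak->end line
    px, py = float(peak), hist[peak]
    ex, ey = float(end), hist[end]
    cx = candidates.astype(np.float64)
    cross = np.abs((ex - px) * (hist[candidates] - py) - (ey - py) * (cx - px))
    dist = cross / np.hypot(ex - px, ey - py)
    return int(candidates[int(np.argmax(dist))])


def triangle_auto_threshold(img: np.ndarray, max_value: int = 255,
                            object_type: str = "light",
                            xstep: int = 1) -> ThresholdResult:
    """Threshold a grayscale image with the triangle method.

    Suits strongly unimodal histograms (a dominant background peak with a
    long object tail). Returns the mask, the chosen gray level and the
    histogram it was derived from.
    """
    img = _check_gray(img)
    hist = histogram256(img)
    t = triangle_threshold_from_hist(hist, object_type=object_type, xstep=xstep)
    return ThresholdResult(mask=_apply(img, t, object_type, max_value),
                           threshold_value=t, histogram=hist)


def otsu_threshold_from_hist(hist: np.ndarray) -> int:
    """Otsu threshold: argmin of weighted within-class variance.

    Every split ``t`` partitions levels into {<=t} and {>t}; ties are
    broken toward the lower level.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram has fewer than two occupied bins")
    total = hist.sum()
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                       # mass of class {<= t}
    s0 = np.cumsum(hist * levels)
    w1 = total - w0
    s1 = s0[-1] - s0
    # minimizing within-class variance == maximizing between-class variance
    # w0*w1*(mu0 - mu1)^2; the latter avoids the catastrophic cancellation of
    # E[x^2] - E[x]^2 on large counts
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, s0 / w0, 0.0)
        mu1 = np.where(w1 > 0, s1 / w1, 0.0)
    between = w0 * w1 * (mu0 - mu1) ** 2
    between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(between))  # argmax takes the first (lowest) level on ties


def otsu_auto_threshold(img: np.ndarray, max_value: int = 255,
                        object_type: str = "light") -> ThresholdResult:
    """Threshold a grayscale image with Otsu's method (bimodal histograms).

    The split assigns level ``t`` itself to the dark class, so the dark
    mask is ``img <= t`` while the light mask is ``img > t``.
    """
    img = _check_gray(img)
    hist = histogram256(img)
    t = otsu_threshold_from_hist(hist)
    if object_type == "dark":
        mask = ((img <= t) * np.uint8(max_value)).astype(np.uint8)
    else:
        mask = _apply(img, t, object_type, max_value)
    return ThresholdResult(mask=mask, threshold_value=t, histogram=hist)


def adaptive_threshold(img: np.ndarray, method: str = "mean",
                       block_size: int = 11, offset: float = 0.0,
                       object_type: str = "light",
                       max_value: int = 255) -> np.ndarray:
    """Per-pixel threshold from the block_size x block_size neighbourhood.

    ``method='mean'`` uses the plain neighbourhood mean; ``'gaussian'`` a
    Gaussian-weighted mean. The local threshold is that statistic minus
    *offset*; edges are replicate-padded. ``block_size`` has no sensible
    universal default — it must match the object scale.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 3, got {block_size}")
    img = _check_gray(img)
    f = img.astype(np.float64)
    if method == "mean":
        local = ndimage.uniform_filter(f, size=block_size, mode="nearest")
    elif method == "gaussian":
        sigma = 0.3 * ((block_size - 1) * 0.5 - 1) + 0.8
        x = np.arange(block_size) - (block_size - 1) / 2.0
        g = np.exp(-(x**2) / (2 * sigma**2))
        g /= g.sum()
        local = ndimage.correlate1d(f, g, axis=0, mode="nearest")
        local = ndimage.correlate1d(local, g, axis=1, mode="nearest")
    else:
        raise ValueError("method must be 'mean' or 'gaussian'")
    return _apply_local(f, local - offset, object_type, max_value)


def _apply_local(img: np.ndarray, thresh: np.ndarray, object_type: str,
                 max_value: int) -> np.ndarray:
    if object_type == "light":
        sel = img > thresh
    elif object_type == "dark":
        sel = img < thresh
    else:
        raise ValueError("object_type must be 'light' or 'dark'")
    return (sel * np.uint8(max_value)).astype(np.uint8)


def binary_threshold(img: np.ndarray, value: float,
                     object_type: str = "light",
                     max_value: int = 255) -> np.ndarray:
    """Fixed-value threshold — the baseline the automatic methods replace."""
    if not 0 <= value <= 255:
        raise ValueError("threshold value must lie in [0, 255]")
    return _apply(_check_gray(img), value, object_type, max_value)
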