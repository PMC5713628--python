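"""Illumination normalization, smoothing and geometric adjustment.

These steps precede segmentation so that one pipeline (one threshold, one
region layout) generalizes across images taken under drifting greenhouse
light or from slightly misaligned trays. The VIS->NIR helpers transfer a
plant mask derived from the visible-light image onto the matching
low-contrast near-infrared image of the same pot.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgcore import as_mask

__all__ = [
    "ROI",
    "white_balance",
    "median_blur",
    "gaussian_blur",
    "rotate_img",
    "shift_img",
    "resize",
    "crop_position_mask",
    "get_nir",
]


@dataclass
class ROI:
    """Axis-aligned rectangular region of interest, (x, y) top-left corner."""

    x: int
    y: int
    w: int
    h: int

    def validate(self, shape: tuple[int, int]) -> None:
        H, W = shape[:2]
        if self.w < 1 or self.h < 1:
            raise ValueError("ROI must have positive width and height")
        if self.x < 0 or self.y < 0 or self.x + self.w > W or self.y + self.h > H:
            raise ValueError(f"ROI {self} not fully inside image of shape {(H, W)}")

    def slice(self) -> tuple[slice, slice]:
        return slice(self.y, self.y + self.h), slice(self.x, self.x + self.w)


def white_balance(img: np.ndarray, roi: ROI | None = None,
                  percentile: float = 100.0) -> np.ndarray:
    """Scale each channel so its reference maximum inside *roi* maps to 255.

    The reference statistic is the channel maximum over the ROI (the whole
    image when no ROI is given). A white color standard placed in the ROI
    therefore becomes pure white and the rest of the image is scaled
    linearly with it. ``percentile`` (default 100 = literal maximum) lets a
    caller ignore isolated hot pixels.
    """
    img = np.asarray(img)
    if img.ndim == 2:
        channels = img[:, :, None]
    elif img.ndim == 3 and img.shape[2] == 3:
        channels = img
    else:
        raise ValueError("white_balance expects a 1- or 3-channel image")
    if roi is not None:
        roi.validate(img.shape)
        ys, xs = roi.slice()
        ref = channels[ys, xs]
    else:
        ref = channels

    out = np.empty_like(channels, dtype=np.uint8)
    for c in range(channels.shape[2]):
        m = float(np.percentile(ref[:, :, c], percentile))
        if m <= 0:
            raise ValueError(f"channel {c}: ROI maximum is 0, cannot scale")
        out[:, :, c] = np.clip(np.rint(channels[:, :, c] * (255.0 / m)), 0, 255)
    return out[:, :, 0] if img.ndim == 2 else out


def median_blur(img: np.ndarray, ksize: int) -> np.ndarray:
    """Median filter with a ksize x ksize window (edge-replicated).

    Removes salt-and-pepper noise that survives thresholding as speckles.
    """
    if ksize < 1 or ksize % 2 == 0:
        raise ValueError(f"ksize must be an odd integer >= 1, got {ksize}")
    img = np.asarray(img)
    if ksize == 1:
        return img.copy()
    if img.ndim == 3:
        size = (ksize, ksize, 1)
    else:
        size = ksize
    return ndimage.median_filter(img, size=size, mode="nearest")


def _gaussian_kernel1d(ksize: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        # same default scale rule as the common imaging-library convention
        sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_blur(img: np.ndarray, ksize: tuple[int, int] = (3, 3),
                  sigma_x: float = 0.0, sigma_y: float = 0.0) -> np.ndarray:
    """Convolve with a normalized sampled-Gaussian kernel (odd dimensions).

    The kernel is the outer product of two normalized 1-D Gaussians, so the
    total intensity of an interior impulse is conserved up to rounding.
    """
    kx, ky = int(ksize[0]), int(ksize[1])
    if kx < 1 or ky < 1 or kx % 2 == 0 or ky % 2 == 0:
        raise ValueError(f"kernel dimensions must be odd, got {ksize}")
    img = np.asarray(img)
    gx = _gaussian_kernel1d(kx, sigma_x)
    gy = _gaussian_kernel1d(ky, sigma_y if sigma_y > 0 else sigma_x)
    kernel = np.outer(gy, gx)

    def _one(channel: np.ndarray) -> np.ndarray:
        out = ndimage.convolve(channel.astype(np.float64), kernel, mode="nearest")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)

    if img.ndim == 3:
        return np.dstack([_one(img[:, :, c]) for c in range(img.shape[2])])
    return _one(img)


def _is_binary(img: np.ndarray) -> bool:
    return img.ndim == 2 and np.isin(np.unique(img), (0, 255)).all()


def rotate_img(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the image center, keeping the canvas size.

    Positive angles rotate counterclockwise in display orientation.
    Vacated regions are zero-filled. Binary masks are resampled
    nearest-neighbour so they stay strictly {0, 255}; intensity images use
    bilinear interpolation.
    """
    img = np.asarray(img)
    order = 0 if _is_binary(img) else 1
    out = ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=order,
                         mode="constant", cval=0, prefilter=False)
    return np.clip(out, 0, 255).astype(np.uint8)


def shift_img(img: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate by integer (dx, dy) pixels; vacated region is zero-filled."""
    img = np.asarray(img)
    H, W = img.shape[:2]
    dx, dy = int(dx), int(dy)
    if abs(dx) >= W or abs(dy) >= H:
        raise ValueError(f"shift ({dx}, {dy}) moves the whole {W}x{H} frame out")
    out = np.zeros_like(img)
    src_y = slice(max(0, -dy), min(H, H - dy))
    src_x = slice(max(0, -dx), min(W, W - dx))
    dst_y = slice(max(0, dy), min(H, H + dy))
    dst_x = slice(max(0, dx), min(W, W + dx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out


def resize(mask: np.ndarray, fx: float, fy: float) -> np.ndarray:
    """Rescale a binary mask by (fx, fy) with nearest-neighbour sampling.

    Used to bring a VIS-derived plant mask to the pixel scale of the NIR
    camera; the factors come from measuring a common reference object in
    one image from each camera.
    """
    if fx <= 0 or fy <= 0:
        raise ValueError("resize factors must be positive")
    mask = as_mask(mask)
    H, W = mask.shape
    out_h, out_w = max(1, round(H * fy)), max(1, round(W * fx))
    rows = np.clip(((np.arange(out_h) + 0.5) / fy - 0.5).round().astype(int), 0, H - 1)
    cols = np.clip(((np.arange(out_w) + 0.5) / fx - 0.5).round().astype(int), 0, W - 1)
    return mask[np.ix_(rows, cols)]


def crop_position_mask(nir_img: np.ndarray, mask: np.ndarray,
                       x_offset: int = 0, y_offset: int = 0,
                       v_pos: str = "top", h_pos: str = "left") -> np.ndarray:
    """Place *mask* over the NIR frame and crop/pad to the NIR dimensions.

    The mask is anchored to the stated corner sides (``v_pos`` in
    {top, bottom}, ``h_pos`` in {left, right}) and pushed inward by the
    nonnegative offsets; anything falling outside the NIR frame is cropped
    and uncovered pixels are background.
    """
    if x_offset < 0 or y_offset < 0:
        raise ValueError("offsets must be nonnegative")
    if v_pos not in ("top", "bottom") or h_pos not in ("left", "right"):
        raise ValueError("v_pos must be top/bottom and h_pos left/right")
    mask = as_mask(mask)
    nir = np.asarray(nir_img)
    Ht, Wt = nir.shape[:2]
    Hm, Wm = mask.shape

    top = y_offset if v_pos == "top" else Ht - y_offset - Hm
    left = x_offset if h_pos == "left" else Wt - x_offset - Wm

    out = np.zeros((Ht, Wt), dtype=np.uint8)
    dst_y0, dst_y1 = max(0, top), min(Ht, top + Hm)
    dst_x0, dst_x1 = max(0, left), min(Wt, left + Wm)
    if dst_y0 >= dst_y1 or dst_x0 >= dst_x1:
        raise ValueError("mask placed entirely outside the NIR frame")
    out[dst_y0:dst_y1, dst_x0:dst_x1] = mask[dst_y0 - top:dst_y1 - top,
                                             dst_x0 - left:dst_x1 - left]
    return out


def get_nir(vis_path: str, naming_rule: tuple[str, str] = ("VIS", "NIR")) -> str:
    """Locate the NIR sibling of a VIS image by filename substitution.

    ``naming_rule`` is an (old, new) substring pair applied to the basename;
    the matching image must live in the same directory.
    """
    old, new = naming_rule
    directory, name = os.path.split(vis_path)
    if old not in name:
        raise ValueError(f"naming rule {old!r}->{new!r} does not match {name!r}")
    nir_path = os.path.join(directory, name.replace(old, new, 1))
    if not os.path.exists(nir_path):
        raise IOError(f"matching NIR image not found: {nir_path}")
    return nir_path
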