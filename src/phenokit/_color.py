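"""RGB<->HSV conversion on the full-byte [0, 255] scale.

Hue is scaled to the full byte range (not the half-range 0-179 convention
some imaging libraries use); all three HSV channels therefore share the
same 256-bin discretization used by the classifier densities.
"""

from __future__ import annotations

import numpy as np


def rgb_to_hsv255(rgb: np.ndarray) -> np.ndarray:
    """uint8 RGB (..., 3) -> uint8 HSV (..., 3), each channel in [0, 255]."""
    from skimage.color import rgb2hsv

    rgb = np.asarray(rgb, dtype=np.uint8)
    flat = rgb.reshape(-1, 1, 3)
    hsv = rgb2hsv(flat)  # floats in [0, 1]
    out = np.rint(hsv * 255.0).clip(0, 255).astype(np.uint8)
    return out.reshape(rgb.shape)


def hsv255_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """uint8 HSV (..., 3) on the [0, 255] scale -> uint8 RGB (..., 3)."""
    from skimage.color import hsv2rgb

    hsv = np.asarray(hsv, dtype=np.float64) / 255.0
    flat = hsv.reshape(-1, 1, 3)
    rgb = hsv2rgb(flat)
    out = np.rint(rgb * 255.0).clip(0, 255).astype(np.uint8)
    return out.reshape(hsv.shape)
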