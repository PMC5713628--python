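"""Size-marker area reporting for cross-image scale normalization.

A size marker is an in-frame reference object of fixed physical size (a
colored sticker, a pot rim). Reporting its pixel area per image lets the
analyst divide plant areas by marker areas downstream, cancelling zoom or
camera-distance differences between images. The division itself is left to
the analysis step, not hidden here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._color import rgb_to_hsv255
from .imgcore import STRUCT8, as_gray
from .preprocess import ROI
from . import threshold as _th

__all__ = ["MarkerReport", "report_size_marker_area"]


@dataclass
class MarkerReport:
    """Marker pixel area and centroid (image coordinates), with the mode used."""

    area: int
    centroid: tuple[float, float]
    mode: str


def _extract_channel(img: np.ndarray, channel: str) -> np.ndarray:
    img = np.asarray(img)
    if channel == "gray":
        return as_gray(img)
    if img.ndim != 3:
        raise ValueError(f"channel {channel!r} requires an RGB image")
    if channel in ("r", "g", "b"):
        return img[:, :, "rgb".index(channel)]
    if channel in ("h", "s", "v"):
        return rgb_to_hsv255(img)[:, :, "hsv".index(channel)]
    raise ValueError(f"unknown channel {channel!r}")


def report_size_marker_area(img: np.ndarray, roi: ROI, mode: str = "detect",
                            channel: str = "gray",
                            threshold_method: str = "otsu",
                            threshold_value: float | None = None,
                            object_type: str = "dark") -> MarkerReport:
    """Measure the size marker inside *roi*.

    ``mode='define'`` treats the whole ROI as the marker (its area is the
    ROI pixel count). ``mode='detect'`` thresholds the chosen channel
    within the ROI and reports the largest detected object, which tolerates
    marker movement within the ROI and ignores small specks.
    """
    img = np.asarray(img)
    roi.validate(img.shape)
    if mode == "define":
        return MarkerReport(area=roi.w * roi.h,
                            centroid=(roi.x + (roi.w - 1) / 2.0,
                                      roi.y + (roi.h - 1) / 2.0),
                            mode=mode)
    if mode != "detect":
        raise ValueError("mode must be 'detect' or 'define'")

    chan = _extract_channel(img, channel)
    ys, xs = roi.slice()
    sub = chan[ys, xs]
    if threshold_method == "binary":
        if threshold_value is None:
            raise ValueError("binary threshold_method requires threshold_value")
        mask = _th.binary_threshold(sub, threshold_value, object_type)
    elif threshold_method == "otsu":
        mask = _th.otsu_auto_threshold(sub, object_type=object_type).mask
    elif threshold_method == "triangle":
        mask = _th.triangle_auto_threshold(sub, object_type=object_type).mask
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")

    labels, n = ndimage.label(mask > 0, structure=STRUCT8)
    if n == 0:
        raise ValueError("no marker object detected inside the ROI")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.argmax(areas)) + 1
    rr, cc = np.nonzero(labels == best)
    return MarkerReport(area=int(areas[best - 1]),
                        centroid=(float(cc.mean()) + roi.x,
                                  float(rr.mean()) + roi.y),
                        mode=mode)
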