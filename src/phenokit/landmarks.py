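"""Landmark morphometrics: acute (Type II) and axis pseudo- (Type III) points.

Type II landmarks are curvature extrema found from the object contour: at
each contour point the angle between chords to the two points *window*
steps away is scored, runs of points below an angle threshold form acute
regions, and each region's middle point is the landmark. Convex regions
(leaf tips) and concave ones (axils between leaves) are told apart by the
mean mask value inside the region's convex hull (``pt_vals``: high = tip,
low = axil).

Type III (pseudo-)landmarks place an equal number of constructed points on
every object: the object extent along one axis is cut into twenty
equidistant bins and each bin contributes its minimum extent, maximum
extent and centroid — sixty points per axis, comparable across plants even
without true anatomical homology. Landmark tables can be exported as
tab-delimited text for downstream morphometrics software, or rescaled to a
common unit frame first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgcore import Contour, as_mask

__all__ = [
    "LandmarkSet",
    "angle_profile",
    "acute",
    "acute_vertex",
    "x_axis_pseudolandmarks",
    "y_axis_pseudolandmarks",
    "scale_features",
    "landmark_reference_pt_dist",
    "write_landmark_table",
]


@dataclass
class LandmarkSet:
    """Ordered landmark points with role labels and optional hull values."""

    points: np.ndarray  # (N, 2) float (x, y)
    roles: list[str]
    pt_vals: np.ndarray | None = None  # mean mask value per point, acute only

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if len(self.roles) != len(self.points):
            raise ValueError("roles and points length mismatch")

    def __len__(self) -> int:
        return len(self.points)


def angle_profile(contour: Contour, window: int) -> np.ndarray:
    """Chord angle (degrees, [0, 180]) at every contour point.

    At point ``p_i`` the angle is between the vectors to ``p_{i-window}``
    and ``p_{i+window}`` (ring indices wrap), computed by the law of
    cosines and clamped to [0, 180]. Duplicate points (zero-length chords)
    score 180 (no bend). The profile is symmetric under traversal
    reversal.
    """
    pts = contour.points.astype(np.float64)
    n = len(pts)
    if not 1 <= window < n / 2:
        raise ValueError(f"window must satisfy 1 <= window < n/2 (n={n})")
    prev = np.roll(pts, window, axis=0) - pts
    nxt = np.roll(pts, -window, axis=0) - pts
    n1 = np.linalg.norm(prev, axis=1)
    n2 = np.linalg.norm(nxt, axis=1)
    degenerate = (n1 == 0) | (n2 == 0)
    n1[degenerate] = n2[degenerate] = 1.0
    cosang = np.clip((prev * nxt).sum(axis=1) / (n1 * n2), -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    ang[degenerate] = 180.0
    return ang


def _circular_runs(below: np.ndarray) -> list[np.ndarray]:
    """Indices of maximal runs of True, wrapping across the ring seam."""
    n = len(below)
    if below.all():
        return [np.arange(n)]
    if not below.any():
        return []
    # rotate so the sequence starts on a False, making runs non-wrapping
    start = int(np.argmin(below))
    rolled = np.roll(below, -start)
    runs = []
    i = 0
    while i < n:
        if rolled[i]:
            j = i
            while j < n and rolled[j]:
                j += 1
            runs.append((np.arange(i, j) + start) % n)
            i = j
        else:
            i += 1
    return runs


def _hull_mean(mask: np.ndarray, pts: np.ndarray) -> float:
    """Mean mask value inside the convex hull of the (x, y) points."""
    uniq = np.unique(pts, axis=0)
    if len(uniq) < 3:
        return float(mask[pts[:, 1].astype(int), pts[:, 0].astype(int)].mean())
    from scipy.spatial import ConvexHull, QhullError
    from skimage.draw import polygon

    try:
        hull = ConvexHull(uniq.astype(float))
    except QhullError:  # collinear points
        return float(mask[pts[:, 1].astype(int), pts[:, 0].astype(int)].mean())
    verts = uniq[hull.vertices]
    rr, cc = polygon(verts[:, 1], verts[:, 0], shape=mask.shape)
    if len(rr) == 0:
        return float(mask[pts[:, 1].astype(int), pts[:, 0].astype(int)].mean())
    return float(mask[rr, cc].mean())


def _runs_to_landmarks(contour: Contour, runs: list[np.ndarray],
                       mask: np.ndarray | None, window: int = 0) -> LandmarkSet:
    pts = contour.points
    n = len(pts)
    mids, vals = [], []
    for run in runs:
        mid = run[len(run) // 2]
        mids.append(pts[mid])
        if mask is not None:
            # the hull spans the acute region out to its chord endpoints,
            # so a concave notch encloses background (low mean) while a
            # convex tip encloses object (high mean)
            region = np.concatenate([run, [(run[0] - window) % n,
                                           (run[-1] + window) % n]])
            vals.append(_hull_mean(mask, pts[region]))
    points = np.array(mids, dtype=np.float64).reshape(-1, 2)
    return LandmarkSet(points=points, roles=["acute"] * len(points),
                       pt_vals=np.array(vals) if mask is not None else None)


def acute(img: np.ndarray, mask: np.ndarray, contour: Contour,
          window: int, angle_threshold: float) -> LandmarkSet:
    """Type II landmarks: middles of contour runs with angle < threshold.

    Runs wrap across the ring seam, so an acute region spanning the
    traversal start is one landmark. ``pt_vals`` carries the mean mask
    value inside each run's convex hull to separate convex tips
    (near 255) from concave axils (near 0).
    """
    mask = as_mask(mask)
    prof = angle_profile(contour, window)
    runs = _circular_runs(prof < angle_threshold)
    return _runs_to_landmarks(contour, runs, mask, window)


def acute_vertex(img: np.ndarray, contour: Contour, window: int,
                 angle_threshold: float, search_stride: int = 1) -> LandmarkSet:
    """Strided variant of :func:`acute` trading resolution for speed.

    Angles are evaluated only at every ``search_stride``-th contour point
    before run detection; stride 1 reproduces :func:`acute`'s point set
    exactly (no hull values, since no mask is consulted).
    """
    n = len(contour)
    if search_stride < 1 or search_stride > n:
        raise ValueError(f"search_stride must lie in [1, contour length={n}]")
    prof = angle_profile(contour, window)
    sampled = np.arange(0, n, search_stride)
    below = prof[sampled] < angle_threshold
    runs = [sampled[r] for r in _circular_runs(below)]
    return _runs_to_landmarks(contour, runs, None)


def _axis_pseudolandmarks(mask: np.ndarray, axis: str) -> LandmarkSet:
    mask = as_mask(mask)
    fg = mask > 0
    if not fg.any():
        raise ValueError("mask is empty")
    ys, xs = np.nonzero(fg)
    along = xs if axis == "x" else ys      # binned coordinate
    across = ys if axis == "x" else xs     # extent coordinate
    lo, hi = int(along.min()), int(along.max())
    if hi - lo + 1 < 20:
        raise ValueError("object spans fewer than 20 pixels along the axis")
    edges = np.linspace(lo, hi + 1, 21)
    mins, maxs, centers = [], [], []
    for b in range(20):
        sel = (along >= edges[b]) & (along < edges[b + 1])
        if not sel.any():
            raise ValueError(f"bin {b} along the {axis}-axis holds no pixels")
        a, c = along[sel], across[sel]
        cmin, cmax = c.min(), c.max()
        mins.append((a[c == cmin].mean(), float(cmin)))
        maxs.append((a[c == cmax].mean(), float(cmax)))
        centers.append((a.mean(), c.mean()))

    def _xy(pairs):
        arr = np.array(pairs, dtype=np.float64)
        return arr if axis == "x" else arr[:, ::-1]

    if axis == "x":
        roles = ["x_top"] * 20 + ["x_bottom"] * 20 + ["x_center"] * 20
    else:
        roles = ["y_left"] * 20 + ["y_right"] * 20 + ["y_center"] * 20
    points = np.vstack([_xy(mins), _xy(maxs), _xy(centers)])
    return LandmarkSet(points=points, roles=roles)


def x_axis_pseudolandmarks(img: np.ndarray, mask: np.ndarray,
                           contour: Contour | None = None) -> LandmarkSet:
    """60 Type III landmarks from 20 equidistant bins along the x-axis.

    Per bin: the point of minimum y extent (top), maximum y extent
    (bottom) and the bin's foreground centroid. Bin edges are half-open
    [left, right) with the last bin closed, so each column belongs to
    exactly one bin.
    """
    return _axis_pseudolandmarks(mask, "x")


def y_axis_pseudolandmarks(img: np.ndarray, mask: np.ndarray,
                           contour: Contour | None = None) -> LandmarkSet:
    """Symmetric y-axis scan: per-bin left extent, right extent, centroid."""
    return _axis_pseudolandmarks(mask, "y")


def plant_base_point(mask: np.ndarray, bottom_frac: float = 0.05) -> tuple[float, float]:
    """Reference point at the plant base: centroid of the lowest mask rows.

    The bottom ``bottom_frac`` of the object's row span (default 5%)
    approximates where the shoot meets the soil in side-view images.
    """
    fg = as_mask(mask) > 0
    ys, xs = np.nonzero(fg)
    cutoff = ys.max() - max(1, round((ys.max() - ys.min() + 1) * bottom_frac)) + 1
    sel = ys >= cutoff
    return float(xs[sel].mean()), float(ys[sel].mean())


def scale_features(points: LandmarkSet, mask: np.ndarray,
                   centroid: tuple[float, float],
                   baseline: tuple[float, float]
                   ) -> tuple[LandmarkSet, tuple[float, float], tuple[float, float]]:
    """Rescale landmarks, centroid and base point to the unit square.

    The affine map sends the object's bounding box corners to (0, 0) and
    (1, 1); ratios of distances along each axis are preserved, making
    feature tables comparable across plants of different sizes.
    """
    fg = as_mask(mask) > 0
    if not fg.any():
        raise ValueError("mask is empty")
    ys, xs = np.nonzero(fg)
    x0, x1 = float(xs.min()), float(xs.max())
    y0, y1 = float(ys.min()), float(ys.max())
    if x1 == x0 or y1 == y0:
        raise ValueError("degenerate bounding box (zero width or height)")

    def _map(p: np.ndarray) -> np.ndarray:
        p = np.asarray(p, dtype=np.float64)
        return np.stack([(p[..., 0] - x0) / (x1 - x0),
                         (p[..., 1] - y0) / (y1 - y0)], axis=-1)

    scaled = LandmarkSet(points=_map(points.points), roles=list(points.roles),
                         pt_vals=None if points.pt_vals is None
                         else points.pt_vals.copy())
    return scaled, tuple(_map(np.array(centroid))), tuple(_map(np.array(baseline)))


def landmark_reference_pt_dist(points: LandmarkSet,
                               centroid: tuple[float, float],
                               baseline: tuple[float, float]) -> pd.DataFrame:
    """Per-landmark displacement features relative to two reference points.

    For each landmark and each reference (object centroid; plant-base
    point) the table holds the horizontal and vertical offsets, Euclidean
    distance and angle (degrees, ``atan2(dy, dx)``). All inputs must share
    one (typically unit-rescaled) coordinate frame.
    """
    rows = []
    for ref_name, ref in (("centroid", centroid), ("baseline", baseline)):
        for (x, y), role in zip(points.points, points.roles):
            dx, dy = x - ref[0], y - ref[1]
            rows.append({
                "role": role, "x": x, "y": y, "ref": ref_name,
                "dx": dx, "dy": dy,
                "dist": float(np.hypot(dx, dy)),
                "angle_deg": float(np.degrees(np.arctan2(dy, dx))),
            })
    columns = ["role", "x", "y", "ref", "dx", "dy", "dist", "angle_deg"]
    return pd.DataFrame(rows, columns=columns)


def write_landmark_table(points: LandmarkSet, path: str) -> None:
    """Export landmarks as tab-delimited text (role, x, y, pt_val)."""
    vals = points.pt_vals if points.pt_vals is not None else [""] * len(points)
    df = pd.DataFrame({
        "role": points.roles,
        "x": points.points[:, 0],
        "y": points.points[:, 1],
        "pt_val": vals,
    })
    df.to_csv(path, sep="\t", index=False)
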