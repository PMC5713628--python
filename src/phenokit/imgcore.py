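"""Core raster, mask and contour primitives.

Conventions shared by every phenokit module:

* coordinates are 0-based ``(x, y) = (column, row)`` with the origin at the
  top-left pixel;
* images are 8-bit ``numpy`` arrays, shape ``(H, W)`` (grayscale) or
  ``(H, W, 3)`` in RGB channel order — any on-disk BGR ordering is hidden at
  read time;
* binary masks are single-channel arrays containing only ``{0, 255}``;
* foreground connectivity is 8-connected (background 4-connected), so thin
  diagonal petioles stay part of one plant object.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "Contour",
    "ShapeSummary",
    "read_image",
    "write_image",
    "find_objects",
    "shape_summary",
    "output_mask",
    "as_gray",
    "as_mask",
    "fill_contour",
]

#: 8-connectivity structuring element for foreground component labelling.
STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Contour:
    """Closed ring of 8-connected pixel coordinates outlining one object.

    ``points`` is an ``(N, 2)`` integer array of ``(x, y)`` coordinates in
    traversal order; the successor of the last point is the first point.
    Holes inside the object are recorded as child contours.
    """

    points: np.ndarray
    is_hole: bool = False
    children: list["Contour"] = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass
class ShapeSummary:
    """Minimal per-object shape record: area, centroid, bbox, convex hull."""

    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max)
    hull: Contour


def _check_uint8(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer) or np.issubdtype(arr.dtype, np.floating):
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        else:
            raise TypeError(f"unsupported image dtype {arr.dtype}")
    return arr


def as_gray(img: np.ndarray) -> np.ndarray:
    """Return *img* as a single-channel uint8 array (luma conversion if RGB)."""
    img = _check_uint8(img)
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] == 3:
        w = np.array([0.299, 0.587, 0.114])
        return np.rint(img @ w).clip(0, 255).astype(np.uint8)
    raise ValueError(f"expected HxW or HxWx3 image, got shape {img.shape}")


def as_mask(mask: np.ndarray) -> np.ndarray:
    """Validate a binary mask: single channel, values a subset of {0, 255}."""
    mask = _check_uint8(mask)
    if mask.ndim != 2:
        raise ValueError("binary mask must be single-channel")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"mask contains values other than {{0,255}}: {vals[:10]}")
    return mask


def read_image(path: str) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file into an RGB (or grayscale) uint8 array.

    Channel order is always RGB regardless of on-disk convention; palette
    and RGBA files are converted, grayscale files stay single-channel.
    """
    if not os.path.exists(path):
        raise IOError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                im = im.convert("L")
            elif im.mode != "RGB":
                im = im.convert("RGB")
            arr = np.asarray(im)
    except Exception as exc:  # Pillow raises various decode errors
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    return _check_uint8(arr)


def write_image(img: np.ndarray, path: str) -> None:
    """Write an image; PNG/TIFF round-trip bit-exactly, JPEG is lossy."""
    img = _check_uint8(np.asarray(img))
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"output directory does not exist: {parent}")
    mode = "L" if img.ndim == 2 else "RGB"
    Image.fromarray(img, mode=mode).save(path)


# ---------------------------------------------------------------------------
# Contour tracing (Moore boundary following with Jacob's stopping criterion)
# ---------------------------------------------------------------------------

# Clockwise Moore neighbourhood in (row, col) offsets, starting due west.
_RING = np.array(
    [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)],
    dtype=np.int64,
)
_RING_INDEX = {tuple(off): i for i, off in enumerate(_RING)}


def _trace_boundary(fg: np.ndarray) -> np.ndarray:
    """Trace the outer boundary of the True region in *fg* (one component).

    Returns an (N, 2) array of (row, col) points in clockwise order. The
    start pixel is the topmost-leftmost foreground pixel, whose west
    neighbour is guaranteed background.
    """
    pad = np.zeros((fg.shape[0] + 2, fg.shape[1] + 2), dtype=bool)
    pad[1:-1, 1:-1] = fg
    rows, cols = np.nonzero(pad)
    start = (int(rows[0]), int(cols[0]))  # nonzero is row-major ordered

    boundary = [start]
    cur = start
    prev = (start[0], start[1] - 1)  # west backtrack: background by scan order
    first_move = None
    while True:
        k0 = _RING_INDEX[(prev[0] - cur[0], prev[1] - cur[1])]
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (cur[0] + int(_RING[k, 0]), cur[1] + int(_RING[k, 1]))
            if pad[cand]:
                nxt = cand
                prev = (cur[0] + int(_RING[(k - 1) % 8, 0]),
                        cur[1] + int(_RING[(k - 1) % 8, 1]))
                break
        if nxt is None:  # isolated single pixel
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            break
        boundary.append(nxt)
        cur = nxt
    pts = np.array(boundary, dtype=np.int64) - 1  # undo padding
    # drop the duplicated closing point(s) at the end if the trace re-entered
    while len(pts) > 1 and (pts[-1] == pts[0]).all():
        pts = pts[:-1]
    return pts


def _rc_to_contour(pts_rc: np.ndarray, is_hole: bool = False) -> Contour:
    return Contour(points=pts_rc[:, ::-1].copy(), is_hole=is_hole)


def find_objects(img: np.ndarray, mask: np.ndarray) -> list[Contour]:
    """Extract one external contour per 8-connected foreground component.

    Holes (background regions fully enclosed by a component) are traced and
    attached as ``children`` of their parent contour. An empty mask yields
    an empty list.
    """
    mask = as_mask(mask)
    img = np.asarray(img)
    if img.shape[:2] != mask.shape:
        raise ValueError(
            f"image {img.shape[:2]} and mask {mask.shape} dimensions differ"
        )
    fg = mask > 0
    labels, n = ndimage.label(fg, structure=STRUCT8)
    contours: list[Contour] = []
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        comp = labels[sl] == i
        outer = _trace_boundary(comp)
        outer[:, 0] += sl[0].start
        outer[:, 1] += sl[1].start
        contour = _rc_to_contour(outer)
        holes = ndimage.binary_fill_holes(comp) & ~comp
        if holes.any():
            hlabels, hn = ndimage.label(holes)  # 4-connected background
            for j in range(1, hn + 1):
                hpts = _trace_boundary(hlabels == j)
                hpts[:, 0] += sl[0].start
                hpts[:, 1] += sl[1].start
                contour.children.append(_rc_to_contour(hpts, is_hole=True))
        contours.append(contour)
    return contours


def fill_contour(contour: Contour, shape: tuple[int, int],
                 subtract_holes: bool = True) -> np.ndarray:
    """Rasterize the region enclosed by *contour* onto an (H, W) bool grid.

    The ring pixels are drawn and interior filled; child hole regions are
    carved out when *subtract_holes* is set.
    """
    grid = np.zeros(shape, dtype=bool)
    pts = contour.points
    grid[pts[:, 1], pts[:, 0]] = True
    filled = ndimage.binary_fill_holes(grid)
    if subtract_holes:
        for child in contour.children:
            hole = np.zeros(shape, dtype=bool)
            hole[child.points[:, 1], child.points[:, 0]] = True
            hole = ndimage.binary_fill_holes(hole)
            filled &= ~(hole & ~grid)  # keep the shared boundary ring
    return filled


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0].astype(float), points[:, 1].astype(float)
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def shape_summary(contour: Contour, shape: tuple[int, int] | None = None) -> ShapeSummary:
    """Area (enclosed pixel count), centroid, bounding box and convex hull.

    Raises on degenerate (collinear / single-pixel-wide) contours, which
    enclose no area.
    """
    pts = contour.points
    if len(pts) < 3:
        raise ValueError("contour must have at least 3 points")
    if _shoelace(pts) < 1.0:
        raise ValueError("degenerate contour encloses no area")
    if shape is None:
        shape = (int(pts[:, 1].max()) + 1, int(pts[:, 0].max()) + 1)
    region = fill_contour(contour, shape, subtract_holes=False)
    area = int(region.sum())
    ys, xs = np.nonzero(region)
    centroid = (float(xs.mean()), float(ys.mean()))
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max()))

    from skimage.morphology import convex_hull_image  # heavier import, lazy

    hull_region = convex_hull_image(region)
    hull_pts = _trace_boundary(hull_region)
    hull = _rc_to_contour(hull_pts)
    return ShapeSummary(area=area, centroid=centroid, bbox=bbox, hull=hull)


def output_mask(img: np.ndarray, mask: np.ndarray, out_dir: str,
                basename: str = "sample") -> tuple[str, str]:
    """Write an image/mask pair as one training example with matched names.

    Produces ``<basename>.png`` and ``<basename>_mask.png`` in *out_dir* —
    the format consumed by two-class classifier training.
    """
    img = _check_uint8(np.asarray(img))
    mask = as_mask(mask)
    if img.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    os.makedirs(out_dir, exist_ok=True)
    img_path = os.path.join(out_dir, f"{basename}.png")
    mask_path = os.path.join(out_dir, f"{basename}_mask.png")
    write_image(img, img_path)
    write_image(mask, mask_path)
    return img_path, mask_path
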