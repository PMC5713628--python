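"""Multi-plant tray handling: grid clustering of contours and splitting.

Trays carry many plants in an approximately regular layout. The image is
divided into an nrow x ncol grid of equal cells serving as approximate
per-plant regions; each detected contour is assigned to the cell holding
its centroid, contours sharing a cell are one plant, and each plant can
then be written out as its own image for the standard single-plant
pipeline. Skewed trays should be straightened first with
``preprocess.rotate_img`` / ``shift_img``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _debug
from .imgcore import Contour, fill_contour

__all__ = ["ContourClusterSet", "cluster_contours", "cluster_contour_split_img"]

# fixed qualitative palette for debug coloring of groups
_PALETTE = np.array(
    [(31, 119, 180), (255, 127, 14), (44, 160, 44), (214, 39, 40),
     (148, 103, 189), (140, 86, 75), (227, 119, 194), (127, 127, 127),
     (188, 189, 34), (23, 190, 207)],
    dtype=np.uint8,
)


@dataclass
class ContourClusterSet:
    """Grid assignment of contours: one (possibly empty) group per cell.

    ``groups`` is row-major over cells; each entry lists indices into
    ``contours``. Every input contour appears in exactly one group.
    """

    groups: list[list[int]]
    grid: tuple[int, int]
    row_edges: np.ndarray
    col_edges: np.ndarray
    contours: list[Contour] = field(default_factory=list)
    image_shape: tuple[int, int] = (0, 0)

    def nonempty(self) -> list[tuple[int, int, list[int]]]:
        """(row, col, contour-indices) for every cell that holds an object."""
        nrow, ncol = self.grid
        out = []
        for idx, grp in enumerate(self.groups):
            if grp:
                out.append((idx // ncol, idx % ncol, grp))
        return out


def _contour_centroid(contour: Contour, shape: tuple[int, int]) -> tuple[float, float]:
    region = fill_contour(contour, shape)
    ys, xs = np.nonzero(region)
    if len(xs) == 0:  # degenerate ring: fall back to the ring points
        return float(contour.x.mean()), float(contour.y.mean())
    return float(xs.mean()), float(ys.mean())


def cluster_contours(img: np.ndarray, contours: list[Contour],
                     nrow: int, ncol: int) -> ContourClusterSet:
    """Assign contours to the cells of an nrow x ncol grid over the image.

    Cells are equal-width/equal-height partitions of the full frame; a
    contour belongs to the cell containing its centroid, so leaves
    overhanging a neighbouring cell do not change the assignment. Cells
    may be empty; a fragmented plant (several contours in one cell) forms
    one group.
    """
    if nrow < 1 or ncol < 1:
        raise ValueError("grid must have at least one row and one column")
    img = np.asarray(img)
    H, W = img.shape[:2]
    row_edges = np.linspace(0, H, nrow + 1)
    col_edges = np.linspace(0, W, ncol + 1)
    groups: list[list[int]] = [[] for _ in range(nrow * ncol)]
    for i, contour in enumerate(contours):
        cx, cy = _contour_centroid(contour, (H, W))
        r = min(int(np.searchsorted(row_edges, cy, side="right")) - 1, nrow - 1)
        c = min(int(np.searchsorted(col_edges, cx, side="right")) - 1, ncol - 1)
        groups[r * ncol + c].append(i)
    cs = ContourClusterSet(groups=groups, grid=(nrow, ncol),
                           row_edges=row_edges, col_edges=col_edges,
                           contours=list(contours), image_shape=(H, W))
    _emit_debug(img, cs)
    return cs


def _emit_debug(img: np.ndarray, cs: ContourClusterSet) -> None:
    if _debug._debug_dir is None:
        return
    overlay = img.copy() if img.ndim == 3 else np.dstack([img] * 3)
    for gi, (_, _, grp) in enumerate(cs.nonempty()):
        color = _PALETTE[gi % len(_PALETTE)]
        for ci in grp:
            pts = cs.contours[ci].points
            overlay[pts[:, 1], pts[:, 0]] = color
    _debug.emit("cluster_contours", overlay)


def _group_mask(cs: ContourClusterSet, grp: list[int]) -> np.ndarray:
    m = np.zeros(cs.image_shape, dtype=bool)
    for ci in grp:
        m |= fill_contour(cs.contours[ci], cs.image_shape)
    return m


def cluster_contour_split_img(img: np.ndarray, clusters: ContourClusterSet,
                              names_file: str | None = None,
                              crop: bool = False) -> list[tuple[np.ndarray, str]]:
    """One output image per nonempty group, other pixels blanked to 0.

    Outputs keep the full original canvas (common coordinate frame for
    downstream per-plant pipelines) unless ``crop`` asks for the group
    bounding box. Labels come from *names_file* (one genotype per line,
    row-major grid order); on a count mismatch a warning is raised, extra
    groups fall back to positional ``row_col`` labels and surplus names
    are dropped.
    """
    img = np.asarray(img)
    cells = clusters.nonempty()
    names: list[str] = []
    if names_file is not None:
        try:
            with open(names_file) as fh:
                names = [ln.strip() for ln in fh if ln.strip()]
        except OSError as exc:
            raise IOError(f"cannot read names file {names_file}: {exc}") from exc
        if len(names) != len(cells):
            warnings.warn(
                f"names file lists {len(names)} labels but {len(cells)} plant "
                "groups were found; applying names in row-major order and "
                "labelling the remainder by grid position",
                stacklevel=2,
            )
    out: list[tuple[np.ndarray, str]] = []
    for gi, (r, c, grp) in enumerate(cells):
        label = names[gi] if gi < len(names) else f"{r}_{c}"
        region = _group_mask(clusters, grp)
        split = np.zeros_like(img)
        split[region] = img[region]
        if crop:
            ys, xs = np.nonzero(region)
            split = split[ys.min():ys.max() + 1, xs.min():xs.max() + 1]
        out.append((split, label))
    return out
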