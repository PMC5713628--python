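"""Seeded generator of synthetic plant scenes with complete ground truth.

The generator emulates the image types a shoot-phenotyping toolkit meets in
practice — single rosette plants, multi-plant trays, and class-colored
calibration images — without needing any external dataset. Everything is
drawn from one seeded random generator per scene, so a fixed spec and seed
reproduce byte-identical output.

Rosette geometry
----------------
A rosette is a thin central ring from which tapered petioles radiate to
elliptical leaf blades. The taper (petioles widen from ring to blade) makes
the Euclidean distance map increase monotonically along each petiole into
its blade, so the map has exactly one regional maximum per leaf: the leaf
count is watershed-recoverable *by construction*. Blade centers are spaced
so neighbouring blades never touch; if the requested canvas cannot hold a
separable rosette, generation fails rather than silently producing merged
leaves.

Colors are sampled per pixel from per-class HSV Gaussians (means and
spreads in [0, 255], clipped) and converted to RGB — the noise model every
classifier-recovery test assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from ._color import hsv255_to_rgb
from .bayes import TrainingSampleTable

__all__ = [
    "ClassColor",
    "RosetteSpec",
    "GridLayout",
    "MarkerSpec",
    "SceneSpec",
    "SceneResult",
    "generate_scene",
    "generate_classmap_image",
    "generate_training_table",
    "DEFAULT_PALETTE",
    "WHEAT_RUST_PALETTE",
]


@dataclass(frozen=True)
class ClassColor:
    """Per-class HSV color model: mean and Gaussian spread per channel."""

    hsv_mean: tuple[float, float, float]
    hsv_sigma: tuple[float, float, float]


#: plant vs background palette: green, well-saturated plants over a dull
#: brownish background; hue gap 55/255, comfortably separable.
DEFAULT_PALETTE: dict[str, ClassColor] = {
    "plant": ClassColor((85, 170, 150), (6, 15, 15)),
    "background": ClassColor((30, 60, 70), (5, 12, 10)),
}

#: four-class palette in the style of rust-infected wheat leaves:
#: background, healthy tissue, chlorotic tissue, rust pustules.
WHEAT_RUST_PALETTE: dict[str, ClassColor] = {
    "background": ClassColor((20, 40, 60), (5, 12, 10)),
    "healthy": ClassColor((85, 180, 140), (6, 15, 15)),
    "chlorotic": ClassColor((42, 200, 200), (5, 12, 12)),
    "pustule": ClassColor((10, 220, 120), (4, 12, 12)),
}


@dataclass(frozen=True)
class RosetteSpec:
    """Rosette plant model (all lengths in pixels)."""

    leaf_count: int = 8
    leaf_length: int = 24
    leaf_width: int = 12
    petiole_width: int = 7        # width where the petiole meets the blade
    ring_radius: int = 10         # thin central ring the petioles start from
    angle_jitter_deg: float = 3.0
    radius_jitter: float = 2.0


@dataclass(frozen=True)
class GridLayout:
    """Tray layout: one rosette per cell of an nrow x ncol grid."""

    nrow: int
    ncol: int
    jitter: int = 3               # max |offset| of each plant from cell center


@dataclass(frozen=True)
class MarkerSpec:
    """Optional size-marker disk stamped into the scene."""

    radius: int
    center: tuple[int, int]       # (x, y)
    color: ClassColor = ClassColor((150, 200, 40), (4, 10, 8))


@dataclass(frozen=True)
class SceneSpec:
    canvas: tuple[int, int] = (128, 128)          # (H, W)
    layout: GridLayout | None = None              # None = single plant
    rosette: RosetteSpec = field(default_factory=RosetteSpec)
    palette: dict[str, ClassColor] = field(
        default_factory=lambda: dict(DEFAULT_PALETTE))
    background: str = "flat"                      # or "hgradient"
    marker: MarkerSpec | None = None
    seed: int = 0


@dataclass
class SceneResult:
    """Rendered scene plus complete ground truth."""

    image: np.ndarray                     # (H, W, 3) uint8 RGB
    class_masks: dict[str, np.ndarray]    # per class, {0, 255}
    plant_masks: list[np.ndarray]         # one {0,255} mask per plant
    leaf_counts: list[int]
    tip_points: list[np.ndarray]          # per plant: (k, 2) float (x, y)


def _effective_ring_radius(r: RosetteSpec) -> int:
    """Ring radius large enough that adjacent petiole bases never fuse.

    Petiole wedges start 4 px wide at the ring; the chord between
    neighbouring wedge bases must exceed that width plus clearance, or the
    bases merge into a thick junction that the distance map would count as
    an extra lobe.
    """
    needed = int(np.ceil(3.0 / np.sin(np.pi / r.leaf_count))) + 1
    return max(r.ring_radius, needed)


def _blade_center_radius(r: RosetteSpec) -> float:
    """Blade-center radius guaranteeing neighbouring blades never touch."""
    gap = 6.0
    spacing = (r.leaf_width + gap) / (2.0 * np.sin(np.pi / r.leaf_count))
    return max(float(_effective_ring_radius(r) + r.leaf_length), spacing)


def rosette_extent(r: RosetteSpec) -> float:
    """Radius of the circle that bounds the rendered rosette."""
    return _blade_center_radius(r) + r.leaf_length / 2.0 + 1


def _draw_rosette(shape: tuple[int, int], center: tuple[float, float],
                  r: RosetteSpec, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize one rosette; returns (bool mask, (k, 2) leaf-tip points)."""
    from skimage.draw import disk, ellipse, polygon

    if r.leaf_count < 1:
        raise ValueError("leaf_count must be >= 1")
    H, W = shape
    cy, cx = center[1], center[0]
    R = _blade_center_radius(r)
    if (rosette_extent(r) + r.radius_jitter > min(cx, cy, W - 1 - cx, H - 1 - cy)):
        raise ValueError(
            "canvas too small for a separable rosette of this size: "
            f"extent {rosette_extent(r):.0f}px around center {center}")

    ring_radius = _effective_ring_radius(r)
    mask = np.zeros(shape, dtype=bool)
    # central ring (annulus of thickness 2 at ring_radius)
    rr, cc = disk((cy, cx), ring_radius + 1, shape=shape)
    outer = np.zeros(shape, dtype=bool)
    outer[rr, cc] = True
    rr, cc = disk((cy, cx), max(1, ring_radius - 1), shape=shape)
    inner = np.zeros(shape, dtype=bool)
    inner[rr, cc] = True
    mask |= outer & ~inner

    base_angles = 2 * np.pi * np.arange(r.leaf_count) / r.leaf_count
    jit = np.deg2rad(r.angle_jitter_deg)
    angles = base_angles + rng.uniform(-jit, jit, size=r.leaf_count)
    radii = R + rng.uniform(-r.radius_jitter, r.radius_jitter, size=r.leaf_count)
    tips = []
    for theta, rad in zip(angles, radii):
        ux, uy = np.cos(theta), np.sin(theta)
        px, py = -uy, ux  # unit normal
        inner_r = ring_radius - 1
        blade_in = rad - r.leaf_length / 2.0 + 2  # wedge overlaps the blade
        # tapered petiole: 4 px wide at the ring growing to petiole_width;
        # the base width matches the ring-junction thickness so the distance
        # map rises monotonically from ring to blade (no spurious maxima)
        w0, w1 = 2.0, max(2.0, r.petiole_width / 2.0)
        corners_x = [cx + inner_r * ux - w0 * px, cx + inner_r * ux + w0 * px,
                     cx + blade_in * ux + w1 * px, cx + blade_in * ux - w1 * px]
        corners_y = [cy + inner_r * uy - w0 * py, cy + inner_r * uy + w0 * py,
                     cy + blade_in * uy + w1 * py, cy + blade_in * uy - w1 * py]
        rr, cc = polygon(corners_y, corners_x, shape=shape)
        mask[rr, cc] = True
        # elliptical blade, major axis along the petiole direction
        rr, cc = ellipse(cy + rad * uy, cx + rad * ux,
                         r.leaf_width / 2.0, r.leaf_length / 2.0,
                         shape=shape, rotation=-theta)
        mask[rr, cc] = True
        tips.append((cx + (rad + r.leaf_length / 2.0 - 1) * ux,
                     cy + (rad + r.leaf_length / 2.0 - 1) * uy))
    return mask, np.array(tips, dtype=np.float64)


def _sample_hsv(color: ClassColor, n: int, rng: np.random.Generator) -> np.ndarray:
    mean = np.asarray(color.hsv_mean, dtype=np.float64)
    sigma = np.asarray(color.hsv_sigma, dtype=np.float64)
    return np.clip(rng.normal(mean, sigma, size=(n, 3)), 0, 255)


def _paint(image: np.ndarray, region: np.ndarray, color: ClassColor,
           rng: np.random.Generator) -> None:
    n = int(region.sum())
    if n:
        image[region] = hsv255_to_rgb(_sample_hsv(color, n, rng))


def generate_scene(spec: SceneSpec) -> SceneResult:
    """Render the scene described by *spec* with complete ground truth.

    Single layout: one rosette at the canvas center. Grid layout: one
    rosette per cell, jittered around the cell center; plants are disjoint
    by construction (each fits inside its own cell).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.canvas
    image = np.zeros((H, W, 3), dtype=np.uint8)

    plant_masks: list[np.ndarray] = []
    leaf_counts: list[int] = []
    tip_points: list[np.ndarray] = []
    if spec.layout is None:
        centers = [((W - 1) / 2.0, (H - 1) / 2.0)]
    else:
        g = spec.layout
        ch, cw = H / g.nrow, W / g.ncol
        if rosette_extent(spec.rosette) + g.jitter > min(ch, cw) / 2.0 - 1:
            raise ValueError(
                f"grid cells {ch:.0f}x{cw:.0f} too small for rosettes of "
                f"extent {rosette_extent(spec.rosette):.0f}px")
        centers = []
        for r in range(g.nrow):
            for c in range(g.ncol):
                jx, jy = rng.integers(-g.jitter, g.jitter + 1, size=2)
                centers.append((cw * (c + 0.5) + jx, ch * (r + 0.5) + jy))

    for center in centers:
        m, tips = _draw_rosette((H, W), center, spec.rosette, rng)
        plant_masks.append((m * np.uint8(255)))
        leaf_counts.append(spec.rosette.leaf_count)
        tip_points.append(tips)

    plant_all = np.zeros((H, W), dtype=bool)
    for m in plant_masks:
        plant_all |= m > 0

    bg = ~plant_all
    marker_region = np.zeros((H, W), dtype=bool)
    if spec.marker is not None:
        from skimage.draw import disk

        mx, my = spec.marker.center
        rr, cc = disk((my, mx), spec.marker.radius, shape=(H, W))
        marker_region[rr, cc] = True
        marker_region &= bg
        bg = bg & ~marker_region

    bg_color = spec.palette.get("background", DEFAULT_PALETTE["background"])
    _paint(image, bg, bg_color, rng)
    if spec.background == "hgradient":
        # value ramp left->right on background pixels only
        ramp = np.tile(np.linspace(0.6, 1.4, W), (H, 1))
        chan = image.astype(np.float64)
        chan[bg] *= ramp[bg][:, None]
        image = np.clip(np.rint(chan), 0, 255).astype(np.uint8)
    elif spec.background != "flat":
        raise ValueError("background must be 'flat' or 'hgradient'")

    plant_color = spec.palette.get("plant", DEFAULT_PALETTE["plant"])
    _paint(image, plant_all, plant_color, rng)
    if spec.marker is not None:
        _paint(image, marker_region, spec.marker.color, rng)

    class_masks = {
        "plant": plant_all * np.uint8(255),
        "background": bg * np.uint8(255),
    }
    if spec.marker is not None:
        class_masks["marker"] = marker_region * np.uint8(255)
    return SceneResult(image=image, class_masks=class_masks,
                       plant_masks=plant_masks, leaf_counts=leaf_counts,
                       tip_points=tip_points)


def generate_classmap_image(palette: dict[str, ClassColor],
                            shape: tuple[int, int] = (96, 128),
                            seed: int = 0) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Render vertical strips, one per palette class, with a label map.

    Returns ``(rgb image, label map, class names)`` where the label map
    holds the class index of every pixel — ground truth for classifier
    accuracy measurements.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    names = list(palette)
    image = np.zeros((H, W, 3), dtype=np.uint8)
    labels = np.zeros((H, W), dtype=np.int32)
    edges = np.linspace(0, W, len(names) + 1).round().astype(int)
    for i, name in enumerate(names):
        region = np.zeros((H, W), dtype=bool)
        region[:, edges[i]:edges[i + 1]] = True
        labels[region] = i
        _paint(image, region, palette[name], rng)
    return image, labels, names


def generate_training_table(palette: dict[str, ClassColor],
                            n_per_class: int = 100,
                            seed: int = 0) -> TrainingSampleTable:
    """Draw RGB training samples from each class's HSV distribution."""
    if n_per_class < 30:
        raise ValueError("n_per_class must be >= 30 for a stable KDE")
    rng = np.random.default_rng(seed)
    means = {n: np.asarray(c.hsv_mean, float) for n, c in palette.items()}
    names = list(palette)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.abs(means[a] - means[b]).max() < 10:
                warnings.warn(
                    f"classes {a!r} and {b!r} have nearly identical HSV "
                    "means; samples will not be separable", stacklevel=2)
    return TrainingSampleTable({
        name: hsv255_to_rgb(_sample_hsv(color, n_per_class, rng))
        for name, color in palette.items()
    })


def tray_spec(nrow: int, ncol: int, leaf_count: int = 5, seed: int = 0,
              cell: int = 90) -> SceneSpec:
    """Convenience spec for a tray of small rosettes, one per grid cell."""
    rosette = RosetteSpec(leaf_count=leaf_count, leaf_length=16, leaf_width=9,
                          petiole_width=5, ring_radius=7, radius_jitter=1.0)
    return SceneSpec(canvas=(nrow * cell, ncol * cell),
                     layout=GridLayout(nrow=nrow, ncol=ncol, jitter=2),
                     rosette=rosette, seed=seed)
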