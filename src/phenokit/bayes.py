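"""Trainable naive Bayes pixel classifier on HSV kernel densities.

Each class (plant, background, lesion, ...) is summarised by three
256-bin probability densities — one per HSV channel — estimated from
training pixels by Gaussian kernel density estimation. A pixel's class
score is the product of its three channel densities (channels treated as
independent — the "naive" assumption) times a uniform prior; the argmax
class wins, giving one binary mask per class that together partition the
image. The classifier replaces the thresholding steps of a pipeline and
is more robust to variable lighting than any fixed cutoff.

Two training routes exist: *two-class* training from image/mask pairs
(foreground = plant), and *multiclass* training from a tab-delimited
table of hand-sampled RGB pixels, one class per column, cells "R,G,B".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._color import rgb_to_hsv255
from .imgcore import as_mask

__all__ = [
    "ClassPDF",
    "TrainingSampleTable",
    "read_training_table",
    "write_training_table",
    "sample_training_pixels",
    "train_two_class",
    "train_multiclass",
    "naive_bayes_classifier",
    "write_pdfs",
    "read_pdfs",
]

CHANNELS = ("hue", "saturation", "value")

#: floor applied to discretized densities before taking products, so a
#: finite training sample can never hard-zero a class.
DENSITY_FLOOR = 1e-10

#: minimum training pixels per class for a stable density estimate
MIN_SAMPLES_PER_CLASS = 30


@dataclass
class ClassPDF:
    """Per-class discretized densities: one 256-bin PDF per HSV channel."""

    name: str
    densities: np.ndarray  # (3, 256), rows ordered as CHANNELS, each sums to 1

    def __post_init__(self):
        self.densities = np.asarray(self.densities, dtype=np.float64)
        if self.densities.shape != (3, 256):
            raise ValueError("densities must have shape (3, 256)")
        sums = self.densities.sum(axis=1)
        if np.any(self.densities < 0) or not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each channel density must be nonnegative and sum to 1")


@dataclass
class TrainingSampleTable:
    """Per-class RGB training pixels: class name -> (N, 3) uint8 array."""

    classes: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self, min_samples: int = MIN_SAMPLES_PER_CLASS) -> None:
        if len(self.classes) < 2:
            raise ValueError("training requires at least two classes")
        for name, arr in self.classes.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"class {name!r}: samples must be (N, 3) RGB")
            if len(arr) < min_samples:
                raise ValueError(
                    f"class {name!r} has {len(arr)} samples; "
                    f"at least {min_samples} are required for a stable KDE")


def read_training_table(path: str) -> TrainingSampleTable:
    """Parse the tab-delimited training table (header = class names).

    Each data cell is a comma-separated "R,G,B" triple in [0, 255]; parse
    errors report the offending line number.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError(f"{path}: empty training table")
    names = lines[0].split("\t")
    if len(names) < 2:
        raise ValueError(f"{path}: line 1: need at least two class columns")
    samples: dict[str, list[list[int]]] = {n: [] for n in names}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split("\t")
        for name, cell in zip(names, cells):
            cell = cell.strip()
            if not cell:
                continue
            parts = cell.split(",")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: cell {cell!r} "
                                 "is not an R,G,B triple")
            try:
                rgb = [int(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer value "
                                 f"in {cell!r}") from exc
            if any(v < 0 or v > 255 for v in rgb):
                raise ValueError(f"{path}: line {lineno}: value out of "
                                 f"[0, 255] in {cell!r}")
            samples[name].append(rgb)
    table = TrainingSampleTable(
        {n: np.array(v, dtype=np.uint8).reshape(-1, 3) for n, v in samples.items()})
    return table


def write_training_table(table: TrainingSampleTable, path: str) -> None:
    names = list(table.classes)
    counts = [len(table.classes[n]) for n in names]
    with open(path, "w") as fh:
        fh.write("\t".join(names) + "\n")
        for i in range(max(counts)):
            row = []
            for n in names:
                arr = table.classes[n]
                row.append(",".join(map(str, arr[i])) if i < len(arr) else "")
            fh.write("\t".join(row) + "\n")


def _kde_density_256(samples: np.ndarray) -> np.ndarray:
    """Discretize a Gaussian KDE (Scott's-rule bandwidth) to 256 bins.

    Degenerate all-equal samples collapse to a point mass in their bin.
    """
    samples = np.asarray(samples, dtype=np.float64)
    grid = np.arange(256, dtype=np.float64)
    if samples.std() == 0:
        out = np.zeros(256)
        out[int(round(samples[0]))] = 1.0
        return out
    from scipy.stats import gaussian_kde

    dens = gaussian_kde(samples)(grid)
    total = dens.sum()
    if total <= 0:
        raise ValueError("kernel density estimate vanished on the grid")
    return dens / total


def _pdfs_from_hsv(samples_by_class: dict[str, np.ndarray]) -> list[ClassPDF]:
    pdfs = []
    for name, hsv in samples_by_class.items():
        dens = np.stack([_kde_density_256(hsv[:, c]) for c in range(3)])
        pdfs.append(ClassPDF(name=name, densities=dens))
    return pdfs


def sample_training_pixels(pairs: list[tuple[np.ndarray, np.ndarray]],
                           seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two-class training sample from pooled image/mask pairs.

    Returns ``(foreground_rgb, background_rgb)``: a seeded random sample
    of 10% of all foreground pixels and the same number of background
    pixels, pooled across pairs before sampling.
    """
    fg_pix, bg_pix = [], []
    for img, mask in pairs:
        img = np.asarray(img)
        mask = as_mask(mask)
        if img.shape[:2] != mask.shape:
            raise ValueError("image and mask dimensions differ in a training pair")
        if img.ndim != 3:
            raise ValueError("two-class training requires RGB images")
        fg = mask > 0
        fg_pix.append(img[fg])
        bg_pix.append(img[~fg])
    fg_all = np.concatenate(fg_pix) if fg_pix else np.empty((0, 3), np.uint8)
    bg_all = np.concatenate(bg_pix) if bg_pix else np.empty((0, 3), np.uint8)
    if len(fg_all) == 0:
        raise ValueError("no foreground pixels in any training pair")

    n_fg = max(1, len(fg_all) // 10)
    n_bg = min(n_fg, len(bg_all))
    if len(fg_all) < 10 * MIN_SAMPLES_PER_CLASS:
        raise ValueError(
            f"need at least {10 * MIN_SAMPLES_PER_CLASS} foreground pixels, "
            f"got {len(fg_all)}")
    rng = np.random.default_rng(seed)
    fg_sample = fg_all[rng.choice(len(fg_all), size=n_fg, replace=False)]
    bg_sample = bg_all[rng.choice(len(bg_all), size=n_bg, replace=False)]
    return fg_sample, bg_sample


def train_two_class(pairs: list[tuple[np.ndarray, np.ndarray]],
                    seed: int = 0) -> list[ClassPDF]:
    """Train plant/background PDFs from (RGB image, binary mask) pairs.

    Pixels are pooled across all pairs; a seeded random sample of 10% of
    the foreground pixels, and the same number of background pixels
    (:func:`sample_training_pixels`), is converted to HSV and used to fit
    the per-channel densities.
    """
    fg_sample, bg_sample = sample_training_pixels(pairs, seed=seed)
    return _pdfs_from_hsv({
        "plant": rgb_to_hsv255(fg_sample).astype(np.float64),
        "background": rgb_to_hsv255(bg_sample).astype(np.float64),
    })


def train_multiclass(table: TrainingSampleTable) -> list[ClassPDF]:
    """Train one ClassPDF per table column; all samples are used."""
    table.validate()
    return _pdfs_from_hsv({
        name: rgb_to_hsv255(arr).astype(np.float64)
        for name, arr in table.classes.items()
    })


def naive_bayes_classifier(img: np.ndarray,
                           pdfs: list[ClassPDF]) -> dict[str, np.ndarray]:
    """Classify every pixel; returns one binary mask per class.

    Scores are computed in log space (floored densities) with uniform
    priors, so multiplying all priors by a constant cannot change the
    argmax. Masks are mutually exclusive and jointly exhaustive; exact
    score ties go to the earlier class in *pdfs* and are reported with a
    warning.
    """
    if len(pdfs) < 2:
        raise ValueError("classification requires at least two class PDFs")
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("classification requires an RGB image")
    hsv = rgb_to_hsv255(img).reshape(-1, 3)
    logd = np.stack([np.log(np.maximum(p.densities, DENSITY_FLOOR)) for p in pdfs])
    # (n_classes, n_pixels): sum of per-channel log densities at pixel bins
    scores = (logd[:, 0, hsv[:, 0]] + logd[:, 1, hsv[:, 1]] + logd[:, 2, hsv[:, 2]])
    best = np.argmax(scores, axis=0)
    top = scores[best, np.arange(scores.shape[1])]
    n_ties = int(((scores == top).sum(axis=0) > 1).sum())
    if n_ties:
        warnings.warn(f"{n_ties} pixels had tied class scores; "
                      "assigned to the first class in PDF order", stacklevel=2)
    H, W = img.shape[:2]
    return {
        p.name: ((best == i).reshape(H, W) * np.uint8(255))
        for i, p in enumerate(pdfs)
    }


def write_pdfs(pdfs: list[ClassPDF], path: str) -> None:
    """Write densities as tab-delimited text: class, channel, b0..b255."""
    with open(path, "w") as fh:
        fh.write("class\tchannel\t" + "\t".join(f"b{i}" for i in range(256)) + "\n")
        for p in pdfs:
            for ci, chan in enumerate(CHANNELS):
                row = "\t".join(repr(float(v)) for v in p.densities[ci])
                fh.write(f"{p.name}\t{chan}\t{row}\n")


def read_pdfs(path: str) -> list[ClassPDF]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("class\tchannel"):
            raise ValueError(f"{path}: not a PDF table (bad header)")
        rows: dict[str, dict[str, np.ndarray]] = {}
        order: list[str] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 258:
                raise ValueError(f"{path}: line {lineno}: expected 258 fields")
            name, chan = parts[0], parts[1]
            if chan not in CHANNELS:
                raise ValueError(f"{path}: line {lineno}: unknown channel {chan!r}")
            if name not in rows:
                rows[name] = {}
                order.append(name)
            rows[name][chan] = np.array(parts[2:], dtype=np.float64)
    pdfs = []
    for name in order:
        if set(rows[name]) != set(CHANNELS):
            raise ValueError(f"{path}: class {name!r} is missing channels")
        pdfs.append(ClassPDF(name=name, densities=np.stack(
            [rows[name][c] for c in CHANNELS])))
    return pdfs
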