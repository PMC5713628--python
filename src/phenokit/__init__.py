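"""phenokit: modular plant shoot phenotyping from images.

Submodules
----------
imgcore     raster/mask/contour primitives, image I/O, shape summaries
preprocess  white balance, blurs, rotation/translation, VIS->NIR mask transfer
threshold   triangle/Otsu/adaptive automatic thresholding
marker      size-marker area reporting for cross-image normalization
multiplant  grid clustering of multi-plant trays and per-plant splitting
watershed   distance-transform watershed leaf counting
landmarks   acute (Type II) and axis pseudo- (Type III) landmark morphometrics
bayes       trainable naive Bayes pixel classifier (HSV kernel densities)
pipeline    filename metadata, parallel per-image runs, SQLite aggregation
synthgen    seeded synthetic rosette/tray/class-image generator
"""

__version__ = "0.1.0"

_SUBMODULES = (
    "imgcore",
    "preprocess",
    "threshold",
    "marker",
    "multiplant",
    "watershed",
    "landmarks",
    "bayes",
    "pipeline",
    "synthgen",
)


def __getattr__(name):
    # Lazy so that light-weight pipeline scripts importing a single submodule
    # do not pay the full scikit-image import cost.
    if name in _SUBMODULES:
        import importlib

        return importlib.import_module(f"phenokit.{name}")
    raise AttributeError(f"module 'phenokit' has no attribute {name!r}")
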