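"""Optional debug-image emission.

Every analysis step can drop an annotated intermediate image into a debug
directory. Emission is off by default: writing an image per step dominates
run time on large datasets, so it is enabled only while building a pipeline.
"""

from __future__ import annotations

import os

_debug_dir: str | None = None
_counter = 0


def set_debug(directory: str | None) -> None:
    """Enable (or disable with None) debug-image output into *directory*."""
    global _debug_dir, _counter
    _debug_dir = directory
    _counter = 0
    if directory is not None:
        os.makedirs(directory, exist_ok=True)


def emit(name: str, img) -> str | None:
    """Write *img* as ``<seq>_<name>.png`` in the debug directory, if set."""
    global _counter
    if _debug_dir is None:
        return None
    from . import imgcore

    _counter += 1
    path = os.path.join(_debug_dir, f"{_counter:03d}_{name}.png")
    imgcore.write_image(img, path)
    return path
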