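"""Reading and writing strip rasters (8-bit PNG, 16-bit TIFF).

Pixel math throughout the package runs on floats in [0, 1]; quantization to
integer bit depths happens only at write time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import FormatError


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF as float array in [0, 1] (2-D gray or (H, W, 3) RGB)."""
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode not in ("L", "I;16", "RGB"):
                    im = im.convert("RGB")
                arr = np.asarray(im)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim not in (2, 3):
        raise FormatError(f"unsupported raster shape {arr.shape} in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(float) / scale
    return np.clip(arr.astype(float), 0.0, 1.0)


def write_image(path, pixels: np.ndarray) -> None:
    """Write a [0, 1] float raster: 8-bit grayscale PNG or 16-bit TIFF."""
    path = Path(path)
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.round(arr * 65535).astype(np.uint16))
    elif path.suffix.lower() == ".png":
        Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)
    else:
        raise FormatError(f"unsupported output format {path.suffix!r} (use .png or .tiff)")
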