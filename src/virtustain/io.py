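"""Image and table I/O.

Grayscale TIFF/PNG only; intensities are never rescaled on read or write, so
8- and 16-bit data round-trip bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

__all__ = ["read_image", "write_image", "write_report"]

_TIFF = {".tif", ".tiff"}
_PNG = {".png"}


def read_image(path: str | Path, page: int | None = None, collapse_rgb: bool = False) -> np.ndarray:
    """Read a single-channel image, preserving dtype and bit depth.

    ``page`` selects one page of a multi-page TIFF (required for such files);
    ``collapse_rgb`` averages an RGB image to one channel instead of raising.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        arr = tifffile.imread(path, key=page) if page is not None else tifffile.imread(path)
    elif suffix in _PNG:
        arr = np.asarray(Image.open(path))
    else:
        raise ValueError(f"unsupported image format '{suffix}' for {path} (TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        if not collapse_rgb:
            raise ValueError(f"{path} is multi-channel; pass collapse_rgb=True to average channels")
        arr = np.round(arr[..., :3].mean(axis=-1)).astype(arr.dtype)
    if arr.ndim != 2:
        raise ValueError(
            f"{path} has shape {arr.shape}; expected a single 2-D page "
            "(use the 'page' argument for multi-page TIFFs)"
        )
    return arr


def write_image(path: str | Path, arr: np.ndarray) -> Path:
    """Write a 2-D integer array as TIFF or PNG without rescaling."""
    path = Path(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D array, got shape {arr.shape}")
    path.parent.mkdir(parents=True, exist_ok=True)
    suffix = path.suffix.lower()
    if suffix in _TIFF:
        tifffile.imwrite(path, arr)
    elif suffix in _PNG:
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format '{suffix}' for {path} (TIFF or PNG)")
    return path


def write_report(rows, path: str | Path, float_precision: int = 6) -> Path:
    """Write tabular rows (DataFrame or list of dicts) as CSV.

    Column order is preserved from the input; floats are serialized at a
    fixed precision so identical inputs produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format=f"%.{float_precision}f")
    return path
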