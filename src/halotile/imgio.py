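"""Raster I/O: grayscale/multichannel TIFF (incl. BigTIFF-sized rasters)
and PNG.

Conventions: segmentation masks are written as 8-bit label images, softmax
maps as 32-bit float TIFF, raw data as 8/16-bit integer or float TIFF.
Arrays are ``(H, W)`` or ``(H, W, C)``; reading always returns ``(H, W, C)``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ConstraintError

__all__ = ["read_image", "write_image", "write_mask"]

_INT_DTYPES = (np.uint8, np.uint16)
_FLOAT_DTYPES = (np.float32, np.float64)


def _check_dtype(arr: np.ndarray) -> np.ndarray:
    if arr.dtype in _INT_DTYPES:
        return arr
    if arr.dtype == np.float64:
        return arr.astype(np.float32)
    if arr.dtype == np.float32:
        return arr
    raise ConstraintError(
        f"unsupported image dtype {arr.dtype}; supported: uint8, uint16, "
        "float32 (float64 is stored as float32)"
    )


def write_image(x: np.ndarray, path) -> None:
    """Write an image; format chosen by extension (.tif/.tiff or .png).

    Integer arrays round-trip exactly (8/16-bit); floats are stored as
    32-bit float TIFF.  PNG supports 8/16-bit integers only.
    """
    path = Path(path)
    x = np.asarray(x)
    if x.ndim == 3 and x.shape[2] == 1:
        x = x[:, :, 0]
    if x.ndim not in (2, 3):
        raise ConstraintError(f"expected (H, W) or (H, W, C) array, got shape {x.shape}")
    x = _check_dtype(x)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        # bigtiff switches on automatically for rasters beyond the 4 GiB
        # classic-TIFF limit (e.g. 20000x20000 16-bit microscopy frames)
        tifffile.imwrite(path, x, bigtiff=x.nbytes >= 2 ** 32 - 2 ** 25)
    elif suffix == ".png":
        if x.dtype not in _INT_DTYPES:
            raise ConstraintError("PNG supports 8/16-bit integer images only; use TIFF")
        import imageio.v3 as iio

        iio.imwrite(path, x)
    else:
        raise ConstraintError(f"unsupported image format {suffix!r}; use .tif or .png")


def read_image(path) -> np.ndarray:
    """Read a TIFF or PNG image as an ``(H, W, C)`` array, native dtype."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
    else:
        raise ConstraintError(f"unsupported image format {suffix!r}; use .tif or .png")
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ConstraintError(f"cannot interpret {path} with shape {arr.shape} as an image")
    if arr.dtype not in _INT_DTYPES and arr.dtype not in _FLOAT_DTYPES:
        raise ConstraintError(f"unsupported bit depth / dtype {arr.dtype} in {path}")
    return arr


def write_mask(mask: np.ndarray, path) -> None:
    """Write an integer label mask as an 8-bit image."""
    mask = np.asarray(mask)
    if mask.ndim == 3 and mask.shape[2] == 1:
        mask = mask[:, :, 0]
    if mask.min() < 0 or mask.max() > 255:
        raise ConstraintError("label mask values must fit in 8 bits")
    write_image(mask.astype(np.uint8), path)
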