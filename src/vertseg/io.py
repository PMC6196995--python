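"""Image loading and saving.

All processing in this package happens on 2-D float arrays with intensities
in [0, 1].  Integer images (8-bit / 16-bit PNG or TIFF) are rescaled by the
dtype maximum on load; float images are validated to already lie in [0, 1].
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import tifffile

from .exceptions import InvalidInputError

__all__ = ["load_image", "save_mask", "load_mask", "save_field", "as_gray_image"]


def as_gray_image(arr: np.ndarray) -> np.ndarray:
    """Validate/convert an array to the internal [0, 1] float representation.

    Integer dtypes are divided by their dtype maximum.  Float inputs must
    already be finite and inside [0, 1].
    """
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):  # RGB(A): collapse equal channels
        arr = arr[..., :3].mean(axis=2).astype(arr.dtype if arr.dtype.kind == "f" else np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise InvalidInputError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.dtype.kind in "ui":
        out = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    elif arr.dtype.kind == "f":
        out = arr.astype(np.float64)
    else:
        raise InvalidInputError(f"unsupported image dtype {arr.dtype}")
    if not np.all(np.isfinite(out)):
        raise InvalidInputError("image contains non-finite pixels")
    if out.min() < 0.0 or out.max() > 1.0:
        raise InvalidInputError("float image intensities must lie in [0, 1]")
    return out


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a single-channel PNG/TIFF and rescale intensities to [0, 1]."""
    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise InvalidInputError(f"cannot read image {path!r}: {exc}") from exc
    return as_gray_image(arr)


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def load_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a mask PNG; any nonzero pixel counts as foreground."""
    try:
        arr = iio.imread(path)
    except OSError as exc:
        raise InvalidInputError(f"cannot read mask {path!r}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def save_field(path: str | os.PathLike, field: np.ndarray) -> None:
    """Write a scalar field (e.g. the level-set function) as a float32 TIFF."""
    tifffile.imwrite(path, np.asarray(field, dtype=np.float32))
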