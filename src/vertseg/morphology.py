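"""Gray-scale mathematical morphology and the hybrid denoising filter.

Erosion and dilation are defined window-wise with the window clipped to the
image domain: the output at (x, y) is the min (resp. max) of the image over
the structuring-element offsets that land inside the image, shifted by the
element's gray-value offsets.  No padding value is ever invented, so border
statistics are those of the actual image.

The hybrid filter used for impulse-noise removal is an alternating
sequential filter that applies a closing *first* and then an opening;
closing first protects weak (low-contrast) boundary segments of bright
objects while still removing dark speckle from the foreground and bright
speckle from the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "StructuringElement",
    "erode",
    "dilate",
    "opening",
    "closing",
    "hmf",
]


@dataclass(frozen=True)
class StructuringElement:
    """A neighborhood footprint with per-offset gray-value offsets.

    Parameters
    ----------
    offsets
        Integer (row, col) displacements forming the domain of the element.
        Must contain the origin (0, 0).
    values
        Additive gray-value offset per displacement; all zero for a flat
        element.
    """

    offsets: np.ndarray
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        offs = np.atleast_2d(np.asarray(self.offsets, dtype=int))
        if offs.ndim != 2 or offs.shape[1] != 2 or offs.shape[0] == 0:
            raise InvalidInputError("offsets must be a non-empty (N, 2) integer array")
        vals = self.values
        vals = np.zeros(len(offs)) if vals is None else np.asarray(vals, dtype=float)
        if vals.shape != (len(offs),):
            raise InvalidInputError("values must have one entry per offset")
        if not np.all(np.isfinite(vals)):
            raise InvalidInputError("structuring element values must be finite")
        if not np.any((offs[:, 0] == 0) & (offs[:, 1] == 0)):
            raise InvalidInputError("structuring element must contain the origin")
        object.__setattr__(self, "offsets", offs)
        object.__setattr__(self, "values", vals)

    @classmethod
    def flat_square(cls, size: int = 3) -> "StructuringElement":
        """Flat square element of odd side length ``size`` centered at the origin."""
        if size < 1 or size % 2 == 0:
            raise InvalidInputError("size must be a positive odd integer")
        h = size // 2
        rr, cc = np.mgrid[-h : h + 1, -h : h + 1]
        return cls(np.column_stack([rr.ravel(), cc.ravel()]))

    @classmethod
    def flat(cls, footprint: np.ndarray) -> "StructuringElement":
        """Flat element from a boolean footprint centered on its middle pixel."""
        fp = np.asarray(footprint, dtype=bool)
        if fp.ndim != 2:
            raise InvalidInputError("footprint must be 2-D")
        cr, cc = fp.shape[0] // 2, fp.shape[1] // 2
        rr, cc_idx = np.nonzero(fp)
        return cls(np.column_stack([rr - cr, cc_idx - cc]))

    @property
    def is_flat(self) -> bool:
        return bool(np.all(self.values == 0.0))

    @property
    def is_symmetric(self) -> bool:
        """Point symmetry about the origin, required for exact min-max duality."""
        items = {(int(r), int(c), float(v)) for (r, c), v in zip(self.offsets, self.values)}
        return all((-r, -c, v) in items for (r, c, v) in items)

    def mirrored(self) -> "StructuringElement":
        return StructuringElement(-self.offsets, self.values.copy())


DEFAULT_SE = StructuringElement.flat_square(3)


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise InvalidInputError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise InvalidInputError("image contains non-finite pixels")
    return img


def _shift_pad(img: np.ndarray, dr: int, dc: int, fill: float) -> np.ndarray:
    """Return J with J[x, y] = img[x + dr, y + dc], filled where out of domain."""
    out = np.full_like(img, fill)
    h, w = img.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = img[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return out


def erode(image: np.ndarray, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Gray-scale erosion: per-pixel min of ``image[x+s, y+t] - b(s, t)``.

    Offsets falling outside the image are excluded from the minimum
    (window clipping); the origin is always inside, so the window is never
    empty.
    """
    img = _check_image(image)
    out = np.full_like(img, np.inf)
    for (dr, dc), b in zip(se.offsets, se.values):
        np.minimum(out, _shift_pad(img, dr, dc, np.inf) - b, out=out)
    return out


def dilate(image: np.ndarray, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Gray-scale dilation: per-pixel max of ``image[x-s, y-t] + b(s, t)``."""
    img = _check_image(image)
    out = np.full_like(img, -np.inf)
    for (dr, dc), b in zip(se.offsets, se.values):
        np.maximum(out, _shift_pad(img, -dr, -dc, -np.inf) + b, out=out)
    return out


def opening(image: np.ndarray, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Morphological opening (erosion then dilation): removes small bright objects."""
    return dilate(erode(image, se), se)


def closing(image: np.ndarray, se: StructuringElement = DEFAULT_SE) -> np.ndarray:
    """Morphological closing (dilation then erosion): fills small dark holes."""
    return erode(dilate(image, se), se)


def hmf(
    image: np.ndarray,
    se: StructuringElement = DEFAULT_SE,
    n: int = 1,
    growing: bool = False,
) -> np.ndarray:
    """Hybrid morphological filter: ``n`` rounds of closing followed by opening.

    One iteration is ``opening(closing(image))``; taking the closing first
    preserves weak boundaries of bright structures.  With ``growing=True``
    iteration ``k`` uses a flat square of side ``2k + 1`` instead of the
    fixed element (both readings coincide at n=1, the default).

    Parameters
    ----------
    image
        2-D gray image.
    se
        Structuring element used at every iteration in fixed mode.
    n
        Number of closing+opening rounds; controls the smoothing strength.
    growing
        Grow the element size with the iteration index.
    """
    if int(n) != n or n < 1:
        raise InvalidInputError("n must be a positive integer")
    out = _check_image(image)
    for k in range(1, int(n) + 1):
        se_k = StructuringElement.flat_square(2 * k + 1) if growing else se
        out = opening(closing(out, se_k), se_k)
    return out
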