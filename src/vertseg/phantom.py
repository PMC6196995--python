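"""Synthetic vertebra-like phantom slices with ground truth.

The phantom emulates the failure modes that make bone segmentation in CT
slices hard: a bright ring-shaped body (vertebral body with an interior
dark foramen, so the object has genus-1 topology), protruding processes
(lobes on the outer boundary), a locally attenuated "weak" boundary arc, a
thin parallel secondary edge ("double boundary"), within-region texture
noise, and optional salt-and-pepper impulse corruption.

The generator is fully deterministic given ``PhantomSpec.seed``; the
ground truth mask depends only on the geometry, never on the noise
settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["WeakArc", "DoubleEdge", "PhantomSpec", "generate_phantom", "add_salt_pepper"]


@dataclass(frozen=True)
class WeakArc:
    """Angular interval of the outer boundary with attenuated contrast.

    Within ``band_px`` of the outer radius and inside the angular interval,
    the image is pulled toward the background level by ``attenuation``
    (remaining contrast fraction), emulating cortical-bone thinning.  The
    default attenuation leaves the rim below the midpoint of the two class
    means, so a global two-class intensity clustering mislabels it.
    """

    start_deg: float = -20.0
    extent_deg: float = 40.0
    attenuation: float = 0.35
    band_px: float = 2.0


@dataclass(frozen=True)
class DoubleEdge:
    """Thin secondary contour parallel to the outer boundary, offset inward."""

    offset_px: float = 4.0
    intensity: float = 0.55
    start_deg: float = 120.0
    extent_deg: float = 60.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of the synthetic slice."""

    size: tuple[int, int] = (256, 256)
    center: tuple[float, float] | None = None  # (row, col); grid center if None
    outer_radius: float = 70.0
    inner_radius: float = 25.0
    n_processes: int = 3
    process_radius: float = 16.0
    fg_level: float = 0.75
    bg_level: float = 0.25
    texture_sd: float = 0.03
    weak_arc: WeakArc | None = field(default_factory=WeakArc)
    double_edge: DoubleEdge | None = field(default_factory=DoubleEdge)
    sp_level: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.sp_level < 1.0):
            raise InvalidInputError("sp_level must be in [0, 1)")
        if self.fg_level == self.bg_level:
            raise InvalidInputError("fg_level and bg_level must differ")
        if not (0.0 < self.inner_radius < self.outer_radius):
            raise InvalidInputError("need 0 < inner_radius < outer_radius")
        h, w = self.size
        if self.outer_radius + self.process_radius >= min(h, w) / 2:
            raise InvalidInputError("phantom geometry does not fit inside the grid")

    def with_noise(self, sp_level: float, seed: int | None = None) -> "PhantomSpec":
        return replace(self, sp_level=sp_level, seed=self.seed if seed is None else seed)


def _angles(spec: PhantomSpec, yy: np.ndarray, xx: np.ndarray) -> np.ndarray:
    cy, cx = spec.center if spec.center is not None else ((spec.size[0] - 1) / 2, (spec.size[1] - 1) / 2)
    return np.degrees(np.arctan2(-(yy - cy), xx - cx))  # math convention, y up


def _in_arc(theta_deg: np.ndarray, start: float, extent: float) -> np.ndarray:
    rel = np.mod(theta_deg - start, 360.0)
    return rel <= extent


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the phantom.

    Returns
    -------
    image : float array in [0, 1]
        The gray-scale slice, including texture, weak arc, double edge and
        (if ``spec.sp_level > 0``) salt-and-pepper corruption.
    mask : bool array
        Ground-truth foreground: ring plus processes, foramen excluded.
    """
    h, w = spec.size
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2, (w - 1) / 2)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d = np.hypot(yy - cy, xx - cx)
    theta = _angles(spec, yy, xx)

    body = d <= spec.outer_radius
    lobes = np.zeros_like(body)
    for k in range(spec.n_processes):
        ang = np.radians(90.0 + 360.0 * k / max(spec.n_processes, 1))
        ly, lx = cy - spec.outer_radius * np.sin(ang), cx + spec.outer_radius * np.cos(ang)
        lobes |= np.hypot(yy - ly, xx - lx) <= spec.process_radius
    foramen = d <= spec.inner_radius
    mask = (body | lobes) & ~foramen

    image = np.where(mask, spec.fg_level, spec.bg_level)

    if spec.weak_arc is not None:
        wa = spec.weak_arc
        rim = mask & (d > spec.outer_radius - wa.band_px) & (d <= spec.outer_radius)
        sel = rim & _in_arc(theta, wa.start_deg, wa.extent_deg)
        image = np.where(sel, spec.bg_level + (image - spec.bg_level) * wa.attenuation, image)

    if spec.double_edge is not None:
        de = spec.double_edge
        line = np.abs(d - (spec.outer_radius - de.offset_px)) <= 0.5
        sel = line & mask & _in_arc(theta, de.start_deg, de.extent_deg)
        image = np.where(sel, de.intensity, image)

    rng = np.random.default_rng(spec.seed)
    if spec.texture_sd > 0:
        image = image + rng.normal(0.0, spec.texture_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    if spec.sp_level > 0:
        image = add_salt_pepper(image, spec.sp_level, seed=int(rng.integers(2**31 - 1)))
    return image, mask


def add_salt_pepper(image: np.ndarray, level: float, seed: int) -> np.ndarray:
    """Corrupt exactly ``floor(level * N)`` distinct pixels to 0 or 1.

    The corrupted-pixel count is exact rather than Bernoulli-per-pixel, so
    fixtures are size-exact; each corrupted pixel is set to 0 or 1 with
    equal probability.  All other pixels are bit-identical to the input.
    """
    if not (0.0 <= level < 1.0):
        raise InvalidInputError("level must be in [0, 1)")
    img = np.array(image, dtype=float, copy=True)
    n_bad = int(level * img.size)
    if n_bad == 0:
        return img
    rng = np.random.default_rng(seed)
    idx = rng.choice(img.size, size=n_bad, replace=False)
    img.ravel()[idx] = rng.integers(0, 2, size=n_bad).astype(float)
    return img
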