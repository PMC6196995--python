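"""Segmentation evaluation criteria: DSC, MCR, MAD and Hausdorff distance.

Region metrics (DSC, MCR) operate on the full masks; boundary metrics
(MAD, HD) operate on boundary pixel sets.  A boundary pixel is a mask
pixel with at least one background 4-neighbor, pixels on the grid edge
included.  Distances are Euclidean between pixel centers, in pixel units.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .exceptions import MetricError

__all__ = ["boundary_pixels", "dsc", "mcr", "mad", "hausdorff", "evaluate"]

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def _as_masks(seg: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    seg = np.asarray(seg, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if seg.shape != gt.shape:
        raise MetricError(f"mask shapes differ: {seg.shape} vs {gt.shape}")
    return seg, gt


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(N, 2) coordinates of mask pixels with a background 4-neighbor or grid edge."""
    mask = np.asarray(mask, dtype=bool)
    inner = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~inner)


def dsc(seg: np.ndarray, gt: np.ndarray) -> float:
    """Dice similarity coefficient in percent: ``100 * 2|S∩G| / (|S| + |G|)``.

    Symmetric overlap measure in [0, 100]; 100 for identical non-empty
    masks, 0 for disjoint ones.
    """
    seg, gt = _as_masks(seg, gt)
    denom = int(seg.sum()) + int(gt.sum())
    if denom == 0:
        raise MetricError("DSC undefined: both masks are empty")
    return 100.0 * 2.0 * int((seg & gt).sum()) / denom


def mcr(seg: np.ndarray, gt: np.ndarray) -> float:
    """Misclassification rate in percent: ``100 * (1 - |S∩G| / |G|)``.

    Fraction of the true object missing from the segmentation; 0 when the
    segmentation covers the ground truth.
    """
    seg, gt = _as_masks(seg, gt)
    n_gt = int(gt.sum())
    if n_gt == 0:
        raise MetricError("MCR undefined: ground-truth mask is empty")
    return 100.0 * (1.0 - int((seg & gt).sum()) / n_gt)


def mad(seg: np.ndarray, gt: np.ndarray, symmetric: bool = False) -> float:
    """Mean absolute boundary distance in pixels.

    Average Euclidean distance from each boundary pixel of the
    segmentation to the nearest boundary pixel of the ground truth
    (directed S -> G).  ``symmetric=True`` averages both directions
    (average symmetric surface distance) for users expecting ASSD.
    """
    seg, gt = _as_masks(seg, gt)
    s, g = boundary_pixels(seg), boundary_pixels(gt)
    if len(s) == 0 or len(g) == 0:
        raise MetricError("MAD undefined: a boundary is empty")
    d_sg = cKDTree(g).query(s)[0]
    if not symmetric:
        return float(d_sg.mean())
    d_gs = cKDTree(s).query(g)[0]
    return float((d_sg.sum() + d_gs.sum()) / (len(s) + len(g)))


def hausdorff(seg: np.ndarray, gt: np.ndarray) -> float:
    """Symmetric Hausdorff distance between the two boundaries, in pixels.

    ``max(sup_x inf_y d(x, y), sup_y inf_x d(x, y))`` over the boundary
    pixel sets.
    """
    seg, gt = _as_masks(seg, gt)
    s, g = boundary_pixels(seg), boundary_pixels(gt)
    if len(s) == 0 or len(g) == 0:
        raise MetricError("Hausdorff undefined: a boundary is empty")
    d_sg = cKDTree(g).query(s)[0].max()
    d_gs = cKDTree(s).query(g)[0].max()
    return float(max(d_sg, d_gs))


def evaluate(seg: np.ndarray, gt: np.ndarray) -> dict[str, float]:
    """All four criteria as a flat record (dsc, mcr, mad, hd)."""
    return {
        "dsc": dsc(seg, gt),
        "mcr": mcr(seg, gt),
        "mad": mad(seg, gt),
        "hd": hausdorff(seg, gt),
    }
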