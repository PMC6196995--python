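"""Brute-force reference implementations used as independent test oracles.

Deliberately written as plain Python double loops over definitions, with no
shared code with the package internals.
"""

import numpy as np


def erode_oracle(image, offsets, values):
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    for x in range(h):
        for y in range(w):
            vals = []
            for (s, t), b in zip(offsets, values):
                if 0 <= x + s < h and 0 <= y + t < w:
                    vals.append(image[x + s, y + t] - b)
            out[x, y] = min(vals)
    return out


def dilate_oracle(image, offsets, values):
    h, w = image.shape
    out = np.empty_like(image, dtype=float)
    for x in range(h):
        for y in range(w):
            vals = []
            for (s, t), b in zip(offsets, values):
                if 0 <= x - s < h and 0 <= y - t < w:
                    vals.append(image[x - s, y - t] + b)
            out[x, y] = max(vals)
    return out


def boundary_oracle(mask):
    """Mask pixels with a background 4-neighbor or lying on the grid edge."""
    h, w = mask.shape
    pts = []
    for x in range(h):
        for y in range(w):
            if not mask[x, y]:
                continue
            on_edge = x in (0, h - 1) or y in (0, w - 1)
            nb_bg = any(
                not mask[x + dx, y + dy]
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if 0 <= x + dx < h and 0 <= y + dy < w
            )
            if on_edge or nb_bg:
                pts.append((x, y))
    return pts


def _dist(p, q):
    return ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2) ** 0.5


def mad_oracle(seg_boundary, gt_boundary):
    return float(
        np.mean([min(_dist(p, q) for q in gt_boundary) for p in seg_boundary])
    )


def hausdorff_oracle(a, b):
    d_ab = max(min(_dist(p, q) for q in b) for p in a)
    d_ba = max(min(_dist(p, q) for q in a) for p in b)
    return float(max(d_ab, d_ba))


def dsc_oracle(seg, gt):
    inter = int(np.logical_and(seg, gt).sum())
    return 100.0 * 2 * inter / (int(seg.sum()) + int(gt.sum()))


def mcr_oracle(seg, gt):
    inter = int(np.logical_and(seg, gt).sum())
    return 100.0 * (1 - inter / int(gt.sum()))
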