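"""Automatic contour initialization.

Stage 1 of the pipeline: fit a two-class Gaussian mixture to the intensity
histogram of the denoised image, label pixels by maximum posterior (the
brighter class is bone/foreground), clean the label map into a single
smooth region per object, and build a binary-step level-set field whose
zero contour sits a couple of pixels *outside* the object boundary — the
evolution stage only ever moves the contour inward, so the initial contour
must enclose the object.

The EM fit is deterministic: means start at the 25th/75th intensity
percentiles (evenly spaced quantiles for general K), weights equal, and a
pooled standard deviation; no random restarts.  CT-style bimodal
histograms are well separated, so a quantile start lands in the right
basin and reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from skimage import morphology as skmorph

from .exceptions import InitializationError, InvalidInputError
from .morphology import DEFAULT_SE, StructuringElement

__all__ = [
    "MixtureModel",
    "InitialContour",
    "fit_gmm_em",
    "classify_pixels",
    "refine_mask",
    "build_initial_lsf",
    "initialize_contour",
]


@dataclass(frozen=True)
class MixtureModel:
    """K-component univariate Gaussian mixture fitted by EM."""

    weights: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    degenerate: bool = False  # single-component fallback was taken
    variance_floored: bool = False

    @property
    def k(self) -> int:
        return len(self.weights)

    def log_component_densities(self, x: np.ndarray) -> np.ndarray:
        """log(w_i) + log N(x | mu_i, sd_i^2), shape (K, *x.shape)."""
        x = np.asarray(x, dtype=float)
        mu = self.means.reshape((-1,) + (1,) * x.ndim)
        sd = self.stds.reshape((-1,) + (1,) * x.ndim)
        w = self.weights.reshape((-1,) + (1,) * x.ndim)
        return np.log(w) - 0.5 * np.log(2 * np.pi) - np.log(sd) - 0.5 * ((x - mu) / sd) ** 2


def fit_gmm_em(
    samples: np.ndarray,
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 200,
    std_floor: float = 1e-4,
) -> MixtureModel:
    """Fit a K-component Gaussian mixture with expectation-maximization.

    Parameters
    ----------
    samples
        Intensity values (any shape; flattened).
    k
        Component count; the segmentation pipeline uses K=2.
    seed
        Accepted for interface stability; the quantile-based start makes
        the fit deterministic without it.
    tol
        Stop when the log-likelihood improves by less than this.
    max_iter
        Iteration cap.
    std_floor
        Lower bound on component standard deviations (intensity units);
        prevents variance collapse on quantized images.

    Notes
    -----
    The per-iteration log-likelihood trace is recorded and is
    non-decreasing (the EM guarantee); tests assert it on every fit.
    """
    del seed  # deterministic initialization; kept for API compatibility
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 or not np.all(np.isfinite(x)):
        raise InvalidInputError("need at least two finite samples")
    if k < 1:
        raise InvalidInputError("k must be >= 1")

    degenerate = False
    if np.unique(x).size < max(2, k):
        # Fewer distinct values than components (e.g. a constant image):
        # moment fit with a single component, flagged.
        degenerate = k > 1
        k = 1

    q = (2 * np.arange(k) + 1) / (2 * k)
    means = np.quantile(x, q)
    if k > 1 and np.any(np.diff(means) <= 0):
        # Quantile ties (e.g. a minority class smaller than the quantile
        # spacing on quantized data) are a symmetric EM fixed point;
        # spread the starting means over the sample range instead.
        means = x.min() + q * (x.max() - x.min())
    stds = np.full(k, max(x.std(), std_floor))
    weights = np.full(k, 1.0 / k)

    trace: list[float] = []
    floored = False
    converged = False
    for _ in range(max_iter):
        model = MixtureModel(weights, means, stds, np.nan, np.empty(0), False)
        log_joint = model.log_component_densities(x)  # (k, n)
        log_norm = logsumexp(log_joint, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_joint - log_norm)  # responsibilities, (k, n)
        nk = resp.sum(axis=1)
        weights = nk / x.size
        means = resp @ x / nk
        var = (resp * (x - means[:, None]) ** 2).sum(axis=1) / nk
        new_stds = np.sqrt(var)
        if np.any(new_stds < std_floor):
            floored = True
        stds = np.maximum(new_stds, std_floor)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

    order = np.argsort(means)  # ascending means: component 0 dark, last bright
    return MixtureModel(
        weights=weights[order],
        means=means[order],
        stds=stds[order],
        loglik=trace[-1],
        loglik_trace=np.asarray(trace),
        converged=converged,
        degenerate=degenerate,
        variance_floored=floored,
    )


def classify_pixels(image: np.ndarray, model: MixtureModel) -> np.ndarray:
    """Maximum-posterior foreground mask from a two-component mixture.

    The component with the larger mean is foreground (bone is bright in
    CT).  Posterior ties are assigned to the foreground.
    """
    if model.k != 2:
        raise InitializationError(
            f"pixel classification needs a 2-component mixture, got K={model.k}"
            + (" (degenerate fit)" if model.degenerate else "")
        )
    log_post = model.log_component_densities(np.asarray(image, dtype=float))
    fg = int(np.argmax(model.means))
    bg = 1 - fg
    return log_post[fg] >= log_post[bg]


def refine_mask(
    mask: np.ndarray,
    min_area: int = 50,
    se: StructuringElement = DEFAULT_SE,
) -> np.ndarray:
    """Clean a raw label map into a smooth, well-defined foreground mask.

    Removes foreground components smaller than ``min_area``, fills enclosed
    background holes smaller than ``min_area``, then applies one binary
    closing with the default structuring element.  Anatomical holes (the
    foramen) are much larger than ``min_area`` and survive.
    """
    mask = np.asarray(mask, dtype=bool)
    # components/holes strictly smaller than min_area are removed
    out = skmorph.remove_small_objects(mask, max_size=int(min_area) - 1)
    out = skmorph.remove_small_holes(out, max_size=int(min_area) - 1)
    h = se.offsets[:, 0].max() - se.offsets[:, 0].min() + 1
    w = se.offsets[:, 1].max() - se.offsets[:, 1].min() + 1
    fp = np.zeros((h, w), dtype=bool)
    fp[se.offsets[:, 0] - se.offsets[:, 0].min(), se.offsets[:, 1] - se.offsets[:, 1].min()] = True
    out = skmorph.closing(out, footprint=fp)
    if not out.any():
        raise InitializationError("mask is empty after cleanup")
    return out


def build_initial_lsf(mask: np.ndarray, c0: float = 2.0, dilation_margin: int = 2) -> np.ndarray:
    """Binary-step level-set field enclosing the mask.

    The mask is dilated by ``dilation_margin`` pixels (disk) so the zero
    contour starts strictly outside the object, then ``phi = -c0`` inside
    the dilated mask and ``+c0`` outside.  No signed-distance
    reinitialization is performed; the internal energy term keeps the
    field regular during evolution.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InitializationError("cannot build a level-set field from an empty mask")
    if c0 <= 0:
        raise InvalidInputError("c0 must be positive")
    dmask = mask
    if dilation_margin > 0:
        dmask = skmorph.dilation(mask, footprint=skmorph.disk(int(dilation_margin)))
    if dmask.all():
        raise InitializationError("dilated mask covers the whole grid; no outside region")
    return np.where(dmask, -float(c0), float(c0))


@dataclass(frozen=True)
class InitialContour:
    """Result of the automatic initialization stage."""

    mask: np.ndarray  # refined foreground mask (before the enclosing dilation)
    lsf: np.ndarray  # binary-step phi: -c0 on the dilated mask, +c0 outside
    model: MixtureModel = field(repr=False, default=None)  # type: ignore[assignment]


def initialize_contour(
    image: np.ndarray,
    min_area: int = 50,
    c0: float = 2.0,
    dilation_margin: int = 2,
    em_seed: int = 0,
    em_tol: float = 1e-6,
    em_max_iter: int = 200,
    std_floor: float = 1e-4,
) -> InitialContour:
    """Full stage-1 pipeline on an already-denoised image.

    Fits the two-class mixture on all pixels, classifies, refines, and
    builds the enclosing binary-step field.  Raises
    :class:`InitializationError` on degenerate images or empty masks.
    """
    model = fit_gmm_em(image, k=2, seed=em_seed, tol=em_tol, max_iter=em_max_iter, std_floor=std_floor)
    raw = classify_pixels(image, model)
    if not raw.any():
        raise InitializationError("no foreground pixels after classification")
    mask = refine_mask(raw, min_area=min_area)
    lsf = build_initial_lsf(mask, c0=c0, dilation_margin=dilation_margin)
    return InitialContour(mask=mask, lsf=lsf, model=model)
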