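# vertseg

Automatic segmentation of bone-like objects in noisy 2-D gray-scale CT
slices, aimed at vertebral bodies: bright, roughly ring-shaped structures
with an interior dark foramen, protruding processes, locally weak
(low-contrast) boundary segments, thin parallel secondary edges, and
impulse noise. Manual contour initialization is the usual bottleneck of
level-set segmentation in this setting; `vertseg` removes it.

## Method

The pipeline is coarse-to-fine in two stages.

**Stage 1 — automatic initialization.** The slice is denoised with a
hybrid gray-scale morphological filter, `n` rounds of closing followed by
opening with a flat 3×3 element (closing first preserves weak boundaries
of bright objects while removing both dark and bright impulses). A
two-class Gaussian mixture

p(x | Φ) = Σᵢ ωᵢ G(x | uᵢ, θᵢ)

is fitted to the intensity histogram by EM (deterministic quantile
initialization); the brighter class, cleaned by component filtering, hole
filling and one binary closing, becomes the foreground mask. The initial
level-set field is the binary step φ = −c₀ inside the mask dilated by a
small margin, +c₀ outside, so the zero contour starts just *outside* the
object.

**Stage 2 — global level-set evolution.** The contour evolves by the
explicit flow

∂φ/∂t = μ div((1 − 1/|∇φ|) ∇φ) + λ g(∇I) δ_ε(φ) exp(MD(H_in, H_out)/η)

where the first term is distance regularization (no signed-distance
reinitialization needed), g = exp(−(|∇(G_σ∗I)|/r)^m) is an exponential
edge-stopping function, δ_ε a smoothed Dirac localizing the force to a
band around the contour, and MD the Mahalanobis distance between the
normalized gray-level histograms of the regions inside and outside the
contour — a global region-correlation factor that accelerates convergence
while the regions are well separated. The force is one-signed: the
contour shrinks from its enclosing initialization and freezes where g ≈ 0
(true edges, including weak ones and the interior foramen boundary).

Defaults are the empirical operating point n = 1, μ = 1.0, λ = 3.0,
σ = 0.7, η = 2.0, m = 2, r = 0.9. Evaluation uses four standard criteria:
Dice similarity coefficient (DSC), misclassification rate (MCR), mean
absolute boundary distance (MAD) and Hausdorff distance (HD).

A synthetic phantom generator produces vertebra-like slices with ground
truth (ring + processes + foramen, weak arc, double edge, texture,
exact-count salt-and-pepper), so the whole pipeline is testable without
clinical data.

## Worked example

```python
from vertseg import PhantomSpec, evaluate, generate_phantom, segment

image, gt = generate_phantom(PhantomSpec(seed=1, sp_level=0.03))
result = segment(image)
print(result.iterations, evaluate(result.mask, gt))
```

Running `python examples/03_segment_and_evaluate.py` prints:

```
converged  : True after 49 iterations
DSC        : 97.11%   (overlap with ground truth)
MCR        : 0.00%    (fraction of the object missed)
MAD        : 1.33 px  (mean boundary distance)
HD         : 4.12 px  (worst boundary distance)
```

i.e. on a 256×256 phantom with 3% salt-and-pepper noise the contour
converges in 49 iterations, covers the object fully (MCR 0) and sits on
average 1.3 px from the true boundary. The other scripts under
`examples/` demonstrate phantom generation, the initialization stage, the
noise-robustness sweep and the edge-stopping maps, one capability each.

## Command line

A thin CLI wraps the library:

```bash
vertseg phantom --out-dir out/ph --seed 0 --sp-level 0.05
vertseg segment out/ph/phantom.png --out-dir out/seg --seed 0
vertseg eval out/seg/mask_*.png out/ph/phantom_mask.png
vertseg sweep --out-dir out/sweep --seed 0
```

`segment` writes the mask (PNG), the final φ field (float TIFF), a
per-iteration diagnostics CSV (energy, contour change, Mahalanobis
distance) and a JSON log of every resolved parameter; artifacts are named
by the configuration hash and reruns are byte-identical. Exit codes
distinguish initialization failure (2), non-convergence (3) and contour
collapse (4). Configurations are versioned YAML files; unknown keys are
rejected.

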