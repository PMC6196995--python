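# Methods

## Scope and data model

`vertseg` segments a single bright, possibly genus-1 object (a vertebral
body with its foramen) in a 2-D gray-scale slice. Images are handled as
float arrays with intensities in [0, 1]; 8-bit and 16-bit PNG/TIFF inputs
are rescaled by the dtype maximum on load. All randomness in the package
lives in the phantom generator; the segmentation pipeline itself is
deterministic, so identical inputs give bit-identical outputs.

## Stage 1: denoising and automatic initialization

**Hybrid morphological filter.** Gray-scale erosion/dilation are defined
window-wise with the window clipped to the image domain — no padding
value is ever invented, so border pixels see only real data. One filter
iteration is a closing followed by an opening; closing first protects
weak boundaries of bright structures while the pair removes both
polarities of impulse noise. The iteration count `n` (default 1)
controls smoothing strength; a `growing` mode enlarges the element to
(2k+1)×(2k+1) at round k for users who want an alternating sequential
filter with increasing scale (both readings coincide at n = 1).

**Mixture fit.** A K = 2 Gaussian mixture is fitted to all pixels of the
filtered image by EM. Initialization is deterministic: means at the
25th/75th intensity percentiles, equal weights, pooled standard
deviation; when those quantiles tie (minority class smaller than the
quantile spacing on quantized data — a symmetric EM fixed point) the
starting means fall back to evenly spaced points over the sample range.
Stopping: |Δ log-likelihood| < 1e-6 or 200 iterations; standard
deviations are floored at 1e-4 intensity units (quantized or two-level
images would otherwise collapse a variance). The per-iteration
log-likelihood trace is recorded and is non-decreasing — asserted on
every fit in the tests. Constant images cannot support two components;
the fit falls back to one component, is flagged, and the pipeline
reports an initialization failure.

**Mask cleanup and the initial field.** Pixels go to the class with the
larger posterior (ties to the brighter class — bone is bright in CT).
Components and enclosed holes smaller than `min_area` = 50 px are
removed/filled and one binary closing is applied; anatomical holes (the
foramen, ~2000 px at default geometry) are far above the threshold and
survive. The initial level-set field is a binary step: −c₀ on the mask
dilated by a 2-px disk, +c₀ outside (c₀ = 2). The dilation matters
because the evolution force is one-signed (below): the contour can only
move inward, so it must start enclosing the object. No signed-distance
reinitialization is performed anywhere; the internal term keeps the
field regular.

## Stage 2: evolution

The energy is

E(φ) = μ ∫ ½(|∇φ| − 1)² + λ ∫ g(∇I) · H_ε(−φ) · exp(MD(H_in, H_out)/η),

with the second integral taken over the *interior* region (H_ε(−φ) ≈ 1
where φ < 0), and the gradient flow applied is

∂φ/∂t = μ div((1 − 1/|∇φ|)∇φ) + λ g δ_ε(φ) exp(MD/η),

with the histogram modulation treated as a frozen scalar within each
step.

**Histograms and the Mahalanobis factor.** Intensities are quantized
into L = 256 equal-width bins (the gray levels of an 8-bit image) and
counted separately for φ < 0 and φ ≥ 0; each histogram is normalized to
sum to 1. The covariance in the Mahalanobis form is not prescribed by
the model, so the package uses the multinomial-style diagonal
Σ = diag((h_in + h_out)/2) + 10⁻⁶ I — symmetric positive definite by
construction, scale-aware, cheap to invert; Σ = I (Euclidean) is
available as an option. With the diagonal choice, fully disjoint
histograms give MD → 2 regardless of L, so exp(MD/η) ranges over roughly
[1, e] at η = 2; the exponent is nonetheless capped at 50 as a
safeguard. Empty inside or outside regions signal contour collapse with
the iteration number.

**Edge-stopping function.** g = exp(−(|∇(G_σ∗I)|/r)^m) with σ = 0.7,
m = 2, r = 0.9, computed on the filtered image, central differences.
The rate r = 0.9 presumes gradients measured in gray-level units of
order 1 in flat tissue and ≫1 on bone edges. Because the package stores
intensities in [0, 1], gradients must be mapped to that unit: with
`gray_scale=None` (default) the unit self-calibrates so that the image's
median smoothed-gradient magnitude — a robust estimate of the noise
floor — lands at 0.25·r, capped at the plain 8-bit convention of 255 for
nearly noise-free images. Flat regions then cost the contour less than
~10% of its speed (g ≥ exp(−0.0625)) while structural edges, an order of
magnitude above the floor, freeze it. The calibration makes the edge map
invariant to affine intensity rescaling. A fixed scale (e.g. 255) can be
set explicitly. An optional gradient-vector-flow variant diffuses the
unit-normalized gradient field (Xu–Prince iteration, `gvf_mu` = 0.2, 80
steps, explicit scheme with reaction coefficient ≤ 1) and applies the
same exponential form to the GVF magnitude, widening the capture basin
around edges.

**Dirac pair.** The compactly supported raised-cosine pair is the
default: δ_ε(z) = (1 + cos(πz/ε))/(2ε) for |z| ≤ ε and exactly 0
outside, ε = 1.5 px. Compact support is essential here, not cosmetic:
the data force is one-signed, and a Dirac with tails (the arctan pair,
kept as an option) applies a non-negligible force on the ±c₀ plateaus
(δ(2)/δ(0) ≈ 0.36), which steadily raises the whole object interior
until it flips sign — the segmentation collapses from the inside. With
compact support the force touches only the contour band and plateaus are
exactly stationary.

**Internal term and stability.** The distance-regularization flux
(1 − 1/s)·∇φ (s = |∇φ|) is anti-diffusive for s < 1 and its magnitude
tends to 1, not 0, as s → 0; with an explicit scheme, any ripple on a
near-flat region therefore drives an O(1) flux and plateau noise grows
without bound. The implementation floors s at `grad_floor` = 1 inside
the coefficient, making the restoring force one-sided: regions steeper
than unit slope diffuse toward it, flatter regions are left alone. This
preserves the term's actual job (relaxing the binary step into a
unit-slope ramp near the contour, so the Dirac band is populated) and
makes the explicit update stable at dt = 1 with μ = 1. Users can lower
the floor to re-enable bounded two-sided behavior at their own time-step
risk.

**Convergence.** The contour is declared converged when it moves by
fewer than 0.1% of the image area (65 px at 256²) over a sliding window
of 20 iterations, with a cap of 300 iterations. A per-iteration change
threshold is too blunt here: pixel flips are episodic and single-
iteration changes essentially never exceed the threshold, which would
declare convergence before any motion happens; the windowed form
measures displacement on the timescale the contour actually moves
(~0.05 px/iteration during the approach).

**What the energy trace shows.** The printed functional is not a
Lyapunov function of the flow: the flow freezes exp(MD/η) per step, and
MD grows as the regions separate, which slightly outweighs the shrinking
edge-weighted interior area — so the recorded energy can drift up a few
per-mille while the segmentation monotonically improves. The descent
property that does hold (and is asserted in the tests) is per-step:
each update decreases the functional with the modulation held at its
pre-step value, in 100% of observed steps at the default time step.

## Phantom generator

The generator emulates the specific failure modes of vertebral CT
slices on a 256×256 grid: a ring of outer radius 70 px and inner radius
25 px (the foramen gives genus-1 topology) with three circular processes
of radius 16 px on the outer boundary; foreground/background levels
0.75/0.25 with Gaussian texture of SD 0.03; a 40° weak arc where the
rim's contrast is attenuated to 0.35 of its value over a 2-px band —
deliberately below the midpoint of the class means, so the global
mixture mislabels that rim and the enclosing dilation must bridge it; a
1-px secondary edge at intensity 0.55, offset 4 px inside the boundary
over a 60° arc (the "double boundary": a parallel edge the contour must
not stop at — it never reaches it, because the true boundary stops it
first); and salt-and-pepper noise corrupting an exact count ⌊level·N⌋
of distinct pixels (exact-count rather than Bernoulli corruption keeps
fixtures size-exact and test assertions sharp). The ground-truth mask
depends only on the geometry. These defaults are fixed study
conditions, not tuning knobs.

What the phantom does *not* emulate: beam hardening, partial-volume
blur, anatomical shape variability, inter-slice context, or structured
(non-impulse) noise. Passing on phantoms therefore demonstrates the
mechanics of the method — automatic enclosure, edge stopping, impulse
robustness, topology handling — not clinical-grade accuracy.

## Experiment protocol

The noise sweep runs {0, 1, 3, 5, 7}% corruption with 3 replicates per
level. Replicates use common random numbers: replicate r shares one
base phantom (geometry + texture) across all levels and only the
impulse corruption differs, so level-to-level comparisons are paired
and the noise effect is not confounded with texture realization. Mean
DSC then degrades strictly monotonically (≈97.4% → ≈96.7%). Iteration
counts to convergence are essentially flat across noise levels (~43 ± 2):
the morphological filter removes the impulses before the contour ever
sees them, so convergence time carries no noise signal in this regime.

## Known limitations

- The evolution force is one-signed: under-segmenting initializations
  (contour starting inside the object) cannot be recovered. The
  initialization stage is responsible for enclosure.
- The global histogram factor is spatially constant; it modulates the
  overall speed, not where the contour stops. Boundary localization
  rests entirely on the edge-stopping function.
- A few 1-px foreground satellites can freeze in the approach corridor
  where the edge map has speckle minima; they are visible to the
  Hausdorff metric but negligible for DSC/MCR/MAD.
- Single object class per slice (K = 2); no shape prior, so pathological
  occlusions or breaks in the cortical rim are out of scope.
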