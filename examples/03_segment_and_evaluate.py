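"""Full pipeline: denoise, auto-initialize, evolve, score.

The level-set contour shrinks from just outside the object under an
edge-stopped force modulated by the Mahalanobis distance between the
inside/outside gray-level histograms, and freezes on the boundary.
"""

from vertseg import PhantomSpec, evaluate, generate_phantom, segment

image, gt = generate_phantom(PhantomSpec(seed=1, sp_level=0.03))
result = segment(image)

scores = evaluate(result.mask, gt)
print(f"converged  : {result.converged} after {result.iterations} iterations")
print(f"DSC        : {scores['dsc']:.2f}%   (overlap with ground truth)")
print(f"MCR        : {scores['mcr']:.2f}%    (fraction of the object missed)")
print(f"MAD        : {scores['mad']:.2f} px  (mean boundary distance)")
print(f"HD         : {scores['hd']:.2f} px  (worst boundary distance)")
print(f"histogram separation (Mahalanobis) rose from "
      f"{result.md_trace[0]:.3f} to {result.md_trace[-1]:.3f} during evolution")
# A DSC in the high 90s with MAD near one pixel means the contour hugs the
# true boundary, including the interior foramen and the weak arc.
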