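# Methods

`vesselwalk` segments retinal blood vessels in fundus photographs with a
four-stage unsupervised pipeline: (1) working-channel extraction and
field-of-view (FOV) masking, (2) multiscale Hessian vesselness
enhancement, (3) centerline extraction from the divergence of the
normalized gradient vector field corrected by a morphological skeleton,
and (4) seeded random-walker segmentation on a vesselness-weighted
8-connected lattice, with seeds placed automatically around the
centerlines.  This note records the model, the parameters that matter,
the numerical choices, and what the synthetic phantoms do and do not
establish.

## Working image and field of view

The green channel of the RGB photograph carries the best
vessel/background contrast and is the working image `I_g`; intensities
are normalized to [0, 1] at load, and every parameter below is
interpreted on that scale.  The circular camera aperture is estimated
from the red channel (brightest inside the aperture): threshold at 0.15
of the red maximum, keep the largest 4-connected component, open with a
3-px disc, fill holes.  All computation and evaluation is restricted to
this FOV.

## Vesselness

At scale σ the Hessian of the Gaussian-smoothed image has eigenvalues
λ1 ≤ λ2 (signed order).  A dark tube gives λ2 ≫ 0 across the vessel and
λ1 ≈ 0 along it.  With s² = λ1² + λ2² and the fractional anisotropy
FAH = |λ1 − λ2| / √(λ1² + λ2²), the single-scale score is

    ν(σ) = 0                                  if λ1 > 0
    ν(σ) = (1 − exp(−s²/2c²)) · exp(FAH − 1)  otherwise

with c = 0.2.  FAH is clipped to [0, 1] before exponentiation (it can
mathematically reach √2 for eigenvalues of opposite sign and equal
magnitude), so ν ≤ 1, and ν = 1 exactly characterizes a strong pure
line.  An alternative anisotropy factor exp(−1/FAH) is available via
`exponent_form="neg_inverse"`.  The final map is the pixelwise maximum
of ν over the scale ladder σ = 0.2·m, m = 1…25, with γ-style scale
normalization (second derivatives multiplied by σ²) so that the
maximum selects the scale matched to the vessel calibre; without it the
maximum degenerates to the smallest scale.  The eigenvector of λ2 at
each pixel points across the vessel and is reused for seed placement.

**Derivative kernels.**  Sampled derivative-of-Gaussian kernels break
down at the sub-pixel scales of the ladder: the truncated
second-derivative kernel at σ ≲ 0.5 no longer annihilates constants and
degenerates toward a scaled negative identity, which floods the
response map with an intensity-proportional artifact.  The kernels used
here are sampled analytic Gaussian derivatives with enforced moment
conditions — order 0 sums to 1, order 1 maps a unit ramp to exactly 1,
order 2 annihilates constants and maps x² to exactly 2 — and converge
to the central-difference stencils [−1/2, 0, 1/2] and [1, −2, 1] as
σ → 0.  Boundary handling is reflective throughout.

## Centerlines

Two detectors are fused.

**Divergence candidates.**  The gradient field F = ∇g(σ) of the
smoothed image points away from a dark axis on both sides, so the
normalized field NF = F/|F| has a sharp positive divergence ridge along
the axis.  For every pair of rotation angle θ = nπ/8 (n = 0…7) and
scale σ from the same ladder, the field is rotated by θ, its divergence
is taken by central differences, pixels with divergence > φ = 0.45 are
kept, and 8-connected components smaller than δ = 50 px are dropped;
the candidates C_can are the union over all 200 (θ, σ) pairs.  Two
guards make this robust:

* *Noise gate.*  Normalization erases magnitude, so in flat regions
  pure noise yields unit vectors with random directions whose
  divergence has standard deviation ≈ 0.7 — above any usable φ.  A
  vessel axis, unlike noise, lies between flank gradients that stand
  out from the noise floor.  Candidates therefore require a gradient
  magnitude within 2 px exceeding max(0.01, 4 × the per-scale noise
  gradient level), where the noise level is the product of the image
  noise σ̂ (Immerkær's Laplacian estimator) and the derivative kernel's
  L2 norm.  This adapts automatically across scales: it is strict at
  σ ≈ 0.2 where noise dominates and permissive at σ ≥ 1 where wide,
  low-gradient vessels live.
* *Rim margin.*  The aperture rim is itself a high-contrast circular
  edge whose expanding gradient pattern mimics a vessel; candidates are
  restricted to the FOV eroded by 5 px.

**Morphological skeleton.**  A sum of bottom-hat transforms (closing
minus original) over 1-px-wide linear structuring elements of lengths
2–12 px (step 2) and orientations 0…7π/8 (step π/8) highlights dark
structures of all calibres and directions.  The image is pre-smoothed
at σ = 1 px — below the smallest structuring element — so sensor noise
does not enter the morphology.  The summed response, rescaled by its
maximum, is binarized by Otsu's threshold computed over in-FOV pixels
only (the black exterior would otherwise dominate the histogram), and
thinned to a 1-px skeleton C_skel.  Thinning runs to fixpoint, removes
no connectivity, and is delegated to scikit-image's `morphology.thin`.

**Correction.**  With C_inter = C_skel ∧ C_can, both masks are split
into 4-connected regions and a region survives iff more than 40% of its
pixels lie on C_inter *dilated by 1 px* — the dilation is needed
because a 1-px skeleton can never cover 40% of a 2–3-px-wide candidate
band, and without it the rule systematically discards exactly the
well-detected vessels.  The union of surviving regions, cleaned of
components under 10 px (`min_length`), is the final centerline mask.

## Random walker

Every in-FOV pixel is a node; 8-neighbors are joined with weight
w_ij = exp(−β (v_i − v_j)²), β = 90, where v is the guide image.
Diagonal edges use the same formula (no distance correction).  The
guide is the multiscale vesselness, linearly stretched to full [0, 1]
range over the FOV and then square-rooted (`guide_stretch`,
`guide_gamma = 0.5`).  Both steps condition the guide for the fixed β:
the raw response magnitude depends on image contrast (on [0, 1]
intensities with c = 0.2 its peak is ≈ 0.2, which would leave the
lattice effectively unweighted), and the amplitude scaling spreads
contrast from the response peak at the axis toward the vessel
outskirts, so the walker's boundary settles at the visible vessel edge
rather than partway down the response spike.

**Seeds.**  Every centerline pixel is a foreground seed.  For each one,
background candidates are placed at round(p ± d·u) with u the
cross-vessel eigenvector, where d = R_mid + 1 = 8 in *dense* areas and
d = R_max + 1 = 13 in *sparse* areas (one pixel beyond the largest
radius a vessel can have; R_min = 2 and R_max = 12 px bracket retinal
vessel radii and R_mid = 7 is their midpoint).  A centerline pixel is
dense iff the centerlines dilated by an R_mid disc split into more than
one 8-connected region within the square window of half-width 2·R_mid
around it — i.e. another vessel runs close enough that a far seed might
land on it.  Candidates outside the FOV, on a foreground seed, or
within 1 px of any centerline pixel are dropped.  Two further
candidates per pixel are placed *along* the vessel direction with a
2-px exclusion zone: for interior pixels they fall on the centerline
corridor and cancel, but at vessel tips they close the otherwise
unseeded region beyond the end, which the walker would flood.

**Solve.**  The foreground probability is 1 at foreground seeds, 0 at
background seeds, and harmonic elsewhere: the unlabeled block of the
graph Laplacian is solved directly by sparse LU.  A direct solve is
used deliberately — the reduced Laplacian is SPD but severely
ill-conditioned (weights span e^−β), where residual-based stopping of
conjugate gradients certifies convergence while leaving errors of
~10⁻³ in the solution, and sparse LU is in fact faster at image sizes.
Lattice components containing no seed get probability 0 with a warning.
The mask is u ≥ 1/2 (per-pixel argmax over the two labels; ties to
vessel), intersected with the FOV.

## Evaluation

Pixelwise sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
(TP+TN)/total, counted over in-FOV pixels only; batch mode reports
per-image metrics and their arithmetic mean.  The Dice coefficient
2|A∩B|/(|A|+|B|) is reported alongside.

## Synthetic phantoms

The generator renders dark vessel trees (polylines with constant
half-width 1–6 px, i.e. full widths 2–12 px) on a brighter shaded
background inside a circular aperture, with optional bright lesion
blobs and additive Gaussian noise (default sd 0.02 on [0, 1]).  The
default cross-profile is Gaussian with its width fixed by the
half-width-at-half-maximum convention: a vessel of nominal half-width h
has profile sd h/√(2 ln 2), so the ground-truth band edge |d| = h is
exactly the half-depth contour — the standard, instrument-independent
definition of a width, and the only convention under which the stated
band is an optically meaningful target.  A flat profile mode stresses
the thinning path; a projected-cylinder profile is not modelled.  The
radial shading vignettes center-bright/rim-dark, as fundus optics do;
note that the opposite sign would put positive tangential curvature
under every vessel axis and the hard λ1 > 0 gate would veto the
response at large scales.  Five canonical phantoms cover a straight
tube, a Y-bifurcation, a close parallel pair (exercising the dense
classification), a curved vessel among three bright lesions, and a
six-branch tree spanning the full width range.

What the phantoms do *not* emulate: the optic disc and fovea, central
light reflexes on wide vessels, non-white noise, JPEG artifacts, and
the density and tortuosity of a real vascular network.  Passing the
phantom suite therefore establishes the correctness of each operator
and the end-to-end plumbing under controlled conditions — not clinical
performance; results on real fundus data (e.g. STARE via the `batch`
command) must be evaluated against expert annotations.

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `sigmas` | 0.2·m, m=1…25 | Gaussian scale ladder (px) |
| `c` | 0.2 | vesselness contrast constant |
| `thetas` | nπ/8, n=0…7 | rotation angles for the divergence detector |
| `phi` | 0.45 | divergence threshold |
| `delta` | 50 | min candidate component (px) |
| `grad_floor` / `noise_gate` | 0.01 / 4.0 | absolute / noise-relative flank-gradient gate |
| `se_lengths` / `se_angles` | 2–12 step 2 / 0…7π/8 | bottom-hat structuring lines |
| `overlap_frac` | 0.40 | region-overlap threshold in the correction |
| `min_length` | 10 | min final centerline component (px) |
| `r_min`, `r_mid`, `r_max` | 2, 7, 12 | vessel radius range and midpoint (px) |
| `beta` | 90 | random-walker edge sharpness |
| `guide_stretch`, `guide_gamma` | True, 0.5 | guide conditioning |
| `solver_tol` | 1e-8 | linear-solve residual check |

## Problem sizes

The phantom suite uses 256×256 images (≈ 45 000 FOV pixels; full
pipeline ≈ 1.5 s per image), which exercises every code path including
the dense/sparse seeding split; the method itself is resolution-
independent and the same configuration runs unchanged on 605×700
photographs.

## Known limitations

* The walker boundary follows the vesselness falloff; for a Gaussian
  cross-profile the response zero-crossing sits slightly inside the
  half-maximum edge, so the widest vessels are segmented marginally
  thin.
* Background seeding assumes the cross-vessel eigenvector is reliable
  at centerline pixels; at junctions the direction is ill-defined and
  an occasional candidate is wasted (dropped by the exclusion rules).
* Otsu binarization of the bottom-hat assumes vessels occupy a
  non-negligible fraction of the FOV; on nearly vessel-free images the
  skeleton becomes noise-dominated and the correction stage is the
  only line of defense.
* The divergence detector's noise gate assumes approximately white
  noise; strongly correlated texture (as in pathological regions of
  real images) is handled only by the φ/δ thresholds.
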