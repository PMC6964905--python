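# Methods

`remodelkit` quantifies extracellular-matrix (ECM) remodeling and
cell–matrix interaction in collagen and collagen–Matrigel hydrogels from
fluorescence microscopy.  Six measurement pipelines share a common image
container (`ImageStack`: a `[z][y][x]` intensity grid with physical voxel
spacing in μm) and a ground-truthed synthetic-scene generator that makes
every stage testable end to end without microscope data.  This note
records the models, the parameters that matter, the numerical choices
made where the design was open, and what the synthetic validation does
and does not show.

## Fiber-network morphometry

**Binarization.** A Gaussian prefilter (σ = 1 voxel by default) is
followed by a per-pixel Otsu threshold computed in a sliding square
window (default 65 px, ≈ 6.4 μm at 0.099 μm/px — wide enough to straddle
several pores).  A window contributes foreground only if its local
standard deviation exceeds a noise floor of twice the background median
absolute deviation.  The background MAD is estimated from horizontal
first-difference residuals, which is blind to structure: a whole-image
MAD would measure the fibers themselves on clean or dense images, while
pure-noise windows have std ≈ σ, safely below the 2×MAD ≈ 1.35 σ floor.

**Tracing.** The mask is skeletonized and the skeleton decomposed into
branches between endpoints and junction clusters.  Branches are merged
across a junction when the straight-through turning angle (estimated
from the last 4 voxels of each branch) is at most `max_turn_deg`
(default 35°), pairing smallest angles first, each branch end at most
once.  Shallow crossings skeletonize into two nearby Y-junctions joined
by a short stub; junction clusters connected by a stub shorter than
`junction_fuse_px` (default 8 px) are fused so such a crossing behaves
as a single four-way junction and both fibers are traced straight
through.  Fibers shorter than `min_fiber_um` (default 2 μm) are
discarded.  Node coordinates are converted to μm with the anisotropic
voxel spacing.

**Mean fiber length** is the mean polyline arc length.
**Persistence length** is fit from pooled tangent correlations: polylines
are resampled at a uniform arc step (default: the median native segment
length), ⟨cos Δθ(s)⟩ is accumulated in arc-separation bins up to half
the mean fiber length, and the decay is fit by weighted least squares on
the log-correlation.  The planar convention ⟨cos Δθ⟩ = exp(−s/2Lp) is
used for 2D networks and exp(−s/Lp) for 3D.  Perfectly straight networks
(no decay) return `inf`.  For a von Mises turning-angle walk the decay
is exactly (I₁(κ)/I₀(κ))ⁿ per n steps, giving the closed-form truth
Lp = −step / (2 ln(I₁/I₀)) used by the recovery tests.
**Pore size** is twice the median of the Euclidean distance transform of
the background evaluated at its regional maxima — the "largest inscribed
sphere" family, deterministic and checkable against slab geometry
(parallel plates with spacing S and thickness t give S − t, up to the
half-voxel pixel-center offset on odd gaps).

## Anisotropy index

A square patch (side ≥ 32 px) is mean-subtracted, Hann-windowed, and its
2D power spectrum restricted to a radial band (default 4/side to
0.45 cycles/px, excluding DC, low-frequency illumination and the Nyquist
corners).  Spectral power is reduced to the 2×2 second-moment
orientation tensor over frequency direction (axial, period π);
α = (λ₁ − λ₂)/(λ₁ + λ₂) is its eigenvalue contrast.  α is 0 for an
isotropic network, 1 for perfect alignment, and the leading eigenvector
rotated by 90° gives the dominant real-space orientation (a stripe
pattern's spectrum is perpendicular to the stripes).  A featureless
patch returns α = 0 by convention.  On 300-fiber isotropic fields the
estimator's sampling bias keeps mean α below 0.15; a stripe field
reaches ≥ 0.99.  For 3D stacks α is computed per slice or on a maximum
intensity projection (configurable; the choice matters little for thin
remodeling stacks).

## Moment-preserving (Tsai) threshold and densification

The grey-level histogram is replaced by a two-level distribution
{z₀ with fraction p₀, z₁ with 1 − p₀} constrained to preserve the first
three grey-level moments; z₀, z₁ are the roots of the quadratic whose
coefficients solve the moment system, p₀ = (z₁ − m₁)/(z₁ − z₀), and the
threshold is the smallest grey level whose cumulative fraction reaches
p₀.  The solved distribution preserves the moments to machine precision
(residuals < 1e−12 in tests); only the final cut quantizes p₀ to the
histogram.

Collagen density is the fiber-pixel fraction inside a region of
interest after binarizing the *whole* image once with this threshold —
per-ROI thresholding would make control and peri-cellular densities
incomparable.  Regions are 100×100 px control/alignment windows and a
"doughnut" band of fixed physical thickness (default 7 μm) around each
cell mask, computed as the set of background voxels within the band
distance of the cell (anisotropic EDT; sub-voxel thickness clamps to a
one-voxel rim; bands of neighbouring cells are computed independently
and may overlap).

## Degradation volumetry

DQ-collagen stacks are binarized with the moments threshold, closed
with a physically spherical structuring element (z radius scaled by
dx/dz; default radius 2 px), and cleaned with a binary median filter
(default radius 1 px); the order threshold → closing → median is fixed.
Closing and median radii are exposed because no canonical values exist;
the defaults are the smallest scales that realize the intent (fill
1-voxel gaps, remove isolated voxels).  Total volume is the foreground
voxel count times the voxel volume; components are counted with
26-connectivity; the per-cell figure divides by an explicit cell count
or the component count of a supplied cell mask.  A per-slice 2D mode
reproduces plane-by-plane processing when strict fidelity to 2D tools
is wanted.

## Focal-adhesion detection

**2D** (immunostained cells on gels), fixed order with defaults from the
published parameter table: median filter (radius 2 px) → rolling-ball
background subtraction (radius 50 px; the radius is not published — 50 px
removes smooth cytoplasmic background while preserving ≤ 2 μm punctae;
run at 4× downscale for large radii, as is conventional) → CLAHE
(block 19 px, 256 bins, slope 6; the slope maps to a clip limit of
slope/nbins, both expressing the histogram clip relative to the uniform
bin height) → exponential remap v′ = (e^{γv} − 1)/(e^γ − 1) with
γ = ln 256 (monotone, convex, full-range; suppresses dim background) →
linear contrast stretch saturating 0.35% per tail → Laplacian of
Gaussian, σ = (5, 5) px, negated so blobs are maxima → iterative
intermeans threshold computed within the cell mask → 3×3 binary closing
→ particle analysis keeping area ≥ 50 px² and circularity 4πA/P²
(Crofton perimeter, clipped at 1) within [0, 1] — the published range
makes the circularity filter a no-op, retained for config completeness.
Areas are reported in px² (the published size filter is in pixels) with
a μm² column alongside.

**3D** (mCherry-vinculin cells in gels): 3D median (1-voxel radius) →
per-slice rolling ball (10 px) → gamma adjustment on the [0, 1]
normalized stack.  "Gamma 2.1" is directionally ambiguous; v^{1/2.1} is
used because the stated purpose is enhancing hyperintense adhesions
before a fixed threshold (v^{2.1} would crush them toward the
background).  The fixed threshold is user-set on the post-gamma scale
(for synthetic scenes with known peaks, the blob half-maximum
0.5^{1/2.1} ≈ 0.72 is the natural choice and makes the detected support
match the half-max footprint); when unset, the 99th percentile of the
post-gamma stack stands in.  Touching adhesions are split by watershed
on the negated EDT seeded at h-maxima deeper than `watershed_dynamic`
(default 0.5 μm).  Note that equal-depth twin lobes never merge under
h-maxima regardless of the dynamic — dynamics are measured against a
strictly higher peak.  Components smaller than 4 voxels are rejected as
sub-resolution specks.  Finally, any adhesion whose centroid lies
within 5 μm of the nucleus (anisotropic EDT of the nucleus mask) is
discarded as Golgi/reticulum-associated vinculin.

**Empty-scene guard.** Both detectors first check that the cell (2D) or
stack (3D) contains hyperintense structure at all: the 99.9th percentile
must sit at least 5 robust σ (1.4826 × MAD) above the median of the
pre-enhancement intensities.  Without the guard, the contrast chain
(CLAHE, EXP, intermeans) faithfully manufactures "particles" out of pure
noise; with it, a noise-only image yields an empty set.  Gaussian noise
alone peaks near 3–4 robust σ, and punctae at the design SNR of 10 sit
far above, so the guard is inert on real scenes.

## Motility

Frames are CLAHE-enhanced (block 64 px, 256 bins, slope 3), segmented by
the two-phase region-mean partition — the iterative intermeans fixed
point, initialized at mid-range so that it lands between the background
and cell modes even when cells occupy a fraction of a percent of the
frame (a mean-initialized iteration collapses into the background mode
in that regime) — and components of at least `min_area_px` (20) become
detections with centroids in μm.  Linking is greedy mutual nearest
neighbour between consecutive frames: a link requires both detections to
choose each other and distance ≤ `max_disp_um` (default 30 μm/frame,
about twice the fastest per-frame step expected at ~12.5 μm/h);
unmatched detections start new tracks; there is no gap closing or
division handling.  Per track, accumulated distance AD = Σ‖p(t+1) − p(t)‖
and speed = AD / elapsed hours; MAD and mean speed average these over
tracks spanning at least 75% of the acquisition (configurable to all
tracks).  When all tracks span the full acquisition T, mean speed equals
MAD/T exactly.

## Synthetic scenes

The generator provides the statistical structure each pipeline assumes,
with all ground truth computed from geometry before rasterization and
noise, and bitwise determinism under a fixed seed.

* **Fiber fields** are persistent random walks: initial orientations
  follow an axial von Mises law about θ₀ (doubled-angle construction,
  orientations mod π; concentration `kappa_orient`, 0 = isotropic,
  ≥ 1e6 treated as the aligned limit), per-step turns follow von Mises
  (0, `kappa_step`), each fiber has contour length `length_um`
  (default 15 μm, the scale of collagen fibers in these gels; the
  parameter exists because a walk needs a length).  Polylines are
  rasterized with a Gaussian cross profile (half-width `radius_px`) and
  Gaussian read noise plus optional Poisson shot noise are added last.
* **Adhesion scenes** place Gaussian punctae inside an ellipse/ellipsoid
  cell with a minimum centre separation (default 25 px in 2D) so that
  recovery tests have unambiguous counts; sizes are half-maximum
  footprints, default 100–200 px² ≈ 1–2 μm² at 0.099 μm/px — the size
  of mature adhesions and the scale the σ = 5 px LoG filter is matched
  to.  3D scenes can restrict punctae to beyond the perinuclear band
  (adhesions sit at protrusions).  Default peak/noise ratio is 10.
* **Degradation scenes** scatter raster-filled near-cubes of exactly
  `blob_vox_each` voxels, pairwise separated by more than the closing
  diameter, so the expected total volume is exact.
* **Time-lapses** render discs taking fixed-length steps in random
  directions (plus optional drift) with pairwise separation never below
  4 cell radii (or an explicit minimum), guaranteeing unambiguous
  linking; defaults mirror a 15-min-interval, 12-hour acquisition
  (49 frames).

What the generator does *not* emulate: a confocal point-spread function
and axial blur, photobleaching, intensity inhomogeneity, cell
protrusions and shape change, fiber bundling, and out-of-plane fiber
curvature.  Passing recovery tests therefore demonstrates the
correctness of the measurement chain on images with the assumed
statistical structure, not performance on real acquisitions — the
published biological values (morphometrics, anisotropy levels, degraded
volumes, adhesion counts, MAD) were measured on microscopy data that is
not deposited and are not reproduction targets.

## Numerical choices and limitations

* Coordinates are 0-based voxel indices; positions are voxel centres;
  physical position = index × spacing.
* `um_to_px` rounds to the nearest voxel and clamps at 1, so sub-voxel
  bands select a one-voxel rim.
* Distance-based quantities (pore size, band membership, EDT watershed,
  perinuclear exclusion) use anisotropic sampling throughout.
* Skeleton thinning (scikit-image, Zhang/Lee) is not exactly equivariant
  under 90° rotation; pore size (EDT-based) is rotation-exact, but the
  traced mean fiber length can shift by several percent on dense meshes
  (held to 10% at moderate density in tests).  Junction-dense meshes
  also fragment fibers, biasing mean length low relative to generated
  contour length.
* Detected 2D adhesion areas reflect the thresholded LoG support; for
  punctae much smaller than the LoG scale this overestimates the
  half-max footprint (blob broadening), for much larger punctae it
  underestimates.  At the matched scale the two effects cancel.
* Problem sizes in tests and the acceptance script (256–512 px planes,
  ≈ 32×160×160 stacks, 10–20 seeds per stochastic check, 500 fibers for
  persistence recovery) were chosen as the smallest scenes that leave
  the estimators' sampling error well inside the asserted tolerances.
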