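# Methods

`mrdistcorr` maps and corrects the 3D system-related geometric distortion of
an MR scanner using a grid-sheet phantom imaged in CT (taken distortion-free,
providing the world coordinates of the grid crossings) and in MR in three
orthogonal orientations, each with forward and reversed read gradient.  This
note records the model, the numerical choices, and what the built-in
simulator does and does not emulate.

## The measurement model

The phantom is a 30 cm box of 17 styrene grid sheets in mineral oil; each
sheet carries a 17x17 lattice of bar crossings at 15 mm pitch, sheets are
7.6 mm thick with 9 mm oil gaps (16.6 mm sheet pitch).  A grid sheet only
defines control points in its own plane, so one acquisition measures, per
control point, the two *in-plane* components of the displacement field
delta(x) = x_MR − x_CT.  The through-plane coordinate of a sheet is known
only as its apparent (distorted) position — which is exactly how the
samples are housed here: in-plane coordinates from the matched CT point,
through-plane coordinate from the detected (MR) sheet position.

Combining transverse (x,y), sagittal (y,z) and coronal (x,z) acquisitions
gives a double estimate per axis:

    dx0 = (dx_tra + dx_cor)/2,  dy0 = (dy_tra + dy_sag)/2,
    dz0 = (dz_sag + dz_cor)/2.

This *first-order estimate* is biased wherever the field has through-plane
gradients, because each orientation's in-plane values are housed at
apparent through-plane positions.  The *iterative refinement* re-evaluates
each component with the lookup coordinate displaced by the current estimate
of that orientation's through-plane component:

    dx_n: transverse map at (x, y, z + dz_{n-1}), coronal at (x, y + dy_{n-1}, z)
    dy_n: transverse at (x, y, z + dz), sagittal at (x + dx_n, y, z)
    dz_n: sagittal at (x + dx_n, y, z), coronal at (x, y + dy_n, z)

(axes updated Gauss–Seidel style in a configurable order; an alternative
formulation evaluates one combined map at the fully displaced point — we
keep the two-orientation split through the iteration, since each
orientation's map is apparent only along its own normal).  Iteration stops when the
largest per-point change of all three components is simultaneously below
the cutoff phi (default 0.2 mm), typically within 2–4 passes: the update is
a fixed-point contraction whose rate is the product of through-plane field
gradient (~0.1 mm/mm here) and displacement magnitude.  If the gap grows
instead, the first-order values are returned flagged as non-converged.

B0 inhomogeneity shifts structures along the read axis with a sign that
follows the read-gradient polarity; averaging the forward- and
reverse-acquired point positions coordinate-by-coordinate removes it before
registration.

## Control-point detection

Per slice perpendicular to the sheet normal: MR inversion (grid bright on
dark, like CT); unsharp masking (sigma = 3 pitches) against smooth
intensity bias; a per-slice threshold at 0.25x the median of the positive
unsharp response (low enough to keep partial-volume bar pixels, which drop
to ~25% of a full bar when a 2 mm bar straddles two coarse pixels); then a
line-crossing detector:

- the thresholded grayscale (not the 0/1 mask — binary gating would
  quantize bar centers to whole pixels and destroy sub-voxel accuracy) is
  opened with a ~7.5 mm grayscale *line* element along each axis, so only
  structures extending at least half a pitch survive: air bubbles are
  compact and vanish here, which is what makes detection bubble-proof;
- each opened image is blurred with a 1D Gaussian (sigma = pitch/3) along
  its axis: a response to lines running along that axis;
- the *product* of the two responses, lightly smoothed, peaks only at
  crossings (the sum used in early experiments leaves too little contrast
  between crossings and bar interiors);
- an arm-validity map requires the line responses to persist 0.6 pitch
  away on both sides in both axes, vetoing bar tips and any remaining
  compact blobs;
- solid bright areas (container walls/air, frame, couch) are vetoed by a
  morphological opening wider than a bar on a strict brightness mask, with
  the veto dilated so a solid region's fringe cannot pose as a line;
- surviving response peaks are cut at 70% of a local maximum (window 1.5
  pitches, so every candidate competes with a genuine crossing) with a
  global floor, split by watershed, and size-filtered.

Dot positions are intensity-weighted centers of mass of the gated grayscale
over the dot region, refined with an iteratively re-centered symmetric soft
window (region-shape asymmetries then cancel).  Per-slice detections are
merged into one point per crossing per sheet by grouping *per in-plane
node* across the whole stack and splitting each node's appearances at
through-plane gaps: per node the inter-sheet gaps are empty even when
strong through-plane field variation smears the sheet stack so that no
slice between sheets is empty.  The mass-weighted mean of the contributing
slice positions localizes the sheet at sub-voxel precision.  Slices whose
best dot response falls below 10% of the median occupied-slice response are
treated as grid-free (oil gaps, noise); sheet clusters with far fewer
points than the median sheet are discarded as stray structure.

Detection is deterministic and invariant to global intensity scaling and to
smooth multiplicative bias (all cutoffs are relative).  Residual false
points (<~1% under strong warps, at the phantom boundary) are removed by
the per-sheet third-order polynomial cleaning during registration — the
polynomial is used only to reject outliers, never as the distortion model.

## Registration and correspondence

The phantom is mounted reproducibly, so registration is a pure translation:
z from aligning the CT z-extent midplane with the MR isocenter plane, x/y
from the point pair nearest the isocenter, where distortion is negligible.
The single transverse CT point set is reformatted for the rotated MR
acquisitions by permuting coordinate axes (equivalent to re-slicing the CT
volume, without interpolation loss).  Matching assigns each CT point its
nearest MR point within half a pitch (7.5 mm), resolving conflicts in favor
of the closest pair; fields up to ~6 mm leave this unambiguous.

## Interpolation

Per orientation, the samples form a regular in-plane lattice on each sheet,
but the sheets sit at warped apparent positions.  The orientation maps use
bivariate cubic splines in-plane (per sheet) and a non-uniform Catmull–Rom
cubic across the warped sheet stack.  In-plane queries beyond the lattice
(the common lattice's 16.6 mm-pitch axis extends past the rotated lattices'
15 mm-pitch extent) follow ghost lines extrapolated linearly from the edge
lines; a curvature-based extension was tried and rejected — spline
curvature at the boundary of noisy data is so poorly conditioned that a
1 cm extrapolation produced multi-millimetre excursions, while the linear
ghost amplifies the per-point noise only modestly.  Through-plane queries
beyond the stack extend linearly up to one pitch and clamp beyond.

The final correction map interpolates the converged samples on the regular
CT lattice with a tensor cubic B-spline (exact at the sites), with ghost
planes linearly extrapolated one pitch out and clamping farther away.
Sites that do not form a lattice fall back to scattered linear
interpolation with nearest-neighbour extension.

## Correction

delta is defined as MR − CT at CT sites, and the simulator's forward model
places a structure truly at x at x + delta(x).  Correction therefore
resamples the distorted volume at x + delta(x) for every output voxel
(cubic spline intensity interpolation, no Jacobian modulation), making the
simulate→correct round trip exact by construction.  For patient volumes not
centered on the isocenter, the in-plane shift is FOV/2 − header position,
applied before map lookups.

## The simulator

Ground truth for every stage.  The phantom is rasterized with exact
separable partial-volume coverage (1D coverage per axis; in-plane union
a + b − ab), so nominal centroids are sub-voxel exact by construction.  The
stand-in scanner field is a per-axis degree-3 polynomial: an odd radial
term (the leading behaviour of gradient nonlinearity) plus a Chebyshev T3
term along one through-plane axis that steepens the field toward the
volume edges, normalized over the phantom extent (bars included) and scaled
to a 5.5 mm maximum over the control-point volume — matching the regime the
method is designed for, with through-plane gradients (~0.12 mm/mm) strong
enough that first-order estimation visibly underperforms the iteration.
The real scanner field's functional form is unknown; this family is a
stand-in and is flagged as such.  B0 is modeled purely as a polarity-signed
read-axis displacement (default ~1 mm at the volume edge).

MR degradations: a smooth multiplicative bias field (seeded Gaussian blobs,
normalized to the requested amplitude over the interior so that "30%"
means 30% across the object), additive Gaussian noise, and air bubbles
(soft dark ellipsoids, kept 5 mm in-plane away from nominal crossings so
the ground-truth point count stays unambiguous).  The forward warp inverts
T(x) = x + delta(x) by damped fixed-point iteration (tolerance 0.01 mm) on
the not-yet-converged points, with the pre-image search clamped to a
plausible range so the polynomial's growth outside the phantom cannot make
it diverge — those voxels are background.

Not emulated: MR pulse-sequence physics, susceptibility/chemical-shift
(object-induced) distortion, grid-sheet manufacturing warp, CT scanner
distortion, scanner reconstruction filters, Rician noise statistics.
Passing tests therefore demonstrate the *algorithmic* chain — detection
robustness to bias/noise/bubbles, estimator correctness against an
analytic field, correction consistency — not performance on any particular
scanner's artifacts.

## Problem sizes

The full-resolution tests (0.9 x 0.9 x 1.0 mm voxels, the acquisition
resolution the phantom protocol uses) exercise single-volume detection;
the end-to-end mapping studies run at half resolution (1.8 x 1.8 x 2.0 mm)
and the unit suite on a proportionally scaled-down phantom (3 sheets of
5x5 points), choices that keep the whole suite runnable on a laptop while
preserving bar-to-voxel ratios and field gradients.  Scaled-down studies
scale the field amplitude with the lattice extent so gradients — which are
what the iteration responds to — match the full-size study.

## Known limitations

- The outermost lattice planes rely on extrapolated lookups (displaced
  queries leave the sampled volume); their iterated accuracy is a few
  times worse than the interior's, mirroring the boundary caveat of any
  phantom-sampled field.
- Sub-voxel accuracy degrades roughly linearly with voxel size once grid
  bars are thinner than a pixel; at half resolution the per-point noise is
  ~0.2 mm per component.
- Rotational setup error is not modeled or corrected (translation-only
  registration, justified by a jig in the physical setup).
- Extraction can report spurious points at the phantom boundary under
  strong warps; they are removed at the cleaning stage, so only workflows
  that consume raw extraction output without registration would see them.

## Analyzed volume of interest

Statistics of the found and residual distortion are reported over an
analyzed VOI that keeps the full in-plane lattice but excludes the
outermost sheet on each side of the sheet stack (half-extents 125 mm with
the default geometry).  The outermost planes are sampled from one side
only, so their estimates carry several times the interior's error; the
full-extent samples remain available on the study result for anyone who
wants them.

## Analysis crop

Detection analyses only the phantom region: the study driver crops each
slice to the lattice plus most of a bar tail (and skips slices beyond the
sheet stack), replicating boundary pixels outward so bars continue as
straight stripes and no artificial edges appear.  Without the crop, the
container walls and the surrounding air — especially after correction
resamples them into wavy bands — produce crossing-like responses strong
enough to distort the per-slice response statistics.
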