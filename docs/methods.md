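# Methods

This note documents the models, parameter choices and numerical
behaviour of `fundusreg`, and what the synthetic test bed does and does
not establish about real fundus imagery.

## Segmentation model

Segmentation operates on the *enhanced* image: inverted green channel,
zeroed outside the field of view, Gaussian-smoothed (σ = 1.5 px), white
top-hat with a disc of radius 9 px, then a linear stretch saturating 3%
of in-mask pixels at each tail. The green channel carries the highest
vessel contrast in colour fundus photography; inversion makes vessels
bright, and the top-hat removes background structure wider than about
twice its radius while passing vessels. σ and the top-hat radius are
exposed parameters; the defaults are chosen for vessels up to ~18 px
wide at the working scale and were fixed before any end-to-end tuning.

The global threshold τ_i maximises the distance between the intensity
CDF and the identity diagonal. The printed form of this criterion mixes
a [0,1]-valued CDF with a 0–255 intensity; we normalise intensity to
l/255 so the criterion is the geometric point-to-line distance between
two curves on the unit square. Ties break toward the smaller level. The
criterion exploits the empirical regularity that the vascular tree
occupies a stable 10–15% of the field of view, so the CDF has a
characteristic knee.

The co-occurrence matrix is accumulated over *all eight* neighbour
offsets (one count per ordered pair of 8-adjacent in-mask pixels),
normalised to unit mass, hence exactly symmetric. On a constant image
the marginal deviations vanish and the correlation is undefined; we
raise a typed error (`DegenerateInputError`) rather than substitute a
value, because a constant enhanced image always indicates unusable
input. τ_sd = ⌊P_bg · corr · n²⌋ is clamped to 0 for negative
correlation — a negative count threshold is meaningless. The window
side n = 7 (unstated in the source method; comparable to the maximum
vessel width after downscaling) is configurable. Windows are clipped at
image borders with missing pixels counted as background, which biases
the rim toward background — deliberately, since field-of-view edge
artefacts live there.

Images whose field-of-view diameter exceeds 1024 px are downscaled so
the diameter is ≈ 1024 px before feature work; fitted transforms are
mapped back to native coordinates. All pixel-unit defaults are defined
at this working scale.

## Skeleton and junction detection

Thinning follows the classical two-subpass iterative scheme driven by
the neighbour count B(p), the circular 0→1 transition count A(p) and
two axis-pixel products per sub-pass, with simultaneous deletions per
sub-pass and termination at the first unchanged full pass. It preserves
8-connectivity and is idempotent. On dense lattice-like binary noise it
can leave isolated thick spots (a known property of the scheme); on
vessel-like masks — elongated dilated strokes — the output is strictly
one pixel thick, which is what the test suite asserts.

Junctions are detected with the hit-or-miss transform over a stencil
bank. The default bank enumerates every fully specified 3×3 stencil
whose eight-cell ring shows at least three 0→1 transitions read
clockwise — i.e. at least three distinct skeleton branches leave the
centre pixel (58 stencils). An earlier hand-built bank of nine stencils
(four axis-aligned T rotations, four diagonal Y rotations, one cross)
detected under a third of planted junctions on thinned synthetic trees,
because thinning realises junctions in many mixed axis/diagonal
patterns; the enumerated bank covers all of them and achieves ≈ 95%
recall within 3 px on skeleton-domain trees. Because each stencil pins
all eight ring cells, at most one stencil can fire on a neighbourhood
(verified exhaustively), and the union over the bank can be evaluated
by a single ring-code lookup — the tests prove this fast path equal to
per-stencil hit-or-miss. Custom banks, including ternary stencils with
don't-care cells, can be supplied as JSON.

Detections closer than 5 px merge to their centroid snapped to the
nearest skeleton pixel (noise splits one junction into nearby
responses); pixels whose 3×3 neighbourhood leaves the image are never
flagged; and points within the top-hat radius of the field-of-view rim
are discarded as edge artefacts.

A caveat on localization: for vessels of width w meeting at angle θ,
the skeletal fork sits roughly w / (2·tan(θ/2)) px downstream of the
geometric branch point. This offset is a property of rasterisation plus
thinning, not of the detector, and is the main contributor to the
final sub-pixel registration residual.

## Description and matching

Each keypoint's 16×16 patch is standardised to zero mean and unit
variance, differentiated by centred differences, and binned into
sixteen 4×4 cells × eight 45° orientation bins weighted by gradient
magnitude — a 128-vector, L2-normalised, clipped at 0.2 and
renormalised. Standardisation plus normalisation make the descriptor
exactly invariant to affine intensity changes of the patch. There is no
dominant-orientation assignment: same-eye fundus pairs rotate by only a
few degrees, which the similarity fit absorbs; the descriptor is
therefore *not* rotation-invariant and this tool should not be used for
pairs rotated by tens of degrees.

Matching is second-nearest-neighbour in both directions with a cross
check; ties break toward the lower index, so matching is deterministic.
Two acceptance rules are implemented: `ratio` (d₁/d₂ ≤ t) and
`magnitude` (d₁ ≤ t·‖b₁‖, an absolute threshold for unit-norm
descriptors). The source method states t = 0.2; on synthetic trees
*neither reading accepts anything* — junction neighbourhoods of a
rendered vascular tree are so self-similar that true-match distances
(median 0.4–0.8) and ratios (median 0.65–0.8) sit far above 0.2. The
operation keeps 0.2 as its documented default, but the pipeline default
is the conventional ratio of 0.8, delegating outlier removal to the
cross check and RANSAC. Real fundus texture is richer than the
generator's, so a stricter threshold may be appropriate there; it is a
single config field.

## Transform estimation

Similarity fits solve the linear least-squares system in (a, b, t_x,
t_y) with the upper-left block a·I + b·J, exact for two pairs; affine
fits solve the 6-parameter system, exact for three non-collinear pairs.
Degenerate geometry (coincident or collinear source points) raises a
typed error; inside RANSAC such samples are skipped.

RANSAC draws minimal samples whose source points are pairwise ≥ 50 px
apart (rejection sampling, 100 retries per draw; ten consecutive
failures abort with a diagnostic). Inliers are matches with
reprojection error ≤ 5 px — far below the 25 px success band, so the
tolerance separates localization jitter from mismatches. The iteration
budget follows the standard confidence formula with p = 0.99, adapts to
the best inlier ratio seen, and is capped at 10 000. Ties in inlier
count break toward lower mean reprojection error. The best model is
refit by least squares on its inlier set. A single integer seed drives
all sampling; identical inputs and seed give identical results.

Warping inverts the fitted transform and pulls intensities by bilinear
interpolation onto a canvas covering the target frame united with the
transformed source corners; the field-of-view mask warps by
nearest-neighbour; the canvas origin in target coordinates is reported
alongside.

## Blending

Laplacian pyramids use Gaussian blur (σ = 1) before 2× decimation and
bilinear upsampling; each level is the Gaussian level minus the
upsampled next level, and collapse telescopes back to the input exactly
(to float precision). Fusion is the mask-weighted average of the two
Laplacians per level; binary input masks become fractional under
repeated blur-and-decimate, which is precisely what produces the
seam-free transition. Zero-denominator pixels are defined as 0 and
masked out of the final mosaic. Colour images blend per RGB channel.
With one octave the method reduces to per-pixel weighted averaging;
three octaves is the default. For constant inputs the overlap output is
a convex combination, so no overflow can occur.

## Evaluation protocol

Registration error is the mean Euclidean distance between mapped source
control points and their marked target positions, in native pixels.
Success curves use the integer thresholds 0..25 px with *inclusive*
comparison (so the 0 px column is meaningful for exact registrations);
AUC is the trapezoidal area normalised by 25. Failed registrations
enter as infinite error — they count against every threshold rather
than being dropped, matching how successful-registration counts are
reported out of category totals. Batch summaries stratify by the
S/P/A first-letter convention of pair identifiers or an explicit
category field.

## Synthetic data generator

The generator is the package's study bed. A recursive always-split
binary tree (default 4 roots, depth 5, giving 60 branch points) grows
from near the disc centre outward; segment widths taper 6 → 2 px,
lengths shrink geometrically, branch angles are drawn uniformly from
20–50° off the parent, and branches heading out of the field of view
are steered back while keeping ≥ 35° between siblings so every recorded
junction is a real fork. Vessels are drawn as anti-aliased capsules
with an optional 1 px central reflex stripe; rendering composes a
reddish tissue background with radial illumination falloff (25% at the
rim), vessel darkening strongest in green, a dark surround with a
700 px field-of-view disc on a 768 px canvas, and Gaussian sensor
noise. The canvas is large enough for 16×16 descriptor windows at
junctions yet keeps a full registration under two seconds.

A pair plants a similarity (scale 0.95–1.05, rotation ±10°) or affine
(extra shear ≤ 0.05) about the disc centre, emulating same-session
refixation; the translation magnitude is bisected so the measured
FOV-overlap hits the requested regime (> 75% "high", < 75% "low", the
two regimes of public registration benchmarks). When the drawn
scale/rotation alone cannot reach the drawn overlap target, the target
clamps to the achievable value. The target view re-renders the
*transformed geometry* inside the fixed disc — content moves, the
aperture does not — with its own noise realisation and an optional
exposure gain. Ten control points are sampled uniformly in the overlap;
applying the planted model to their source coordinates reproduces the
target coordinates exactly, so the planted model has zero registration
error by construction. Identical seeds give byte-identical images.

What the generator does *not* emulate: pathology (tumours, cotton-wool
spots, microaneurysms), vessel tortuosity and calibre variation of real
retinas, optic disc and macula, chromatic aberration, and real sensor
noise statistics. Passing tests therefore demonstrate the pipeline's
internal correctness and its accuracy under controlled geometry and
exposure change — not clinical-grade performance on datasets such as
FIRE, whose category-A anatomical changes are specifically outside the
generator's vocabulary.

## Problem sizes and numerical choices

The test suite and the acceptance script run 20 end-to-end pairs at
768×768, 100 RANSAC recovery trials, 100 thinning/detection property
checks on small random masks, and brute-force oracle comparisons on
8×8–32×32 grids — sizes chosen so a full run completes in minutes on
one CPU while still exercising every code path. Reported end-to-end
numbers (success rate at 2 px, mean error, AUC) are over those 20
pairs. Known limitations: descriptors are not rotation-invariant (by
design, see above); junction localization inherits the fork-migration
offset; and the co-occurrence statistics assume an 8-bit intensity
range.
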