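# Methods

This note records the models, parameter choices and numerical decisions
behind `flockvision`, and what the synthetic benchmarks do and do not show.

## Setting and conventions

Frames are top-view pen images up to 1440×1080 px.  Masks are boolean
`(H, W)` arrays, coordinates are 0-based `(row, col)` with row 0 at the
top; all conic math uses `x = col`, `y = row` in pixel units.  Connected
components default to 8-connectivity so diagonal-touching bird fragments
count as one region, matching visual contiguity at this resolution.
Region boundaries are traced at the 0.5 iso-level of the mask
(`skimage.measure.find_contours`), i.e. with sub-pixel vertices along
pixel edges; this gives the ellipse fit smoother input than integer pixel
chains and is deterministic for a given mask.

## Pipe detection

The accumulator is defined literally: `counts[i, j]` is the number of
foreground pixels within `rho_res/2` of the line `(rho_i, theta_j)`, with
1 px / 1° default resolution and theta the normal angle in `[-90°, 90°)`.
Only the global maximum is retained (ties: smallest theta, then smallest
rho, so detection is deterministic).

For a pipe footprint ~11 px wide, the accumulator maximum alone is a poor
centerline estimate: many `(rho, theta)` cells within the band collect
near-identical votes, and on short frames a line tilted a few degrees can
stay inside the band for its whole visible length.  The centerline is
therefore refined by two rounds of total-least-squares fitting to the
pixels within a capture distance (default 6 px, ≈ half-width + 1) of the
current line.  This is the "centerline construction" step of the pipeline
and brings angular error well under the accumulator's 1° bin width.

Collinear runs along the centerline are merged across gaps ≤ `fill_gap`
(default 20 px — birds standing over the pipe interrupt its visible
footprint), fragments < `min_length` (default 40 px) are dropped, and the
segment spans the extremal surviving projections.  Neither parameter has a
canonical value; both are config-exposed.  The band is every pixel within
`half_width` (default 5 px) perpendicular distance of the centerline,
extended to the frame border when the segment reaches it; on axis-aligned
lines this is exactly `2·half_width + 1` px wide.  Hough input is the
equipment-colored pixel mask when an RGB frame is available, else the
morphological gradient of the binary mask; both are supported because the
stage only needs *some* image in which the pipe is the dominant line.

## Regulator detection

Wrapped HSV window: hue in ±20° around red, saturation ≥ 0.5, value
≥ 0.2, minimum region area 20 px, detected regions dilated by 2 px to
cover anti-aliased rims.  The thresholds are generous because the
regulator's saturated red is far from both litter and plumage colors; all
are config-exposed.

## Occlusion classification

Regions come from labeling the cleaned mask.  A pair of regions touching
the (1-px-dilated) pipe band from opposite sides, with overlapping spans
along the band, is one TA case; a single region touching equipment is OA;
otherwise none.  The single-bird area is estimated as the **median** area
of regions touching no equipment (median rather than mean for robustness
to a stray merged blob; a config flag restores the mean).  A region larger
than 1.6× that estimate is flagged `crowded` — multi-bird blobs are out of
scope for ellipse fitting — and an OA region whose estimated occluded
fraction `1 − area/estimate` reaches 0.5 is `unrestorable`, per the
method's applicability bound.

## TA restoration

Closing with a linear structuring element of length
`2·(half_width + se_margin) + 1` (default margin 5 → length 21) oriented
perpendicular to the pipe axis; "along the pipe" would slide material
parallel to the gap and never bridge it, so the element must act across
the band.  Only pixels inside the band dilated by `se_margin` may be
added.  Writing the result as `mask ∪ (closing(mask) ∩ box)` makes the
operation exactly idempotent: the closing of the result is squeezed
between the closing of the input and its own closure, so a second
application adds nothing.  Fragments separated by more than the element
length stay separate and the case is reported as unreconnected.

## OA restoration

Point choice on the boundary is the genuinely open design point: different
five-point subsets give different ellipses.  The default is deterministic
equal-arc-length spacing on the free boundary (points within 3 px of the
occluder are inadmissible; on a partially free boundary the longest free
arc is used with points at `(i + ½)/5` of its length, keeping them away
from the cut edges).  An optional robust mode draws 25 seeded five-point
subsets and keeps the ellipse with the smallest mean absolute conic
residual over the whole free boundary; the deterministic mode is the
default because it is reproducible without auxiliary randomness and
performs comparably on the benchmarks.

The conic through five points is the SVD null vector of the 5×6 monomial
design matrix — exact, no least-squares smoothing — validated by the
discriminant `e² − 4ab < 0` and normalized to `a = 1`.  Rank deficiency
(singular value ratio < 1e-10) raises "degenerate point set".  Because at
most half the bird may be occluded, the intact bird is at most ~2× the
observed region (and observed over-restorations stay below ~1.25× the
intact area), so a fitted ellipse larger than 2.5× the observed region is
geometrically implausible; it is rejected and the case downgraded to
unrestorable rather than unioned in.  The restored mask is the union of
the observed region and the rasterized ellipse interior (conic ≤ 0 at the
pixel center, leading coefficient positive) — restoration never deletes
observed pixels, and over-restoration is reported, not clamped.

## Metrics

`OR = |N₁∩N₂|/|N₁|`, `FPR = (|N₂|−|N₁∩N₂|)/|N₁|`, `FNR = 1 − OR`.  FNR is
computed as the complement of OR — algebraically identical to
`(|N₁|−|N₁∩N₂|)/|N₁|` since both share the denominator — so the identity
`OR + FNR = 1` holds to the last bit.  Rates are fractions; CSV output
adds percent columns.  One-way ANOVA is the classical
`F = MS_between/MS_within` on `(k−1, N−k)` degrees of freedom with the
usual 0.05 significance threshold; zero within-group variance is resolved
explicitly (equal means → `F = 0, p = 1`; unequal → `F = ∞, p = 0`).

## Synthetic scenes and what they show

Birds are ellipses (semi-major axis 25–60 px, aspect 0.5–0.8, the plausible
on-screen size range for the first weeks of growth at this camera height)
perturbed by a smooth radial Fourier series of orders 2–4 with total
amplitude 2 px, because real silhouettes are irregular and perfect-ellipse
fixtures would make the ellipse-fit benchmark trivially perfect.  Placement
is rejection sampling (≤ 1000 attempts per bird) with ≥ 2 px separation
unless crowding is explicitly allowed.  Rendering quantizes all shading
noise to integers before drawing, and every draw derives from one seeded
generator, so scenes are bit-identical across runs and platforms.

TA fixtures put a pipe band of half-width 5 px through the bird interior
and resample until the occluded mask has exactly two components of ≥ 10 px
(slivers below that are not meaningful restoration targets).  OA fixtures
remove a disk-shaped bite centered on a boundary point, with the removed
fraction bisected to a target drawn from (0.05, 0.45) — the protocol of
artificially editing intact birds into one-area occlusions, bounded by the
< 50 % applicability rule.

The benchmark groups fixtures into four semi-axis bands standing in for
four recording ages; this reproduces the *structure* of a growth
comparison, not its biology.  Passing benchmarks therefore show that the
pipeline restores noisy-elliptical single birds occluded by straight bands
and circular bites; they do not certify performance on real plumage
textures, posture variation (wing spread, lying birds), soft shadows, or
crowded groups — the latter is explicitly out of scope.

## Problem sizes and tolerances

Benchmarks use 150 fixtures per occlusion kind on ~170 px square frames,
and the pipe-recovery suite uses 50 scenes at 240×320 px with pipes
≥ 100 px — sizes at which every geometric effect of interest (band width,
bin quantization, boundary noise) is fully expressed while the whole suite
runs in seconds.  Conic recovery is asserted at 1e-6 relative coefficient
error (the conditioning limit of the raw monomial basis at pixel
coordinate scales), pipe recovery at 1° / 2 px (the accumulator's bin
width and band quantization), and rasterized-circle area at 3 %
(pixelation of a radius-10 circle).
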