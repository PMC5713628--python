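# Methods

This note documents the models and procedures behind each phenokit module,
the parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic data generator does and does not
emulate, and the known limitations.

## Conventions

All modules share one coordinate convention: 0-based `(x, y)` =
(column, row), origin at the top-left pixel. Images are 8-bit arrays in RGB
channel order (converted at read time; on-disk BGR never leaks out). Binary
masks hold exactly {0, 255}. Foreground connectivity is 8-connected with
4-connected background — the standard duality, chosen so thin diagonal
petioles remain part of one plant object.

Every analysis step can emit an annotated intermediate image into a debug
directory (`phenokit._debug.set_debug`); emission is off by default because
writing an image per step dominates run time on large datasets.

## Contours and shape summaries (`imgcore`)

Connected components are labelled with scipy's 8-connected structuring
element; each component's outer boundary is traced with Moore neighbour
following (Jacob's stopping criterion), giving a closed, ordered ring of
8-connected pixel coordinates. Background regions fully enclosed by a
component are traced the same way and attached as child contours.

Object area is the enclosed-pixel count of the rasterized ring (ring drawn,
interior filled), the centroid is the mean of the enclosed pixel
coordinates, and the convex hull is the traced boundary of the hull image.
Contours whose shoelace area is below one pixel (single-pixel-wide lines,
collinear rings) are rejected as degenerate rather than given area 0.

## Preprocessing (`preprocess`)

**White balance** scales each channel by `255 / max` where the maximum is
taken over a user ROI containing a white standard (whole image if none).
The reference statistic is the literal channel maximum; an optional
`percentile` parameter (default 100) exists to ignore isolated hot pixels
on cameras that produce them. The operation is idempotent bit-exactly:
after one application the ROI maximum is 255 and the scale factor becomes 1.

**Geometric adjustments.** Rotation keeps the original canvas (no
auto-expand) because downstream grid clustering assumes a fixed frame;
vacated regions are zero-filled. Interpolation is bilinear for intensity
images and nearest-neighbour for anything already binary, so masks stay
strictly {0, 255}. Translation is integer-exact (array slicing). Mask
resizing for VIS→NIR transfer is nearest-neighbour; the scale factors are
supplied by the user from measuring a shared reference object in one image
from each camera — the tool does not auto-calibrate, and full VIS/NIR
registration (lens distortion, rotation between cameras) is out of scope.

**Blurs.** The Gaussian kernel is the normalized sampled Gaussian (outer
product of two 1-D kernels); when sigma is not given it follows the common
`0.3·((k−1)/2 − 1) + 0.8` scale rule. Edges are replicate-padded in both
blurs so constant images are preserved exactly.

## Thresholding (`threshold`)

**Triangle (Zack).** The line runs from the histogram peak to the last
*occupied* bin on the object side — empty tail bins carry no histogram
information, and using bin 255 regardless of occupancy would tilt the line
arbitrarily. The threshold is the level between peak and end whose
`(level, count)` point maximizes perpendicular distance to that line,
evaluated in raw count units. The `xstep` parameter strides the candidate
levels (a coarser search that shifts the distance evaluation along the
x-axis); stride 1 is exhaustive. Ties go to the level nearest the peak.
A constant image (single occupied bin) is an error: there is no line.

**Otsu.** The split `t` assigns level `t` to the lower class; the
implementation maximizes between-class variance `ω₀ω₁(μ₀−μ₁)²`, which is
algebraically the same as minimizing within-class variance but avoids the
catastrophic cancellation of `E[x²]−E[x]²` on large pixel counts. Ties
break toward the lower level. Consistently with the split definition, the
dark-object mask is `img ≤ t` and the light-object mask `img > t`.

**Polarity.** Everywhere else the comparison is strict: light selects
`> value`, dark `< value`. This is stated (and tested) so masks are
bit-reproducible.

**Adaptive.** The per-pixel threshold is the block mean (or
Gaussian-weighted mean, same sigma rule as the blur) minus `offset`,
replicate-padded at edges. `offset` defaults to 0; `block_size` has no
default because it is scale-dependent — it must exceed the width of the
structures being segmented.

## Size marker (`marker`)

`define` mode reports the ROI pixel count; `detect` mode thresholds a
chosen channel (r/g/b/h/s/v/gray) inside the ROI and reports the largest
detected object — largest-area selection makes the measurement robust to
small specks and to marker movement within the ROI. The marker area is
written to the result record; dividing plant area by marker area is left
to the user's analysis, not hidden in the tool. No conversion to physical
units is attempted (that requires the marker's known real size).

## Multi-plant trays (`multiplant`)

The frame is divided into `nrow × ncol` equal cells; each contour is
assigned to the cell containing its *centroid*, so leaves overhanging a
neighbouring cell do not change the assignment, and fragments sharing a
cell form one plant group. Cells may be empty. Skewed trays should be
straightened first with `rotate_img`/`shift_img`; arrangement-independent
clustering (e.g. k-means on contour positions) is deliberately not
attempted.

Split images keep the full original canvas with non-group pixels blanked,
preserving a common coordinate frame for downstream per-plant pipelines
(`crop=True` gives bounding-box crops instead). Genotype labels come from
a names file in row-major order; on a count mismatch a warning is raised,
names are consumed in order, surplus groups get positional `row_col`
labels and surplus names are dropped.

## Watershed organ counting (`watershed`)

The Euclidean distance map (EDM) of the plant mask peaks once inside each
leaf blade when blades connect through thinner petioles. Markers are
chosen in three deterministic steps:

1. **Prominence suppression.** Regional maxima standing less than
   `min_prominence` (default 1.5 px) above their surroundings are removed
   by h-maxima reconstruction. A pixel-discretized EDM carries
   rasterization-scale bumps of height ~1 along any thin ridge; treating
   those as organ cores would wildly over-count. Organ lobes rise several
   pixels above their connecting ridges and survive. Set it to 0 for raw
   regional maxima. If suppression removes everything (objects thinner
   than the floor), raw maxima are used as a fallback.
2. **Plateau reduction.** Each connected plateau contributes one candidate
   at the plateau pixel nearest its centroid, topmost-leftmost on exact
   ties.
3. **Greedy spacing.** Candidates are kept in order of decreasing EDM
   value (same tie-break), discarding any within `min_distance` (Euclidean)
   of one already kept.

Flooding the negated EDM from the markers (scikit-image watershed,
constrained to the mask) assigns every foreground pixel exactly one label;
the label count is the organ estimate. The count is non-increasing in
`min_distance`. The mask is used as given — callers wanting smoother peaks
may blur it first. Known limits: heavily occluded canopies where blades
merge have no EDM valley to cut along, and `min_prominence` hides lobes
shallower than the floor (e.g. blobs of inradius < 2 px).

## Landmarks (`landmarks`)

**Acute (Type II).** At each contour point the angle between the chords to
the points `window` steps away (ring indices wrap) is computed by the law
of cosines, clamped to [0, 180]°; duplicate points give 180° (no bend).
Runs of consecutive points below `angle_threshold` form acute regions —
runs wrap across the ring seam so a region spanning the traversal start is
one landmark, not two. The region's landmark is its middle element
(`floor(len/2)` in traversal order; parity tie-break is ours, the
definition leaves it open). `pt_vals` is the mean mask value inside the
convex hull of the run *extended to its chord endpoints* — the extension
matters: a short notch run hugs the boundary and its raw hull contains
almost no background, whereas the chord-extended hull spans the concave
opening. Convex tips therefore score near 255 and concave axils near 0.
The binary mask (not the grayscale image) is sampled.

`acute_vertex` evaluates angles only at every `search_stride`-th contour
point before run detection — a cheaper search over the same definition;
stride 1 reproduces `acute`'s point set exactly.

**Axis pseudolandmarks (Type III).** The object's extent along one axis is
cut into 20 equidistant bins (half-open `[left, right)`, last bin closed,
so every column belongs to exactly one bin); each bin contributes its
minimum extent, maximum extent and foreground centroid: 60 points per
axis, 20 per role. Objects spanning fewer than 20 pixels along the axis
are rejected (bins would be empty). Because 8-connected objects occupy
every column between their extremes, no interior bin of a connected mask
can be empty.

**Rescaling and reference distances.** `scale_features` maps the mask's
bounding box to the unit square (per-axis affine), applied to landmarks,
object centroid and the plant-base point alike. The base point is the
centroid of the bottom 5% of the object's rows (the fraction is
configurable; the notion "centroid localized to the base" needs *some*
definition and this one is stable under rasterization).
`landmark_reference_pt_dist` then tabulates Δx, Δy, Euclidean distance and
angle (`atan2(Δy, Δx)`, degrees) of every landmark from both references.
Downstream morphometrics (Procrustes, shape PCA) is left to dedicated
morphometrics software; tables export as tab-delimited text.

## Naive Bayes pixel classifier (`bayes`)

Training pixels are converted RGB→HSV with hue on the full [0, 255] byte
scale (not the half-range 0–179 convention), so all three channels share
one 256-bin discretization. Hue is treated as a linear variable; circular
wrap-around at red is a documented limitation which leaves green-centered
plant hues unaffected. Per class and channel, a Gaussian KDE with
Scott's-rule bandwidth is evaluated at the 256 integer bins and
renormalized to sum to 1; an all-equal sample degenerates to a point mass
in its bin. Classes need ≥ 30 samples for a stable estimate.

*Two-class route:* foreground/background pixels are pooled across all
image/mask pairs, then a seeded sample of 10% of the foreground pixels and
the *same number* of background pixels is drawn (pooled sampling, not
per-image). *Multiclass route:* a tab-delimited table, one class per
column, cells `R,G,B`; all samples are used.

Classification scores each pixel per class as the sum of log densities at
its three channel bins (densities floored at 1e-10 so a finite sample
never hard-zeros a class) under uniform priors — the equal-count
background sampling of the two-class route makes uniform priors
consistent, and scaling all priors by a constant cannot change the argmax.
Exact ties go to the earlier class in PDF order and are reported with a
warning. The per-class masks partition the image by construction. Priors
are never estimated from data, and no color-constancy correction happens
inside the classifier — white-balance first if illumination drifts.

PDF files are tab-delimited (`class  channel  b0 … b255`), readable as
plotting input and by `phenokit classify`.

## Pipeline runner (`pipeline`)

Filename metadata is parsed positionally against a template over a
restricted vocabulary (plantbarcode, timestamp, camera, …, other), split
on a delimiter; `other` fields are captured verbatim. A field-count or
timestamp mismatch is a *skip signal* — the file is excluded and counted,
never fatal.

Each image is processed by an independent subprocess (`python script.py
<image> <result>`), so pipeline scripts share no mutable state; results go
to one temporary key/value text file per image (line-atomic `trait<TAB>
value` rows plus a JSON metadata header added by the runner). Aggregation
into SQLite happens strictly after all images finish, in a single process,
sorted by filename — database content is therefore invariant to worker
count and completion order. A crashing script marks one image failed and
the run continues; `processed + skipped + failed` always equals the number
of image files seen.

The store is a minimal three-table schema — `runinfo` (run id, timestamp,
pipeline, template), `metadata` and `features`, both long-format keyed by
(run, image) — so new cameras or traits require no schema change.
Re-aggregation appends a new run id and never touches prior rows.
`export_table` pivots to one wide row per image (metadata columns in
template order, traits sorted by name, missing traits empty) and
re-exports byte-identically.

## Synthetic scenes (`synthgen`)

The generator emulates the image types the toolkit targets: single rosette
plants (thin central ring, tapered petioles radiating to elliptical
blades), trays (one rosette per grid cell with positional jitter), an
optional size-marker disk, flat or horizontally graded backgrounds, and
class-colored strip images for multiclass training. Pixel colors are drawn
per class from HSV Gaussians (means/spreads on the 0–255 scale, clipped)
and converted to RGB; all randomness flows through one
`numpy.random.default_rng(seed)` per scene, so a fixed spec is
byte-reproducible.

Default study conditions, chosen as representative of top-view rosette
imaging and frozen: plant HSV mean (85, 170, 150) with spread (6, 15, 15)
— saturated green; background (30, 60, 70) with spread (5, 12, 10) — dull
brown; hue gap 55/255. The default rosette has 8 leaves, 24×12 px blades,
7 px petiole tips on a 128×128 canvas; the 4-class palette emulates
rust-infected wheat leaves (background / healthy / chlorotic / pustule),
separated mainly by hue and saturation. Recovery measurements use 50
rosettes with 3–12 leaves (144×144), 200 scenes for the area-method
correlation, and 20 images for pipeline runs — sizes at which every
quantity is stable across seeds.

Rosette geometry is constructed so the EDM has exactly one prominent
maximum per leaf: petioles taper outward (width 4 px at the ring growing
to `petiole_width`), so the distance map increases monotonically along
each petiole into its blade, and the ring radius grows with leaf count so
adjacent petiole bases never fuse into a thick junction. Blade centers are
spaced at least `leaf_width + 6` px apart; a canvas too small for that
spacing raises an error instead of silently rendering merged leaves. This
is what "watershed-separable by construction" means here, and it is why
leaf-count recovery is a test of the watershed implementation rather than
of lucky geometry.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: occlusion and overlapping leaves, shadows and
specular highlights, soil/moss background texture, perspective and lens
distortion, diurnal illumination drift, and NIR physics (NIR-style
fixtures are just low-contrast grayscale renders of the same geometry).
Real-world accuracy claims need real annotated images.

## Out of scope

Full color/NIR histogram trait extraction (only the minimal shape summary
is provided), EXIF handling, learning-based leaf segmentation, leaf
identity tracking over time, Procrustes/PCA morphometrics, cluster
scheduler integration, and automatic VIS/NIR calibration.
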