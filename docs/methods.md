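# Methods

`micromot` quantifies how physical cues position motile processes in
adherent fibroblasts, across four assays: (1) corner/side scoring of
membrane extensions and of focal adhesions (FAs) in cells confined to
square micropatterned ECM islands, (2) circular-dorsal-ruffle (CDR)
counting, (3) scrape-wound migration-track metrics, and (4) inverted
Transwell Matrigel-invasion scoring from nuclei z-stacks.  A seeded
synthetic-data generator supplies ground-truth inputs for every stage, so
every measurement in the package is validated against planted truth.

## The corner/side partition

A cell on a square adhesive island of side L adopts the island's shape.  The
island is overlaid with a 4x4 grid; the four corner grid cells define the
*corner* class and the eight edge-interior cells the *side* class.  Along
the boundary this puts the outer quarter of every edge (within L/4 of a
vertex) in the corner class and the central half in the side class, so both
classes carry exactly 2L of perimeter — comparisons of corner vs side
quantities are not confounded by boundary length.

Conventions:

* image coordinates are 0-based `(row, col)` pixels, origin top-left;
  physical coordinates are `pixel * pixel_size_um`; each island carries a
  local frame `(u, v) in [0, L]^2` with a stated origin and rotation.
* A boundary point exactly on a corner/side grid junction is labeled
  *corner* (a deterministic tie-break over a measure-zero set; flip it by
  re-deriving labels from `_classify_uv` if ever needed).
* Masks are rasterized with hard labels (no anti-aliasing) so the two
  classes partition the one-pixel boundary band exactly.  The pixel-count
  length estimates assign half a pixel to each class when a pixel centre
  falls exactly on a junction, which can happen when L/4 is an integer
  multiple of the pixel size (e.g. L = 40 um at 0.2 um/pixel); without this
  the tie-break would bias the corner count by up to 8 pixels.

**Interior zones for FA assignment.**  FAs are assigned to interior corner
and side zones with equal total area *and* equal island-edge contact.  A
single uniform-depth band cannot satisfy both, so the zones are constructed
as follows: corner zones are L-shaped bands of depth `d` hugging both edges
at each vertex over the outer quarter of each edge; side zones are bands
along the central half of each edge with depth `d_s = d - 2 d^2 / L`, which
makes the class areas analytically equal (corner: `2dL - 4d^2`; side:
`2 L d_s`).  At the default `d = L/4` the corner zones coincide with the
four corner cells of the 4x4 grid.  The construction (and its closed-form
equality) is only valid for `d <= L/4`; deeper bands raise an
invalid-geometry error.  Zone membership of an FA is decided by its
centroid — adhesions are small relative to the zones, and the rule is
deterministic.

The partition is registered to the *island* (known by construction for
stamped substrates and for synthetic data), not to the segmented cell
outline; for real images the island origin/rotation is config-supplied or
fit as the minimal bounding square of the cell mask.

## Membrane extensions and CDRs

The actin channel is intensity-thresholded (Otsu by default; percentile and
manual rules are available, and the chosen threshold is recorded in the
provenance log).  An *extension* is an 8-connected component of the
thresholded mask **outside** the island footprint that contacts the island
boundary band and whose projected area strictly exceeds 1 um^2 (the
`min_area_um2` filter is exposed; the strict inequality is deliberate).
Its region is the class with the greater boundary-contact length, ties to
corner — consistent with the geometric tie-break.  Areas are projected 2D
areas from a single frame (maximum-intensity projections can be quantified
the same way but are the caller's choice).  Lamellipodia that fold back
over the cell body cannot be separated from cortical actin by thresholding
alone; the exterior-component area is the operational surrogate, and the
synthetic generator plants lobes that are exterior up to a 0.5 um inward
overlap so that truth and measurement coincide.

A *CDR* is operationalized as a bright component lying wholly inside the
footprint eroded by 1 um whose annularity — hole area divided by filled
area — strictly exceeds 0.1.  Its area is the ring-filled area (the area
the ruffle encircles).  Both parameters are config-exposed; the
morphological identification used with real microscopy is analyst-driven,
and this surrogate is what makes CDR counting testable.

Per-cell summaries conserve member areas exactly and report
`corner_fraction = corner / (corner + side)` (NaN-flagged when no lateral
area was measured).  Time-course tables are long-format
(condition, timepoint, region) with mean, SD (NaN at n = 1) and n;
duplicate (cell, timepoint) rows are an integrity error.

## Focal-adhesion morphometry

FAs are detected in the adhesion-marker channel in three steps: a 1-pixel
Gaussian denoise; a global first threshold (Otsu or manual) to propose
candidates; then a per-component re-threshold at a fixed fraction of the
component's peak amplitude over the image background (background = median
outside the first mask).  Components whose peak does not clear the
background by six robust noise SDs (1.4826 x MAD) are discarded — without
this, a structure-free frame would be shattered into noise detections,
because a global Otsu threshold on a unimodal image simply bisects the
noise.

FA length is the major-axis length of the second-moment ellipse, the
standard morphometric surrogate.  The peak fraction defaults to 0.4 rather
than the FWHM value 0.5: for the imaging model used throughout (solid
elongated plaque 0.8 um wide, 0.3 um PSF, 0.2 um pixels) the half-max
outline erodes the blurred, tapered plaque tips and biases the moment
length by -8 to -10%, while the 0.4 contour makes it unbiased to within a
few percent for 2-6 um objects.  This calibration was derived from the
noise-free forward model, and both the fraction and the minimum area
(0.25 um^2, sub-resolution speckle rejection) are config-exposed.

## Migration-track metrics

For a track p_0..p_n with strictly increasing times and a wound frame
(edge point, unit into-wound normal n, edge direction e = n rotated +90):

* path length `P = sum |p_i+1 - p_i|`; net displacement `D = |p_n - p_0|`;
* signed displacement into the wound `(p_n - p_0) . n` (negative =
  retreat; group means use signed values);
* speed `P / (t_n - t_0)` in um/min;
* angle = `arccos(((p_n - p_0) . e) / D)` in degrees — 90 means
  perpendicular to the wound edge whether the cell moved into or out of the
  wound; the 0-vs-180 distinction depends only on the chosen edge-direction
  sign.  A per-step variant (`step_angles_deg`) is provided; the headline
  angle uses the net vector.
* persistence `D / P` in [0, 1] (clipped against float round-off; exactly 1
  iff all steps are collinear and co-directed); NaN for a stationary track,
  as is the angle for a closed loop.

All metrics are invariant under rigid motions applied jointly to track and
frame (property-tested).  Path length grows with sampling rate, so speed
and persistence must be compared at a common sampling interval; tables
carry the interval implicitly through the time column.

## Invasion scoring

Nuclei are 3D components (26-connectivity) of the thresholded z-stack,
volume-filtered (default > 20 um^3) and subject to the same
6-robust-SD peak prominence guard as FAs.  The depth of a nucleus is the
plane nearest its 3D centroid times the z-interval (4 um default; per-plane
counting, no sub-plane interpolation — a nucleus spanning two planes
resolves to the nearer one).  A cell is *invasive* when its depth strictly
exceeds 8 um and *deep* beyond 24 um (roughly half-way through a 16-plane,
0-60 um stack); percentages are per-FOV and pooled count-weighted across
FOVs, with a warning below five FOVs per insert.  Scoring an empty record
set is undefined and raises rather than returning 0%.

## Group statistics

Between-condition comparisons default to Welch's unequal-variance t test,
two-sided.  A permutation alternative (absolute mean difference statistic)
is exact — full enumeration of label assignments — whenever C(n, n_a) is
at most `exhaustive_limit`, and otherwise uses seeded random splits with
the add-one estimator.  Corner-vs-side comparisons **within** a condition
use a paired t test on per-cell differences: the two areas come from the
same cells and are negatively correlated (they split a shared per-cell
total), so an unpaired test there is anti-conservative (measured ~8% type-I
at a nominal 1% on null cohorts).  Identical degenerate groups return
statistic 0 with p flagged 1.  No multiple-testing correction is applied by
default (comparisons are reported per contrast); `holm_adjust` is available.

## The synthetic-data generator

The generator emulates each assay at a fixed, documented scale and records
analytic truth at placement time:

* **Island cells**: 50x50 um island (900-2500 um^2 is the physical assay
  range), 0.2 um pixels, 15 um frame margin.  The cell body fills the
  footprint at a dim cytoplasmic level (30 vs background 10); structures
  are painted at 200, blurred with a 0.3 um PSF, plus sd-5 Gaussian noise.
  Four extension lobes per cell with Gamma(k=6) area variability around a
  200 um^2 total, truncated at 3x the mean lobe area (an untruncated tail
  occasionally produced a single lobe too large to be a plausible
  lamellipodium or to fit the frame).  Each lobe is a disk tangent to the
  boundary with a 0.5 um inward overlap, placed on corner or side arcs by a
  Bernoulli draw with probability `corner_bias`; because lobe class is
  independent of lobe area, the per-cell truth corner fraction has
  expectation `corner_bias` and the measured fraction is an unbiased
  estimator of it.  Lobes keep 2.5 um clear of class junctions and one
  radius clear of vertices so the analytic exterior area (disk minus one
  circular segment) is exact.  CDRs are annuli (outer 5 um, hole 3 um)
  Poisson-distributed per cell, placed with margins that keep them interior.
  FAs are ellipses (10 corner at N(4, 0.5^2) um, 4 side at N(2, 0.5^2) um,
  0.8 um wide, 5 um minimum centre separation so plaques never merge) in
  the corner/side interior zones of the same geometry the quantifier uses.
* **Tracks**: persistent biased random walks; each step direction is von
  Mises around the resultant of the previous direction (weight
  `track_persistence`) and the wound normal (weight `track_bias`), with
  concentration `track_kappa` times the resultant length, falling back to a
  uniform direction at zero resultant — so zero persistence and zero bias
  give an exactly unbiased walk.  Defaults: 0.5 um/min, 6-min intervals,
  60 steps (a 6 h assay).
* **Invasion stacks**: 16 planes at 4 um (0-60 um), 0.5 um pixels, nuclei
  ellipsoids r_xy = r_z = 4 um placed without xy overlap (density beyond
  the packing limit raises an error).  Depths are a mixture: with
  probability `fraction_invasive`, 12 um + Exp(12 um) clipped 2 um below
  the stack top; otherwise uniform on [0, 6] um.  The deliberate (6, 12) um
  gap keeps the truth label stable under 4 um plane quantization at the
  strict 8 um threshold — real depth distributions are continuous there,
  so near-threshold quantization flips are a known limitation of per-plane
  counting, not of the scoring rule.

Determinism: identical parameters and seed give bit-identical outputs; one
root seed spawns independent substreams for geometry and for each channel's
noise, so skipping a channel does not perturb the others.

### What passing tests do and do not show

The generator plants geometrically clean structures: lobes are disks, CDRs
are closed rings, FAs are well-separated ellipses, nuclei do not touch.
Passing recovery tests therefore demonstrates that the measurement chain
(thresholding, labeling, region logic, depth quantization, statistics) is
correct and calibrated under the documented imaging model — not that
segmentation would be this accurate on real micrographs, where ruffles are
textured, CDRs open and close, FAs abut, and background is structured.
Analyst-set manual thresholds are supported for that regime, and every
threshold used is recorded in the provenance output.

## Numerical choices and degenerate inputs

* Strict inequalities at every filter (area > 1 um^2, depth > 8/24 um,
  annularity > minimum), matching the stated definitions.
* Constant images/stacks raise a degenerate-threshold error; empty but
  noisy frames return empty record lists.
* Undefined statistics are NaN-flagged (corner fraction with no lateral
  area, SD at n = 1, empty-region mean lengths) rather than zero-filled;
  percentages of zero cells raise.
* Rasterization tolerances: boundary-class equality to 2 pixels; interior
  zone areas to ~2% axis-aligned and ~2.5% at 45 degrees; planted-annulus
  area recovery to 5%.
* 8-connectivity in 2D (thin ruffle arms stay connected), 26-connectivity
  in 3D; per-plane 2D nucleus counting is available as a compatibility
  mode via per-plane slicing, but the default is 3D components.

## Problem sizes used in validation

Cohort-level checks run at 200 cells per bias setting for corner-fraction
recovery, 100 seeds for CDR sensitivity and for the null random walk,
6 FOVs x 100 cells for invasion recovery, 1000 replicates for Welch
calibration, and 100 replicates of the 50 + 50-cell two-condition
experiment for the end-to-end contrast.  At these sizes the full suite
completes in a few minutes on one CPU; all sizes are set in the tests and
scale linearly.

## Known limitations

* The partition is registered to the island, not the (slightly irregular)
  cell outline; cells that under-spread their island are scored against
  island geometry.
* Fixed-fraction-of-peak FA outlining assumes one dominant plaque per
  candidate component; merged plaques are measured as one.
* An FA-free frame containing only diffuse cytoplasm can survive the
  prominence guard in unfavourable noise and yield one large spurious
  component; it is dropped at region assignment (centroid in neither zone)
  but inflates the detected count upstream.
* Whether real areas derive from projections or single planes, and how
  folded-back lamellipodia were separated from cortical signal, are
  analyst choices; the operational definitions above are this package's
  testable surrogates.
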