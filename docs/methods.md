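# Methods

`spinemetry` implements an automated, open-box pipeline for 3D and 4D
dendritic-spine morphometry from fluorescence z-stacks, together with a
synthetic phantom generator that provides exact ground truth for every
stage. This note documents the models, the numerical choices, and what the
phantom validation does and does not establish about real data.

## Coordinates and units

Arrays are indexed `(z, y, x)`; voxel sizes are `(z, y, x)` triples in
micrometres, defaulting to `(0.15, 0.1075, 0.1075)` — a 0.15 um z-step with
~0.1075 um pixels, typical of a 60x/1.4 NA acquisition. Physical
coordinates are micrometres with the origin at the volume corner and voxel
centres at `(i + 0.5) * voxel`. All processing happens on an isotropically
resampled grid at the in-plane spacing, because thinning and distance
transforms on anisotropic grids bias the medial axis.

## Segmentation

The intensity volume is lightly smoothed (Gaussian, `presmooth_sigma_um` =
0.05 um ~ half an in-plane voxel), thresholded by Otsu's method, and the
connected component containing the user-supplied dendrite starting point is
kept. Thresholding is *hysteresis* style: voxels above half the Otsu
threshold (above background) are kept when connected to supra-threshold
structure. This matters for spine necks near or below the voxel size, which
carry only partial-volume intensity; a single hard threshold disconnects
them. A start point that falls in background after thresholding is an
error, with a hint to override the threshold or move the point.

## Centerline extraction

The mask is thinned to a 3D skeleton; the Euclidean distance transform
(EDT) provides a local radius at every skeleton voxel. The dendrite is the
maximal geodesic path from the start point through skeleton voxels whose
local diameter is at least `min_dendrite_end_diameter` (0.75 um); ties are
broken toward the path with the larger mean radius (the dendrite is the
thickest structure). The path is smoothed by a moving average over a 0.5 um
window; the reported dendrite length is the smoothed polyline length.

Two robustness measures address failure modes of parallel 3D thinning
(which can delete even-width structures wholesale — a verified behaviour of
the library routine on analytic cylinders):

* *dual-grid fallback* — if the skeleton is empty or spans far less than
  the mask, the mask is shifted by half a voxel (flipping width parity),
  thinned, and the skeleton mapped back;
* *ridge recovery* (at detection time) — EDT ridge voxels with no skeleton
  within 3 voxels mark protrusions whose branch the thinning dropped; a
  replacement branch path is computed as a geodesic through the mask,
  weighted toward the medial axis (edge costs scaled by `exp(-EDT)`).

The volume is edge-padded before thinning so structures cut by the ROI
border (the dendrite itself) are treated as continuing, preventing the
skeleton from eroding away from the ROI edges.

## Spine detection

Every skeleton branch leaving the dendrite path (branch level 2) is a
candidate protrusion. It is kept as a spine iff

1. its geodesic length from the dendrite *surface* to its tip is at most
   `max_spine_length` (5 um fixed mode / 15 um live mode, the latter to
   include filopodia);
2. its tip local diameter is at least `min_spine_end_diameter` (0.215 um
   fixed / 0.3 um live), where the tip diameter is the maximum local
   diameter over the distal 0.3 um of the branch;
3. it protrudes at least `min_protrusion_um` (0.2 um) beyond the dendrite
   surface — skeleton spurs from surface roughness do not;
4. its distal part has a bright core: the median occupancy (see below) over
   the distal half is at least `min_tip_occupancy` (0.35), or over the tip
   window at least 0.5. Noise fuzz riding the hysteresis shell is dim and
   fails both; PSF-dimmed necks of genuine mushrooms do not disqualify a
   spine whose head is bright.

The surface crossing is computed geometrically — the first point of the
branch path whose distance to the traced centerline exceeds the local
dendrite radius (the median trace radius within +-1 um of the attachment,
because the EDT at junction voxels is biased). The attachment point is that
crossing; its arclength along the dendrite and its azimuth around the local
dendrite axis parameterize the spine's position for tracking.

## Morphometry

An *occupancy* field accompanies the mask: the intensity normalized between
the background median and the bright-core median, clipped to [0, 1] — an
estimate of the foreground volume fraction per voxel.

* **Width profile.** The local width at each point of the spine path is the
  equivalent diameter `2*sqrt(A/pi)` of the occupancy integrated over the
  plane perpendicular to the path. For a protrusion pointing away from the
  shaft this plane runs parallel to the dendrite axis and never cuts the
  dendrite cylinder. Because blur and partial volume conserve the integral,
  this estimator is far less biased than widths read off the binary
  surface, which systematically compress head/neck ratios. Without an
  intensity volume the (neighbourhood-maximum) EDT profile is used instead.
* **Neck width** is the minimum of the (lightly smoothed) width profile
  between the surface crossing and the head centre; flat minima resolve to
  the most proximal point.
* **Head width** is the maximum of the width profile over the distal half
  of the path (`head_fraction` = 0.5; the split between head and neck is
  not defined by the source protocol and is configurable).
* **Length** is the geodesic distance, within the mask, from the junction
  to the farthest bright voxel of the head region, minus the surface
  offset — the skeleton itself stops about one tip radius short of the real
  tip. Voxel-graph geodesics use optimal chamfer weights (0.9445, 1.3459,
  1.6531) to stay within ~2% of Euclidean length in arbitrary directions.
* **Head volume** is the occupancy-weighted voxel volume of the head
  region, defined by a geodesic watershed between the head centre and the
  neck minimum (voxels geodesically closer to the head centre). Head volume
  is a well-posed quantity for mushroom-shaped spines; for thin and stubby
  protrusions, which have no articulated head, the reported value describes
  the distal compartment of the watershed and should not be compared to an
  idealized head.

## Classification

With ratio `r = head_width / neck_width`:

* **mushroom** iff `r >= 1.5` and length <= maximum;
* **stubby** iff `r < 1.5` and length <= 1 um;
* **thin** iff `r < 1.5` and 1 < length <= maximum;
* longer protrusions are `excluded`.

Boundary semantics are exact (length 1.0 is stubby-side, ratio 1.5 is
mushroom-side), implemented with a 1e-9 relative tolerance so float
round-off cannot flip a mathematically exact boundary case.

## Tracking and remodeling analytics

Spines in consecutive frames are linked by minimum-cost one-to-one
assignment (Hungarian algorithm) on attachment positions: cost =
|arclength difference| + 0.5 um x (azimuthal difference / pi); pairs
costlier than the gate (1 um) stay unmatched. Tracks are contiguous by
construction (no gap closing). Fates over the series: *stable* (present at
first and last frame), *pruned* (first only), *new* (last only),
*transient* (neither; reported separately rather than folded into new or
pruned). Intermediate gaps are not required for "stable" — presence at both
ends suffices.

Transition analysis conditions on presence at the first frame and excludes
newly formed protrusions. The outcome of a surviving track is its class at
the last frame; pruned tracks count as pruned. Fractions are reported per
initial class (rows summing to 1; classes absent at t0 yield undefined
rows, not zeros) and as incidence over all t0 protrusions. Fate-group
geometry reports the initial (t0) mean head width, neck width, length and
head/neck ratio for the stable / remodeled / pruned groups of a chosen
initial class.

## Phantom generator

Phantoms are rendered as the union of a dendrite tube (radius 0.6 um —
diameter comfortably above the 0.75 um trace threshold) along a straight,
sinusoidal, or arbitrary polyline centerline, and one solid per spine: a
neck capsule from the centerline to the head centre plus a head sphere,
oriented by attachment arclength and azimuth. True geometry is analytic by
construction: head width = head sphere diameter, neck width = capsule
diameter, length = surface-to-tip distance, head volume = sphere volume.
Every ground-truth class label is produced by the package's own classifier
applied to the true geometry (generator–classifier consistency), using
live-mode thresholds so filopodia are labellable.

Rendering uses partial-volume antialiasing: each voxel is sampled at 2^3
sub-positions and receives its inside fraction, so 0.2 um necks on a
~0.1 um grid are representable. Default contrast is foreground 10x
background (1000 vs 100), approximating a well-expressing, deconvolved
actin-labelled neuron; optional Gaussian PSF blur and Gaussian or Poisson
noise are applied afterwards and never alter the truth table. The source
acquisitions report no SNR, so the benchmark noise level — Gaussian sigma =
(foreground − background)/10, "SNR 10" — is this package's own choice.

Time series apply scripted events per spine — `appear(t)`, `prune(t)`,
`morph(t, geometry)` — and an independent per-frame positional jitter
(default 0.1 um, split between arclength and azimuth so surface motion is
roughly isotropic). The default series is 13 frames at 5-minute intervals
(a one-hour session). A pruned spine never reappears under the same id.

### Benchmark scenarios (`spinemetry.benchmarks`)

* *mixed phantom* — 50 um dendrite, 20 spines cycling six templates of the
  three classes, 2.4 um spacing, unblurred; optionally Gaussian noise at
  SNR 10. Used for detection precision/recall and geometry-recovery
  checks.
* *filopodium* — a single 6 um protrusion; 0 detections in fixed mode,
  1 in live mode.
* *remodeling series* — 10 thin protrusions, 13 frames, 0.1 um jitter;
  4 morph to mushroom, 3 are pruned, 3 persist. Spacing (2.4 um) exceeds
  twice the tracking gate and jitter stays below gate/2, so identity
  recovery is well-posed.
* *fate-offset series* — mushroom population in which pruned spines are
  generated with 0.1 um thinner necks than stable ones; per-spine geometry
  varies around the group means with SDs on the order of the automated
  population spread, so group comparisons carry realistic sampling error.

The 4D scenarios are rendered with a modest PSF (sigma 0.12/0.08/0.08 um).
Unblurred sub-voxel capsules rasterize with genuine oblique quantization
pinches that no width estimator can disambiguate at this grid — the same
resolution limit that makes some real spine heads indistinguishable from
short wide necks. Blur, which any real microscope applies, regularizes
exactly this.

### What phantom validation does not show

Phantoms contain one unbranched dendrite, geometrically ideal spines,
spatially uniform contrast, and no photobleaching, drift, or crossing
neurites. Passing the phantom suite demonstrates that the geometry engine
recovers known shapes within stated tolerances and that tracking logic is
exact under its stated conditions; it does not certify performance on real
tissue, where segmentation quality dominates. The statistics module
(regression agreement, Kolmogorov–Smirnov distribution comparison, CV,
adjusted Fisher–Pearson skewness — the variant standard statistics packages
report) exists precisely so users can quantify agreement against manual
annotation on their own data.

## Numerical choices and degenerate inputs

* Problem sizes in tests and the acceptance script (50 um / 20-spine
  phantoms, 13-frame series, 10 replicate fate studies) were chosen to make
  every validation statistically meaningful while keeping a full run in the
  order of a minute.
* Detection scoring matches detected to true attachments greedily,
  one-to-one, closest first, under a 0.5 um default tolerance.
* Constant images, start points in background, zero-length traces, empty
  samples, and zero-variance regressors raise errors rather than returning
  degenerate numbers; branches with fewer than 3 skeleton voxels keep their
  records flagged `short_path` with tip-diameter geometry.
* Records whose mask-based refinement degenerates (possible on repaired
  skeleton branches) fall back to the skeleton-based estimates and are
  flagged `degraded`.
* All randomness flows from explicit seeds; identical seeds give
  bit-identical phantoms.

## Known limitations

* Branched dendrites and crossing neurites are out of scope (the tracing
  model assumes one unbranched segment, matching ROI selection practice).
* Gap closing across missed detections is deliberately absent; a detection
  dropout splits a track into pruned + new.
* Widths below ~2 voxels are reported at the resolution floor (~0.2 um on
  the default grid); the published median neck width of real spines
  (~0.11 um) lies below it, so absolute neck widths near the floor are
  upper bounds.
* Head volume for non-mushroom shapes is a watershed compartment volume,
  not an anatomical head.
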