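# Methods

`organoid3d` quantifies 3D organoid cultures imaged on high-content
confocal screening systems: plates of wells, each well a grid of fields,
each field a z-stack acquired in several fluorescence channels.  The
pipeline has two segmentation stages — whole organoids first, then nuclei
within each organoid — followed by well-level quantification (densities,
clone ratios, live/dead filtering), dose–response fitting, clone
co-localization statistics and a nuclear-morphology classifier.  A
ground-truthed synthetic plate generator makes every stage testable
without any imaging data.

## Image model and conventions

All volumes are ordered `(channel, z, y, x)`, coordinates are 0-based,
bounding boxes half-open.  Physical voxel size `(dz, dy, dx)` in µm is
carried in the plate layout; z-spacing is typically much larger than the
pixel pitch, and every distance-like parameter in the package is specified
in µm and converted through the voxel size, so behaviour does not depend
on the sampling grid.  Fields tile a well edge-to-edge with zero overlap
in row-major order; overlapping layouts are rejected rather than blended,
because no overlap information is available in this acquisition model.
Wells persist as Zarr v2 stores chunked one `(channel, z)` plane per
chunk, so single-plane reads never load a full well.

## Stage 1: organoid segmentation

Per field: (1) the per-pixel maximum over the fluorescence channels and z
gives a 2D projection; (2) the projection is binarized at a low debris
threshold (default 2% of the dtype range), opened (disk radius 2 px, kills
dust and hot pixels) and dilated (radius 1 px); (3) the resulting 2D mask
is broadcast over z and multiplied into every channel ("cleaning"); (4)
the cleaned channel-max volume is smoothed with an anisotropic Gaussian
(default sigma (0.5, 2, 2) voxels, reflecting z-anisotropy) and binarized
with the triangle threshold.  Segmentation is per field because fields
differ in noise and illumination.

The triangle threshold builds a 256-bin histogram, draws the line from the
histogram peak to the farthest occupied bin on the longer-tail side, and
returns the bin with maximal perpendicular distance to that line.  One
numerical subtlety: the threshold is computed over the voxels the cleaning
step kept.  Cleaning writes exact zeros outside its mask; those zeros
would otherwise form an artificial histogram peak separated from the true
background level and drag the threshold below background, ballooning every
mask along z.  Restricting the histogram to the cleaned support restores
the intended peak-to-tail geometry.  A constant image raises a degenerate-
histogram error at the operation level; the field-level wrapper converts
that to an empty mask.

Field masks are stitched to the full well extent *before* 3D
connected-component labeling (26-connectivity), so organoids spanning
field borders receive one label.  Components below `min_volume_voxels`
(default 64 voxels, roughly one nucleus at the default synthetic voxel
size) are removed — this deliberately sacrifices isolated single cells for
precision.  Labels are renumbered 1..N in raster order of first voxel, so
labelings are reproducible.  Features per organoid come from 3D
regionprops measured twice: once spacing-aware for physical quantities
(volumes in µm³, axis lengths in µm, solidity, Euler number, inertia
tensor) and once on the voxel grid for centroid/bbox, which downstream
cropping needs in index units.

## Stage 2: nucleus segmentation

Each organoid is cropped by its padded bbox and each fluorescence channel
is normalized per crop to [0, 1] between the 1.0th and 99.8th intensity
percentiles (per-crop rather than per-well, so dim organoids are not
crushed by bright neighbours).  The segmentation backend is a contract —
any callable from a normalized crop to an instance labeling.  The default
is a classical anisotropy-aware watershed: Gaussian smoothing (1 µm),
Otsu foreground threshold, Euclidean distance transform with physical
sampling, seeds at distance-map maxima with a minimum physical separation
(default 6 µm), and a seeded watershed on the negated distance map.  A
star-convex CNN adapter slot exists for externally trained models (the
recorded reference configuration: anisotropy (9, 1, 1), 64 rays,
receptive field (17, 30, 30) voxels); no weights ship with the package,
and star-convexity is a known failure mode boundary for that backend
family.  Labels under 20 µm³ are dropped; nuclei touching the crop border
are kept and flagged (`on_border`).  Per-nucleus features mirror the
organoid table plus eccentricity, defined here as minor/major axis length
(1 = sphere, smaller = more elongated).  Channels are segmented
independently, so a nucleus's record never depends on the other channel.

## Well quantification

*Imaged area.*  Cell counts are normalized by the area of the imaged well
actually occupied by organoids, not the nominal well area: on the 2D
max-projection of the organoid labels, objects larger than 25% of the
projection are discarded as artifacts, the mask is dilated (2 px) and
closed (disk 5 px) to absorb gaps between adjacent organoids, and the
remaining pixel count is converted to mm².

*Dead-cell filter.*  The dead-dye channel of each organoid crop is
min–max normalized to [0, 1] (a percentile variant is available for
hot-pixel robustness) and each nucleus's mean normalized intensity over
its *bounding box* is compared to a threshold (default 0.1, strictly
greater-than = dead).  Bounding-box averaging includes non-nucleus voxels
and can pick up an immediately adjacent dye-positive neighbour; this is a
documented property of the method, and the exactness benchmark therefore
uses dye-sparse organoids (14 µm centre separation).  One guard was added
beyond the basic recipe: if the crop's dynamic range is below a floor
(default 12 noise SD, estimated by 1.4826×MAD), the channel is treated as
signal-free and all nuclei are called live — otherwise min–max
normalization of a pure-noise crop would rescale read noise across [0, 1]
and flag arbitrary nuclei.

*Summaries.*  Live counts per channel, densities (counts / imaged area),
and the clone ratio A:B.  A zero denominator leaves the ratio flagged
undefined rather than NaN.  Clone proportions can be normalized to the
mean of untreated control wells, with replicate mean and SD per dose.

## Dose–response

The model on `x = log10(dose)` is
`f(x) = B + (T − B) / (1 + 10^(b(x_mid − x)))^s` with asymmetry `s ≡ 1`
for the 4-parameter variant (the default; 5PL optional).  Fitting is
bounded nonlinear least squares, multi-started (10 starts) from
data-driven initials with both slope signs; bounds and initials are
defined relative to the data ranges, which makes the fit exactly
equivariant under dose rescaling.  The relative IC50 (dose at the midpoint
of the fitted asymptotes) has a closed form; the absolute variant
(response = 0.5 of control) is also reported when the curve crosses it.
A flat response (range < 1e-3) or fewer distinct doses than parameters is
an error, not a fit.

Confidence intervals use a seeded bootstrap refit from the point estimate.
The default resamples pooled fitted residuals scaled by `sqrt(n/(n−p))`;
well-level case resampling is available (`boot_method="case"`) but with
only ~3 replicates per dose it understates the noise and measured ~80–85%
coverage at nominal 95%, so the residual scheme is the default (~91–94%
measured under the standard benchmark conditions: 8 doses × 3 replicates,
noise SD 0.05, 200 resamples).  Interval endpoints use expanded
percentiles (t-corrected quantile levels), the standard small-sample
adjustment, which converges to the plain 2.5/97.5 percentiles as n grows.

## Clone co-localization

For an organoid's nucleus centroids (µm, anisotropy already applied) with
clone labels, the windowed localization score of clone X is
`Lc = X_n / (K · R_x)` per clone-X cell — `X_n` of its `K` nearest
neighbours are clone X, `R_x` is the clone's organoid-wide fraction — and
`Lo` is the mean `Lc` over the clone's cells.  `Lo = 1` means random
mixing; under uniformly random labels the exact expectation is
`n(n_X−1)/((n−1)n_X)` (hypergeometric windows), slightly below 1 because
the focal cell is excluded from its own window but included in `R_x`.
Both of those conventions are flags, since either choice is defensible;
the defaults are: focal excluded from the window, included in the
fraction.  Ties in distance break by stable index order.  Organoids with
`n ≤ K` are skipped for that window rather than shrinking K.  The radial
variant counts neighbours within `r_i = i·r_max/6` (r_max = organoid
diameter by largest pairwise distance), reported at `i = 2` by default;
focal cells with empty neighbourhoods are skipped with a warning.
Significance uses label permutation over the fixed geometry with
`p = (1 + #{Lo_perm ≥ Lo_obs}) / (1 + n_perm)`.  Per-organoid scores can
be stratified by clone fraction (0.2-wide bins) and filtered to balanced
organoids (fractions 0.4–0.6) for homogeneous-vs-heterogeneous contrasts.

## Morphology classifier

A binary L2-regularized logistic regression (weak regularization, C = 100)
on the standard nuclear feature vector (volumes: raw/filled/convex/bbox;
intensity mean/max/min; eccentricity; solidity; Euler number; inertia
tensor eigenvalues), evaluated by ROC AUC on a held-out stratified 20%
split.  Standardization is fit on the training split only (leakage guard);
constant columns are dropped with a warning.  Coefficients are reported on
the standardized scale so their magnitudes are comparable.

## Synthetic data generator

The generator emulates the targeted imaging regime at desk scale.  Default
study conditions: 3×3 fields of 256×256 px, 30 planes, voxel (2, 1, 1) µm
(a 3-channel well of 0.77×0.77 mm); 20 organoids per well as ellipsoids
(xy radius 35 ± 3 µm, z radius 20 ± 2 µm, ≥15 µm apart) each holding
~75 nuclei (centre separation ≥ 8 µm, radius 3.5 ± 0.25 µm); two clone
channels plus a dead-dye channel; background offset 200 counts with
Gaussian read noise (SD 20).  One well is ~1,500 nuclei.

Nuclei render as flat-top blobs: constant intensity inside the nominal
radius with a Gaussian rolloff (SD 0.8 µm) outside.  Pure Gaussian blobs
were rejected because their effective object size is ill-defined and much
smaller than the nominal radius; the flat-top profile keeps watershed
valleys between neighbours while making the instance's half-max support —
the reference mask for IoU matching — essentially the nominal radius plus
a fixed shell.  A faint organoid "body" (400 counts in both clone
channels) stands in for cytoplasmic background and scattering; it is what
makes an organoid one connected bright region in stage 1, and it is kept
well below the Otsu split between body and nuclei in stage 2.  Debris
renders as bright 1 µm points at a configurable Poisson rate.

Clone labels come from a spatial-affinity process: each nucleus gets a
score `α·rank + (1−α)·uniform`, where rank orders nuclei along a random
spatial axis of the organoid; the lowest fraction becomes clone A.  α = 0
gives uniformly random labels, α = 1 two contiguous blocks, intermediate
values partial clustering.  Dead flags are i.i.d. Bernoulli.  Dose
ladders thin each clone binomially by its survival curve and can scale
nucleus volume and intensity per dose (programmable analogues of
drug-induced morphology shifts, including survival-curve crossings that
reverse clone proportions).  Everything derives from one seed;
regeneration is bit-identical.

What the generator does *not* model: optical PSF and depth attenuation,
illumination gradients across fields, autofluorescence texture,
non-ellipsoidal organoid shapes, nucleus shape irregularity and mitotic
figures, and spatially correlated death.  Passing the synthetic benchmarks
therefore demonstrates the correctness of the algorithms under the stated
geometry and noise model, not segmentation performance on real organoid
images — the classical watershed backend in particular will degrade on
crowded, irregular real nuclei sooner than these benchmarks suggest.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) and the acceptance tests
use: one default well (~20 organoids / ~1,500 nuclei) for end-to-end
recovery plus four wells across mix fractions 0.2–0.8 for clone-ratio
error; 2,000 relabelings of a 200-point geometry for the score-expectation
check; 100 single-organoid point sets per affinity condition; 1,000 random
histograms for the threshold oracle; 200 simulations × 200 bootstrap
resamples for IC50 coverage; 5,000 nuclei per class for the classifier
checks.  These sizes were chosen so the full suite completes in minutes on
one CPU while keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

* The watershed backend assumes blob-like nuclei; elongated or hollow
  nuclei will be over-split or merged.  The backend contract exists so a
  trained star-convex (or other) model can replace it without touching the
  rest of the pipeline.
* Bounding-box dye averaging (kept for fidelity to the quantification
  recipe) can misflag a live nucleus adjacent to a dead one; a mask-based
  average would be the natural extension.
* The imaged-area estimate depends on the dilation/closing radii; it is
  meant for ratio and density comparisons within a plate, not as an
  absolute area measurement.
* Stage-1 grayscale conversion uses the channel maximum, which favours
  recall in mixed-clone wells but lets one saturated channel dominate.
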