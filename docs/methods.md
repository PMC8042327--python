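# Methods

## Problem and model

`tubertrack` quantifies below-ground potato tuber growth from time series
of reconstructed X-ray CT volumes ("4D" data: one 3D volume per pot per
scan day). The central obstacle is that the reconstructed linear
absorption coefficient alone cannot separate tubers from soil, stolons,
roots, or stones — their absorption ranges overlap. The method instead
exploits *texture*: granular soil is spatially inhomogeneous, while
tuber parenchyma is homogeneous. A windowed local-variance map is
therefore low inside tubers and high in soil, and a single variance
threshold (plus an absorption floor to exclude the equally homogeneous
air) separates them.

### Intensity normalization

Reconstructions of different scans carry different overall gains. Every
volume is referenced against its unattenuated-air signal before
analysis, so one gray-scale ladder holds for the whole experiment. Two
modes exist:

* **affine** (default): scale by `air_level / mean(air region)` and
  shift air to 0. `air_level` (default 0.2 reference units) is the
  nominal raw pedestal of air; after normalization the ladder is
  air = 0, soil ≈ 0.6, tuber tissue ≈ 1.0 (water-like), stone ≈ 1.8.
  All later thresholds are expressed on this ladder.
* **multiplicative**: pure scaling to a nonzero air target, for data
  whose offset is already trusted.

The `"auto"` air region is the corner octant with the lowest median
intensity (the pot never fills all eight corners). Because that octant
can still contain part of the pot, the air level is the mean of the
octant voxels inside a 4-MAD window around the octant median; soil and
pot material lie far above this window, so the estimate is unbiased by
them. Normalization is idempotent: a volume whose air region already
sits at the target is returned unchanged.

### Segmentation (virtual excavation)

Stages, applied with **one frozen parameter set per experiment**:

1. **3D median filter**, cubic window of radius `median_radius_vox`
   (default 1), reflective boundaries — suppresses reconstruction noise
   without blurring edges.
2. **Local variance** `V = G_λ ⊛ I² − (G_λ ⊛ I)²` with an isotropic
   Gaussian window of scale `lambda_mm` (default 0.4 mm, converted to a
   voxel-space sigma). Computed in float64 on mean-centered data to
   avoid cancellation; negative round-off is clamped to 0. A window
   below half a voxel is rejected as unresolvable.
3. **Binarization**: foreground = `V < variance_threshold` AND
   `I > absorption_floor` (default 0.3: above air, below soil mean).
   If the threshold is unset it is calibrated **once**, on the first
   volume of the experiment, as the 25th percentile of the variance
   distribution over in-pot voxels (those above the absorption floor),
   then frozen for every pot, timepoint, and condition.
4. **Binary erosion** with a Euclidean ball (default radius 4 voxels) —
   disconnects tubers from tangent stolons and deletes thin structures.
5. **Connected components** under 26-neighborhood (chessboard-metric)
   adjacency; labels are re-indexed densely 1..N by decreasing size.
6. **Constrained per-label dilation** restoring object size: all labels
   grow simultaneously in one-voxel shells along a chamfer cross/cube
   schedule that approximates a Euclidean ball; contested voxels go to
   the lowest (largest-object) label, and existing labels are never
   overwritten, so touching tubers cannot merge.
7. **Minimum-volume filter** (default 5 mm³) applied at the *restored*
   size, so that genuinely small tubers whose eroded core is tiny are
   not discarded prematurely.

**Size restoration.** Both the variance window and the erosion shave
object boundaries: the variance band at a tuber/soil edge extends about
two window sigmas into the object before the value falls below the
threshold. The default dilation radius is therefore
`erosion_radius + round(2.2 · λ/voxel)`. The 2.2 constant was fixed by
rendering analytic spheres (3.6–10 mm diameter) in default soil at
88.9 µm voxels and choosing the radius whose restored voxel volumes
bracket the analytic volumes most tightly (measured ratios 0.94–1.07).
Because the constrained dilation grows into any background, the restored
radius — not local intensity — sets the final object size; the residual
volume error is about one voxel of radius, so volumetric accuracy is
resolution-limited for small tubers.

### Features and false-positive rejection

Per labeled object: voxel-count volume (mm³), mean normalized
absorption, intensity-weighted centroid (center of mass), principal
semi-axis lengths from the eigen-decomposition of the positional
second-moment tensor (a uniform ellipsoid has axis `a = √(5·eigenvalue)`;
each voxel contributes its own edge²/12 spread, keeping axes positive
for single-voxel objects), and the aspect ratio (longest/shortest axis).

Three rules demote candidates, in order, and never resurrect a record:

1. **Absorption band** (default closed interval [0.8, 1.3]): absorption
   tracks density at fixed composition, so homogeneous clay or stones
   fall outside the water-like band → `rejected_stone`.
2. **Aspect ratio** (default max 3.0): disconnected stolon fragments are
   tubes, far from spherical → `rejected_stolon`.
3. **Growth** (after tracking, once the series has ended): a tuber has
   to grow. A track is kept if its volume rises by ≥ 5% (default)
   across some run of 3 consecutive usable observations; otherwise
   `rejected_nongrowing`. Observations inside a user-declared stress
   window are exempt — growth arrest under stress is biology, not a
   false positive — so runs simply span the window, and a tuber that
   grew before or after the arrest is kept. Tracks too short to
   demonstrate growth are rejected.

The numeric defaults of all three rules are package choices (the rules
themselves only fix the direction of each cut); all are
config-overridable, and one `RunConfig` governs an entire experiment.

### Tracking

Tubers barely move between scans. Objects at consecutive timepoints are
linked greedily in ascending centroid-distance order; a link is
admissible if the displacement does not exceed the **diameter of the
sphere with the previous object's volume**, `d = (6V/π)^(1/3)` — a
threshold that grows with the tuber, scaling from millimeter initials to
mature tubers. The previous timepoint's volume is used because the
current object's identity is not yet established. Unmatched objects
start new tracks; a track survives one missed observation (configurable
`max_gap`) before terminating. Ties break on (distance, track id,
label), so tracking is deterministic and invariant to within-timepoint
record order.

### Fresh-weight calibration and growth analytics

For constant-composition tissue the absorption coefficient is
proportional to density, so `vfw = volume × mean absorption` is
proportional to fresh weight. An OLS fit of measured masses on vfw
(intercept by default — it absorbs residual partial-volume bias; a
through-origin fit is available) converts every tracked observation to
grams; negative predictions clamp to 0 with a warning.

Per-plant totals are the exact sum of member-tuber weights per
timepoint. Growth velocity (g/day) uses divided differences on the
actual day spacings — second-order central differences at interior
points, one-sided at the ends — never assuming uniform sampling. Group
summaries (mean ± sd across pots of one condition) are computed only at
timepoints shared by every pot of the group; there is no temporal
interpolation.

## The phantom generator

The synthetic module replaces the scanner. Per timepoint it renders
`gain × (0.2 + absorption + noise)` where 0.2 is the nominal air
pedestal and gain is a per-scan source-intensity factor (default sd 5%),
or, on request, an already-normalized volume (emulating a cropped,
flat-field-corrected sub-volume). Scene content:

* **soil**: Gaussian-smoothed white noise with a stated correlation
  length (default 1 mm) scaled to a heterogeneity sd (default 0.15)
  around a mean of 0.6; the texture field is static across the series
  (same soil), while a moisture drift adds a per-day offset to the soil
  mean (stress pots dry at −0.003/day by default);
* **tubers**: analytic ellipsoids at absorption 1.0 following a logistic
  volume model `dV/dt = r·V(1−V/K)`, optionally multiplied by an arrest
  factor inside a stress window (solved exactly through the effective
  time, so volume is continuous and non-decreasing); semi-axes scale
  isotropically with the cube root of volume;
* **stolons**: static capsule chains at tuber absorption (radius
  1.2 mm), attached near tubers;
* **stones**: static ellipsoids at absorption 1.8;
* **pot**: a cylinder (wall absorption 1.6) with air above the soil
  surface and outside.

Object boundaries are anti-aliased with a first-order partial-volume
fraction (signed distance over one voxel width), since millimeter-scale
detectability is meaningless with hard edges. Ground truth (labels,
volumes, masses at density 1.09 g/cm³) comes from the analytic shapes,
never from the noisy voxels. Identical spec + seed renders bitwise
identically; noise and gain derive from per-timepoint child seeds while
the soil texture derives from the scene seed alone, so two seeds give
different soil but identical true growth curves.

**What the phantom does not emulate:** beam hardening, scatter, ring or
metal artifacts, root systems, soil compaction or macropores, tuber
shape irregularity beyond ellipsoids, and tuber movement as soil
settles. Passing tests therefore demonstrate the pipeline's behavior
under the stated texture-contrast hypothesis at realistic geometry and
noise, not robustness to every artifact of field data.

## Benchmark studies and problem sizes

`tubertrack.studies` recomputes the two headline figures end to end;
`scripts/acceptance.py` drives both and writes JSON.

* **Calibration fidelity**: 30 spherical tubers, 4–25 mm diameter, 2%
  multiplicative intensity noise, each segmented (default frozen
  parameters) out of its own soil crop at 0.2 mm voxels (88.9 µm voxels
  would need ~340³ volumes for the largest tubers); OLS of true
  mass on segmented vfw. Expected R² ≥ 0.99; the fitted slope recovers
  the encoded tissue density within a few percent.
* **Detectability**: single spheres in 160³ soil crops at 88.9 µm
  voxels, 10 replicates per diameter over
  {2.4, 2.8, 3.2, 3.6, 4.0, 4.8, 6.4, 8.0} mm — dense 0.4 mm steps
  through the decision region, thinned above it to keep the run within
  a desk-scale compute budget. Reported: the smallest diameter detected
  (one label covering ≥ 50% of the true voxels) in all replicates, with
  all larger probed diameters also fully detected. Measured: ~3.2 mm.

The stock experiment (`default_experiment`) used by the test suite is a
paired control/stress pot at 0.4 mm voxels (120³), three tubers per pot
plus one stone and one tangent stolon, 12 scan days over 6 weeks with a
day 15–29 stress arrest. The coarser-than-scanner voxel size keeps the
suite fast; detection metrics are resolution-robust, while volumetric
accuracy at this scale is the resolution limit discussed above.

## Numerical choices and degenerate inputs

* Axis order (z, y, x), 0-based, voxel centers at half-integer offsets;
  isotropic voxels only (anisotropic input is rejected).
* Reflection padding for all windowed operators.
* Variance is clamped at 0; constant volumes give identically zero
  variance.
* Empty label sets yield empty feature lists (not errors); a pot with a
  single timepoint yields totals but no velocity.
* Degenerate calibration input (constant vfw, or n < 3) is an error.
* `erode`/`dilate` use exact digital Euclidean balls; only the
  multi-label restoration uses the chamfer approximation (effective
  radius within ~7% of Euclidean, absorbed by the calibrated
  restoration constant).

## Known limitations

* Volumetric accuracy is edge-limited: ~1 voxel of radial uncertainty,
  i.e. ~5% volume for a 10 mm tuber at 88.9 µm but ~25% for a 5 mm
  tuber at 0.4 mm voxels.
* Touching tubers are kept apart by erosion and constrained dilation,
  not split: two tubers merged already at the binarization stage would
  be tracked as one object.
* The growth rule needs several scans; very short tracks are rejected
  rather than classified.
* Calibration assumes constant tissue composition; strong maturity or
  disease gradients in density would bias fresh weights.
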