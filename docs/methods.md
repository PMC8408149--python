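# Methods

## The measurement problem

Calcified precipitates in cataractous lens cores appear in reconstructed
micro-CT volumes as compact or strip-like objects whose linear
attenuation (reported as "absorption per cm") is several-fold above the
surrounding fiber-cell tissue.  The quantities of interest are
per-object geometry (volume, Maximum Feret diameter, aspect ratio),
per-object density (mean attenuation), and the population's spatial
organization (distance-to-lens-center distribution and its shell peaks,
anterior/posterior asymmetry).  `lensxct` computes all of these from an
attenuation volume with known voxel pitch, and ships a phantom generator
so that every stage can be validated by recovering known planted
parameters.

All coordinates are (z, y, x), 0-based, with physical positions at voxel
centers (`index × pitch`); the anterior pole is +z by convention and is
recorded in every volume's metadata sidecar.

## Segmentation

Foreground is `attenuation ≥ threshold`; objects are 26-connected
components (face, edge or corner adjacency — the convention of
commercial 3D morphometry tools, which avoids splitting thin diagonal
strips); components smaller than `min_volume_voxels` (default 8) are
discarded as noise.  Labels are assigned 1..K by decreasing size, ties
broken by the lexicographically smallest voxel, so labelings are
reproducible.

The default threshold is `median + 5 × (1.4826 · MAD)` of the
attenuation inside the lens mask.  The robust location/scale pair is
insensitive to the precipitates themselves (a ≲1% voxel fraction), and
five robust SDs put the false-positive rate per voxel near 3·10⁻⁷ for
Gaussian noise, which the 8-voxel size filter then suppresses entirely.
A tiny epsilon keeps the automatic threshold strictly above the
background median so that noiseless volumes (robust SD = 0) do not
flood-fill the lens.  The threshold, the policy that produced it, and a
warning when it does not clear the background are all recorded in the
label map's provenance.

The lens itself is segmented separately: Otsu's two-class threshold
separates tissue from the surrounding medium, the largest connected
component is kept, and interior holes are filled.

## Morphometry

**Maximum Feret diameter (MFD).**  The Feret diameter along a direction
is the distance between the two parallel planes perpendicular to that
direction that just enclose the object; the MFD is its maximum over
directions, attained by a pair of convex-hull vertices.  We compute the
convex hull of the object's voxel centers (falling back to all points
for degenerate sets) and take the maximum pairwise vertex distance, plus
one pitch for the physical extent of the voxels: an n-voxel straight rod
measures exactly n pitches and a single voxel measures one pitch.  The
hull route is exactly equivalent to the brute-force maximum over all
voxel pairs (this equivalence is asserted in the test suite) but scales
with hull size rather than object size.  Voxel Feret estimates carry a
positive bias of up to ~1 voxel-diagonal for very small objects because
the +1-pitch correction is exact only along grid axes; at the default
5 µm pitch this shifts the measured below-40 µm fraction of a calibrated
population down by about one percentage point.

**Aspect ratio.**  AR = (minimum extent) / MFD, clipped to (0, 1].  The
minimum extent is the smallest peak-to-peak projection (plus one pitch)
onto the three principal axes of the voxel-center covariance — an
approximation to the exhaustive minimum Feret chosen for robustness and
speed.  It can exceed the true minimum Feret for awkward shapes; the
test suite bounds it against an exhaustive direction-sampling oracle at
2° resolution (within a factor of 1.3, and never below the oracle's
minimum beyond the oracle's own angular discretization).  AR is used for
range, ordering and trend statements only, not as an absolute
cross-instrument quantity.

**Other measurements.**  Volume is `voxel_count × pitch³`; the centroid
is the mean voxel center; mean absorption is the mean attenuation over
the object's voxels (accumulated in float64 so constant-valued objects
measure exactly).

## Radial shell analysis

Distances are Euclidean, from each precipitate centroid to the lens
center.  The center is the lens-mask centroid by default: the
precipitate cloud is strongly anterior-biased, so its own centroid would
drag the origin anteriorly and smear the shell peaks ("center of
precipitation" is nevertheless available via `center_mode=
"precipitates"`).  Distances are histogrammed from zero in 10 µm bins
(config-exposed), smoothed with a centered 3-bin moving average, and
peaks are local maxima with prominence ≥10% of the global smoothed
maximum; the reported location refines the peak bin center by a
three-point parabolic fit (≤ half a bin), which removes most of the bin
quantization.  Zero-padding at both ends lets edge bins hold peaks
(e.g. when every object sits at the center).  The anterior flag is the
sign of the centroid offset along the anterior axis.

## The phantom generator

The generator emulates the features of Cx46KO lens-core populations that
the pipeline is meant to recover; it is a model of the *population
statistics*, not of image formation.

* **Geometry.**  The lens core is a ball of homogeneous tissue
  attenuation (default 5 cm⁻¹) in air, radius 750 µm — the core region
  that contains the shell layers, not the whole ~1 mm juvenile mouse
  lens.  Voxel pitch defaults to 5 µm so a whole phantom is a ~305³
  grid; all measurements are pitch-independent and reported in µm.
* **Placement.**  A shell is chosen uniformly from `shell_radii_um`
  (defaults 420 and 520 µm, the two layers seen in severe cataracts);
  the radius is Normal(shell, `shell_sd_um`); with probability
  `anterior_fraction` (default 1) the direction is confined to the
  anterior hemisphere and to three azimuthal sectors of ±35° spaced
  120° apart — the Y-suture branches; otherwise isotropic.  The shell
  radii and the anterior-suture enrichment are observed features of the
  modeled populations; the within-shell scatter and sector width are
  modeling choices, sized so the default populations remain placeable
  (below).
* **Shape.**  Each precipitate is a spherocylinder (capsule): one
  two-parameter family that spans sphere-like to strip-like shapes.
  Lengths follow a log-normal truncated to [15, `length_max_um`] µm
  whose median is calibrated numerically (bracketing root solve on the
  truncated CDF, survival functions for tail stability) so that
  P(length < 40 µm) equals `frac_below_40um` exactly.  The 15 µm floor
  guarantees every planted object exceeds the 8-voxel segmentation
  floor at 5 µm pitch.  Elongation couples to length as
  `min(1, (width_um / L) ** ar_coupling)`; the default
  `ar_coupling = 1` gives a constant physical width (`width_um`,
  default 15 µm), i.e. growth confined along fibers — longer objects
  are proportionally more chain-like, reproducing the joint
  volume-up/AR-down trend.  Orientations are radial (the local fiber
  direction in the core).
* **Absorption.**  Planted mean attenuation is a truncated normal on
  [`absorption_min`, `absorption_cap`]; the floor (10 cm⁻¹) keeps every
  object above any sensible threshold, satisfying the invariant that
  planted absorption exceeds background.
* **Collision-free placement.**  Candidate centers are rejected until
  the capsule clears every placed capsule by `min_separation_um`
  (default 10 µm = 2 voxels) between surfaces, measured by
  segment-to-segment distance.  Retries redraw *position only*, so the
  planted length distribution is preserved exactly; objects are placed
  longest-first.  Without this, the shell geometry at n = 2000 merges a
  substantial fraction of objects under connected-component labeling
  and corrupts every per-object statistic.  Default geometry jams near
  n ≈ 3600, leaving ~1.8× headroom at the default n = 2000; an
  unplaceable configuration raises rather than silently dropping
  objects.
* **Rendering and noise.**  Voxels whose centers lie inside a capsule
  take its absorption (binary fill — noiseless renders are exact);
  i.i.d. Gaussian noise (default SD 0.5 cm⁻¹) is added everywhere.  A
  voxel budget guards against accidental full-resolution renders.
* **Determinism.**  All randomness flows from two spawned child streams
  (population, noise) of the config seed; fixed seed gives bitwise
  identical truth and volume.

### Named configurations

Four presets encode the published age/strain trends for Cx46KO lenses at
postnatal days 23–31 on B6 and 129 backgrounds:

| preset  | frac < 40 µm | length max (µm) | absorption mode/cap (cm⁻¹) |
|---------|--------------|-----------------|----------------------------|
| P23-B6  | 0.995        | 95              | 13 / 30                    |
| P27-129 | 0.96         | 95              | 14 / 30                    |
| P31-B6  | 0.94         | 180             | 21 / 35                    |
| P31-129 | 0.90         | 180             | 25 / 35                    |

Young presets cap absorption at 30 cm⁻¹ (no precipitate above it, most
below 20); P31 presets allow lengths in the 100–200 µm range and higher
absorption, with the P31-129 mode near 25 cm⁻¹.  All presets default to
n = 2000 precipitates — per-lens counts are not published, and 2000
gives useful binomial resolution (3 SE ≈ 2 percentage points on the
below-40 µm fraction) while staying well inside placement capacity; age
trends are carried by the size/shape/absorption distributions, not by
counts.  Shell scatter is 20 µm for P31 presets and 25 µm for the young
ones (whose layers are reported as less distinct).

### What the phantoms do not model

Reconstruction physics (phase-contrast fringes, ring/beam-hardening
artifacts, anisotropic PSF), partial-volume edges (objects are binary
capsules), clustered or touching precipitates, non-spherical lens shape,
and attenuation gradients within the lens.  Passing recovery tests
therefore demonstrates the correctness of the measurement chain on
cleanly resolvable populations with realistic statistics — not
performance on heavily merged or artifact-laden scans, where the
threshold and minimum-size parameters would need tuning per dataset.

## Problem sizes and tolerances in the test suite

End-to-end recovery tests run the named presets at their default
n = 2000 on ~305³ grids (about 15 s per run); unit tests use ~125³
phantoms.  Recovered below-40 µm fractions are compared at 3 binomial
SE; shell-peak locations at ±1 histogram bin (10 µm); Feret oracle
equivalence is exact to 10⁻⁹; determinism is byte-exact.  The 20-seed
replicate check for two-shell peak recovery samples populations without
rendering, which is what the property concerns.
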