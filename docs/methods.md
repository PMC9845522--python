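# Methods

## Scope and model

`osseoquant` quantifies the degradation of a biodegradable screw in bone and
the tissue response around it, from exclusive voxel label maps (background,
residual metal, degradation layer, bone, gas) with physical voxel spacing.
All quantities are voxel counts times voxel volume, surface-voxel counts, or
distance-transform constructions; nothing depends on grayscale data. The
"implant" is always residual metal plus the attached degradation layer.

Time is converted as 1 week = 7 days, 1 year = 365.25 days; degradation
rates are reported in mm/year. `A_i` in the rate equation is always the
*initial* (non-degraded) surface area, never the current degraded one, so
the rate is a mean recession speed of the original surface.

## The phantom generator

The phantom stands in for segmented scans and defines the conditions under
which the pipeline is validated.

**Screw.** An analytic signed-distance field (SDF): a core cylinder carrying
a trapezoidal thread (root half-width 0.3 × pitch, crest half-width
0.08 × pitch) swept helically, a cylindrical head with an off-center drive
notch, and a linearly tapered tip. Defaults approximate a 3.5 × 16 mm
cortical compression screw (2.4 mm core, 1.25 mm pitch); voxelized at
0.05–0.2 mm it measures ≈ 111 mm³ and ≈ 229 mm², matching real screws of
this format (≈ 112 mm³, ≈ 227 mm²). The drive notch is not cosmetic: a
screw is otherwise nearly invariant under rotation about its axis combined
with a compensating axial shift (that is what makes it a screw), and the
notch makes the rigid pose fully determined for registration.

**Pose.** Both the implanted screw and the reference scan are placed at
small generic poses (≈ 2° tilts plus sub-voxel offsets). A perfectly
grid-aligned solid is an artifact no scanner produces: its flat faces
coincide with voxel-center planes, volume convergence degrades from
O(spacing²) to O(spacing), and sub-voxel surface recession quantizes to
whole voxel layers. The relative pose between reference and implanted screw
is recorded as registration ground truth.

**Degradation.** Uniform surface recession of depth *d* is applied on the
continuous SDF (`sdf < -d`), which remains exact for depths below one
voxel — a 10 µm recession is meaningful on a 20 µm grid. For arbitrary
*mask* inputs (no SDF available), `apply_degradation` instead thresholds
the anisotropy-aware Euclidean distance transform of the mask; this is
faithful but quantized to the grid, so depths under one voxel leave a mask
unchanged. The degradation layer is a shell grown outward from the residual
metal by `layer_thickness`; it may swell slightly beyond the original
surface, as corrosion products do. Label precedence on overlap:
residual metal > degradation layer > gas > bone > background.

**Bone environment.** Along the screw axis from the head: entry cortex
(default 1.5 mm, fully mineralized), an intramedullary cavity (4 mm) lined
by a cortical tube of the same wall thickness, trabecular bone up to the
physis plane (11 mm), a 0.6 mm mineralized-tissue-free physis gap, then
trabecular bone to the end of the grid. Trabecular bone is a Gaussian
random field (strut scale 0.4 mm) thresholded at the exact quantile for the
requested fill fraction (default 0.30, a typical metaphyseal BV/TV), so the
generated fraction equals the request by construction. The four compartment
masks (dpROI, ppROI, cROI, iROI) exclude the screw voxels — the drill
analogue — and are pairwise disjoint. Gas pockets are analytic spheres
rasterized with the precedence above; their per-compartment volumes are
recorded from the rasterized voxels, hence exact.

**What the phantom does not emulate.** Scanner noise, beam hardening,
partial-volume gray values and segmentation error; cracked or spatially
heterogeneous corrosion layers; mechanistic (electrochemical) corrosion;
curved anatomy — compartments are plane slabs and coaxial tubes. Passing
recovery tests therefore demonstrates the correctness of the *measurement*
chain on ideal segmentations, not robustness to segmentation error.

## Registration

Only labels exist in this pipeline, so the overlap metric is the Dice
coefficient of binary masks, and the transform is rigid (screws are
machined bodies; the reference is the same physical size). The procedure is
fully deterministic:

1. **Initialization**: centroid alignment; rotation candidates are the
   identity, the two minimal rotations aligning the long principal axes
   (both orientations), and the four proper principal-triad sign
   combinations (resolving 180° flips). Best Dice wins; ties favor the
   identity. Full-triad alignment alone is avoided as the primary
   candidate because for a nearly axisymmetric body the transverse axes
   are noise, injecting an arbitrary spin.
2. **Refinement**: coordinate descent over the six parameters (fixed sweep
   order, step halving from 2 mm / 10° down to 0.01 mm / 0.05°), accepting
   only strict improvements, so the objective is non-decreasing.

The objective is a *soft* Dice: the reference mask's voxel-center points
(subsampled by a fixed stride above 150k points) are mapped through the
trial transform and the target mask is sampled trilinearly. A hard
nearest-voxel count is piecewise constant and stalls the descent on
sub-voxel plateaus.

An intrinsic limit worth knowing: after eroding *k* voxels from the target
surface (as corrosion does), any pose within slack ≈ erosion/lever-arm of
the truth has identical overlap. For rotation about the screw axis the
lever is only the screw radius, so on a 0.1 mm grid a 2-voxel erosion
leaves the axial spin determined only to a few degrees; on a 0.03 mm grid
the same construction pins it below 2°. Transform-recovery checks are run
at 0.03 mm for this reason.

Label resampling is nearest-neighbor only (labels are categorical), with
scipy's standard rounding at exact half-voxel ties; voxels mapping outside
the source grid become background. Rotations are intrinsic Euler angles
about the array axes (0, 1, 2) in that order, about the reference-mask
centroid, with translation applied after.

## ROIs and metrics: numerical choices

- Distances are exact Euclidean distance transforms with the physical
  sampling, so anisotropic grids are handled correctly; distance is zero
  inside the mask, and shells explicitly exclude the mask itself.
- A shell thinner than one voxel (the 30 µm shell on a ≥ 30 µm grid) is an
  error in strict mode; lenient mode proceeds with a one-voxel effective
  shell and a warning. The 30 µm shell is only meaningful on
  synchrotron-scale grids.
- The gas ROI is reported both with and without the implant voxels; GV/IV
  needs the implant volume separately anyway, and whether published ROI
  volumes included the screw is generally ambiguous.
- Surface voxels (BIC) use 6-connectivity by default — face adjacency is
  the standard digital surface definition — with 26-connectivity exposed;
  both are validated against a brute-force neighbor-enumeration oracle.
  Voxels beyond the grid edge count as background.
- Mesh surface areas are marching cubes at iso-level 0.5 after smoothing
  the binary mask with a one-voxel Gaussian. Iso-surfacing a raw 0/1 grid
  leaves staircase facets that overestimate oblique surfaces by up to
  ~10%; with smoothing a digital sphere's area is recovered well within
  1%. The `face_count` method (exposed voxel faces) is exact for the
  digital solid and documented to overestimate smooth surfaces by up to
  ~1.5×. Note the mesh estimate needs the features resolved: on grids
  coarser than the thread scale it underestimates a threaded screw.
- Negative volume loss (residual > initial, e.g. segmentation variance) is
  reported with a `negative_vl` flag, never clamped.
- BV/TV excludes implant and gas voxels from numerator *and* denominator,
  making it invariant under gas ↔ implant relabeling inside the ROI.

## Pipeline choices

- Per-compartment volume loss sections the implant by assigning every
  voxel to its *nearest* compartment (via distance maps, ties breaking in
  dpROI, ppROI, cROI, iROI order), since the compartment masks themselves
  exclude the screw. The local rate uses the reference surface area within
  the section by default (`subroi_area_mode="local"`); the whole-screw
  area is available as an alternative normalization.
- In phantom mode the true pose is known and used directly unless
  registration is explicitly requested; in import mode registration is on
  by default.
- Reports are sorted by (sample, timepoint, ROI, metric) and written with
  a fixed float format, so identical config + seed give byte-identical
  files; a manifest records the config hash, seed and package versions.
- Any stage failure aborts the run with a stage-labeled error and removes
  partial outputs.

## Problem sizes used in the test and acceptance suites

Chosen to probe each claim at the scale where it is meaningful: unit tests
and pipeline checks run phantoms at 0.15–0.25 mm spacing (≈ 10⁶-voxel
grids); degradation-rate recovery runs at 0.02 mm (the sub-voxel-recession
regime, ≈ 6.7 × 10⁷ voxels); registration recovery at 0.03 mm (where the
erosion slack permits a sub-2° bound); counting oracles on 16³–24³ grids
where brute force is exact and fast.

## Known limitations

- Mask-based (EDT) recession cannot represent sub-voxel depths; use the
  analytic path for phantoms, or finer grids for real masks.
- Mesh surface area is unreliable when surface features approach the voxel
  size (see above); the degradation-rate denominator should come from a
  grid that resolves the threads.
- Axial spin after heavy surface loss is weakly determined by any overlap
  metric; treat reported spin angles accordingly.
- Compartment geometry is idealized; importing manually drawn ROI masks is
  the intended path for real anatomy.
- One sample per configuration: the pipeline produces measurements, not
  statistics across animals.
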