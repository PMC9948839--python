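# Methods

## The sensitivity-analysis model

`segsense` treats a trained segmenter as a black box `f : image → labels`
and estimates the map

    S(θ) = DSC( reference(θ), f(T_θ(image)) ),   θ ∈ Θ,

where `T_θ` is a parameterized perturbation (rigid rotation about the x/y
axes, or an intensity transform `i ↦ scale·i + offset`) and `Θ` is a finite
grid. Every grid point starts from the pristine input volume — perturbations
are never chained — so cells are independent and the map does not depend on
evaluation order. Two reference modes exist:

* **ground_truth** — the reference is the ground-truth label volume under
  the *same* transform. For rotation grids the comparison is made in the
  rotated space (labels resampled nearest-neighbor alongside the image);
  for intensity grids the labels are untouched. Comparing in rotated space
  rather than back-rotating the segmentation avoids a second resampling of
  the prediction; the identity grid point therefore equals the direct
  `DSC(f(image), labels)` with no round-trip error.
* **staple** — for segmenters without ground truth. Every segmentation is
  back-rotated into the pristine space with the exact inverse rotation
  (nearest-neighbor; the inverse uses the transposed rotation matrix, not
  re-composed Euler angles, so composed x/y rotations invert exactly), a
  per-label binary STAPLE consensus over all back-rotated segmentations
  serves as the reference, and scoring is restricted to the common field
  of view (the intersection of the round-trip validity masks; voxels that
  ever left the volume are excluded from both consensus and scores). Maps
  in this mode are *relative* to a reference estimated from the very
  segmentations being scored, so they are qualitative by construction.

### Conventions

Rotations are extrinsic about the fixed world axes, right-handed, positive
counter-clockwise looking down the axis; a combined (x, y) grid point
applies the x-rotation first (`R = R_y R_x`). The rotation center is the
geometric volume center, the intensity-weighted center of mass, or an
explicit point in mm; it is resolved once on the pristine volume and then
held fixed as an explicit point, so forward and inverse transforms share
one geometry even when the perturbed image's mass center would differ. The
convention string and center are written into every map's provenance.
Images are resampled trilinearly, labels nearest-neighbor (no new label IDs
can appear). Out-of-field image voxels take the volume's background level,
estimated as the median of the one-voxel boundary shell — the mode of a
continuous-valued image is ill-posed, and the boundary median equals it for
any volume whose edges are background (≈0 after z-normalization); it can be
overridden with `pad_value`. Diffusion b-vectors are rotated by the same
world-space matrix as the volume; 4-D series rotate every 3-D sub-volume
with the same transform (rigid-body assumption).

Z-normalization (zero mean, unit variance volume-wise) is exposed as an
explicit, optional step (`RunOptions.normalize`) rather than built into the
sweep, so intensity perturbations can be configured to act before or after
it.

### Grids

| grid | axes | values | size |
|---|---|---|---|
| `rotation_grid_case1` | x, y angle | −180° … 180°, 20° steps | 19×19 = 361 |
| `rotation_grid_case2` | x, y angle | −16° … 16°, 2° steps | 17×17 = 289 |
| `intensity_grid_case1` | scale, offset | scales 1/5, 1/4.5, …, 1/1.5, 1.0, 1.5, …, 5.0; offsets −3.0 … 3.0 in 3/8 steps | 17×17 = 289 |

Custom grids of any dimension are supported; heat-map rendering is limited
to 2-D.

### Summaries

`map_summary` reports mean and standard deviation (population convention,
ddof 0 — the map is the full population of grid cells, not a sample), the
maximum, and the argmax's offset from the identity point. Argmax ties break
to the first maximum in row-major axis order and all tied coordinates are
reported. Degenerate cells (empty-reference vs empty-prediction, DSC 0/0)
are scored 1.0 with a flag, and flagged cells are excluded from all means —
this keeps maps comparable across subjects when a structure leaves the
field of view. `aggregate_maps` averages coordinatewise over subjects (per
label) or over labels (after per-map label averaging).

## STAPLE

Binary EM with a global foreground prior. The prior defaults to the mean
foreground fraction across raters ("auto"); initialization is
p_k = q_k = 0.9999 (the canonical near-perfect start, which avoids the
label-swapped fixed point); the E-step is computed in log space; iteration
stops when the mean absolute posterior change falls below 1e-6 (max 100
iterations). The observed-data log-likelihood trace is recorded and is
non-decreasing to numerical tolerance — a property the tests assert.
Consensus probabilities are thresholded at 0.5 (configurable). Multi-label
consensus runs binary STAPLE per label ID. Degenerate rater sets (uniformly
all-foreground or all-background) are rejected: the performance parameters
are unidentifiable there. The estimate is only meaningful when enough
raters are meaningful; a test demonstrates consensus degradation when more
than half the raters are random masks. A SimpleITK cross-check on a small
fixture confirms the consensus against an independent EM implementation.

## Augmentation samplers

*Rotation*: each of x, y, z mirrored independently with probability 0.5
(type 1); type 2 additionally draws an x-rotation uniformly from
{0°, 30°, 50°} — mirroring is applied first, though for axis-aligned
mirrors combined with an x-rotation the generated operator set is the same
either way. The angle choice is uniform and unsigned; the x-axis is the
natural head-nodding axis.

*Intensity*: landmarks are intensity quantiles at 12.5%…87.5% in 12.5%
steps (7 landmarks), linear interpolation between order statistics,
computed over all voxels without foreground masking (the simplest auditable
choice — the model sees whatever intensity scale the network would see).
For every *ordered* pair of landmark sets a quadratic is least-squares
fitted ("all possible pairs" with an asymmetric transfer function implies
direction matters; n sets give n·(n−1) fits); the per-coefficient normal
fit is the sample mean and sample standard deviation (ddof 1), which is the
maximum-likelihood/unbiased reduction for a location-scale family. Fits are
not constrained to be monotone over the intensity range; with 7 landmarks
spanning the bulk of the histogram, non-monotone fits indicate genuinely
incompatible histograms rather than a fitting artifact. The fitted model
serializes to JSON.

## Synthetic fixtures

The phantom is an ellipsoid with distinct semi-axes (default 0.30/0.14/0.09
of the volume shape), displaced from the volume center, plus a spherical
protrusion at the +x tip of its long axis pushed off both mid-planes. This
combination has no mirror or rotational self-symmetry: its DSC against any
non-identity rotation of the 20°-step full-circle grid, and against any
axis mirroring, stays below 0.9 (asserted in tests). That matters because
the template-matching toy segmenters discriminate orientations only if the
structure itself does. Default contrast is background 0, foreground 1, with
additive Gaussian noise σ = 0.05 — a ~20:1 contrast-to-noise ratio typical
of a well-normalized structural acquisition; foreground occupies ~2% of the
volume (brain-structure scale). All generators are seed-deterministic.

Toy segmenters: a threshold segmenter (intensity window + largest connected
component) is the minimal model with intensity sensitivity; template
segmenters (normalized cross-correlation over a candidate orientation bank)
emulate models trained without (`identity_only`) and with (multi-orientation
bank) rotation augmentation. The oracle segmenter returns the ground truth
under the same transform the engine applied — a segmenter seeing only the
perturbed image cannot know that transform, so the engine passes it to
segmenters that opt in via a `wants_transform` attribute; this is test
plumbing for the perfect-segmenter upper bound, not part of the segmenter
contract. `inject_orientation_bias` pre-rotates a phantom to emulate a
misoriented training sample: a template built from it peaks at the injected
angle when the pristine phantom is swept, which is the argmax-offset bias
diagnostic.

## Problem sizes and numerics

The shipped study sizes are chosen for desk-scale determinism: phantoms
48³ (64³ for STAPLE recovery), rotation sub-grids 5×5 over ±40°, the full
17×17 intensity grid, 200 random 16³ mask pairs for the Dice cross-check,
10⁴ draws for sampler frequencies. The full synthetic study runs in well
under a minute on one CPU; the qualitative conclusions (band structure,
flattening under augmentation, bias recovery within one grid step) are
stable across seeds at these sizes. Gradient-scheme vectors off unit norm
by ≤1e-3 are renormalized, beyond that rejected; labels must be integral to
1e-6 on read. What passing tests on phantoms does *not* show: robustness
conclusions about real MRI (no bias fields, no partial-volume effects, no
anatomy-dependent contrast), absolute DSC levels of any real network, or
STAPLE behavior on correlated raters (simulated raters err independently;
real segmentations share systematic errors).

## Known limitations

Binary STAPLE with a global prior only (no spatially varying priors or MRF
variants); heat-map rendering is 2-D; rotation grids rotate about x and y
only (the z-axis is available through `RigidRotation` but not gridded);
custom grids require a user transform factory; no DICOM ingestion or
preprocessing (denoising, bias-field correction, registration) — those are
upstream of this tool.
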