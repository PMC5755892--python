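# Methods

## Problem and model

Paranasal CT is the standard modality for assessing maxillary sinus (MS)
disease, but volume quantification is usually manual or semi-automated.
`sinusvol` implements a fully automated pipeline that locates both maxillary
sinuses on an axial CT stack and reports, per side, the **total** cavity
volume, the **air** volume, and the **involvement** volume (mucosal
thickening, cysts, fluid — everything inside the sinus that is not air),
with total = air + involvement by construction.

The segmentation is a per-slice hybrid of classical operators:

1. **Bone thresholding.** Voxels with HU ≥ 150 are bone (closed lower
   bound). This exposes the bony sinus walls and removes soft tissue,
   mucosa and fluid from the mask.
2. **Morphological opening** with a disk of radius 2 px, then removal of
   connected components smaller than 20 mm², to suppress noise specks in
   the bone mask.
3. **Watershed.** The HU landscape of the slice is smoothed with a Gaussian
   (σ = 1 px); cleaned bone pixels are raised far above any tissue value so
   they act as ridges; the surface is flooded from its regional minima into
   a complete partition — every pixel gets exactly one basin, air cavities
   become deep basins, bone walls become basin boundaries.
4. **Rule-based selection** keeps, per side, the largest basin that passes
   all individual rules: area within [50, 3000] mm², solidity ≥ 0.6, and
   centroid inside a lateral band (5–45 % of image width from the side's
   lateral edge) and an axial band (25–85 % of image height). On the seed
   slice, if both sides have a surviving basin the pair must also be
   roughly symmetric (area ratio ≤ 3, mirrored-centroid distance ≤ 15 mm).

The pipeline starts on the middle slice (falling back outward up to ±25 %
of the stack if neither sinus is accepted there) and then propagates each
side independently, slice by slice in both directions. A basin on a new
slice is accepted only if it passes the individual rules **and** overlaps
the previous slice's accepted region with Dice ≥ 0.3 — the overlap guard
prevents the walk from jumping to a different cavity. The first failing
slice stops that direction, yielding a contiguous volumetric region per
side.

Inside a region, voxels are banded by HU: **air** in [−1200, −200] HU
(closed bounds), **involvement** in (−200, 150) HU. Voxels at or above the
bone threshold (intruding septa) or below −1200 HU are excluded from both
classes and from the total. Volumes are voxel counts × voxel volume
(product of the three spacing components); meshes exported for display are
never used for measurement.

## Numerical choices

- **Shallow-minimum suppression.** Regional minima of a noisy smoothed HU
  surface would fragment both the cavities and the background into
  noise-scale basins. Minima shallower than `min_basin_depth_hu` (default
  100 HU) are therefore suppressed by greyscale reconstruction by erosion
  before the markers are extracted. 100 HU sits far above the residual
  noise after smoothing (≈4 HU for 15 HU input noise at σ = 1 px) and far
  below the air–tissue contrast (≈1000 HU), so each air cavity yields one
  marker while every enclosed region keeps a marker of its own and the
  partition stays complete.
- **Boundary conventions.** HU ≥ 150 is bone; the air band is closed at
  both ends; the involvement band is open at both ends and tied to the
  bone threshold so air + involvement partitions the non-bone region.
- **Tie-breaks.** Equal-area surviving basins are ordered by basin id
  (ids assigned in raster order of the watershed markers); the pipeline
  contains no randomness, so a fixed input and parameter set always gives
  the identical label map.
- **Degenerate inputs.** A constant slice is a single basin; a volume with
  no candidate anywhere in the seed window raises a segmentation-failure
  error rather than returning an empty result.

All thresholds above are explicit fields of `SegmentationParams` /
`RuleParams` and can be overridden from a flat `key = value` config file or
`--param` CLI flags; the resolved values are embedded in every report.

## The phantom generator

`sinusvol.phantom` builds head-like test volumes with analytically known
ground truth: a soft-tissue block (40 HU) containing, per side, an
ellipsoidal air cavity (−1000 HU) enclosed by a 1.5 mm bone shell (700 HU),
optionally lined by mucosa (30 HU, configurable thickness), optionally
part-filled with a dependent fluid layer (the lowest fraction of the
cavity's height, delimited by a continuous axial plane so the
ellipsoid-cap volume formula applies exactly), plus additive Gaussian HU
noise and, by default, a midline low-HU "nasal cavity" channel that
exercises the position rules of the basin selection. The default grid is
80×256×256 at 0.5×0.35×0.35 mm spacing, matching a thin-slice paranasal
reconstruction.

Ellipsoids were chosen over anatomical meshes because exact volumes
(4/3·π·abc, minus the cap below the fluid plane) give an oracle for every
stage; rotation is restricted to a single in-plane angle so the fluid-plane
analytics stay exact. Ground truth (volumes and label map) is computed from
voxel-centre membership before noise is added.

The validation cohort (`generate_cohort`) draws per-side semi-axes
z ∈ [12, 16], y ∈ [12, 18], x ∈ [9, 14] mm, centre jitter ±2 mm, mucosa
thickness [0.5, 2.5] mm and fluid fraction [0, 0.3] uniformly, with 15 HU
noise — mean cavity volume ≈ 10 cm³, inside the adult range reported
across the MS literature and sized so both sinuses plus walls fit the
default grid. Noise seeds are derived per exam from the base seed, so a
cohort is fully reproducible from `(seed, ranges)`.

What the phantom deliberately does **not** emulate: partial-volume blur at
tissue interfaces, beam hardening and streak artifacts, the maxillary
ostium (cavities are closed), dental metalwork, and real anatomical shape
variation. Passing the phantom suite therefore demonstrates the logic and
the geometry handling of the pipeline, not clinical-grade accuracy on
patient data; on clean phantoms the residual error is essentially
voxelisation error (≲0.5 %), far below the ≈7 % agreement one can expect
against a human reference standard.

## Agreement statistics

`sinusvol.agreement` implements the method-comparison toolkit used to
validate automated volumetry against a reference standard, treating each
sinus as an independent observation:

- absolute percent difference 100·|automated − reference| / reference
  (the reference is the natural denominator, and the absolute value
  matches reporting a positive mean ± SD);
- ordinary least squares of automated (y) on reference (x), with R² the
  squared Pearson correlation;
- Bland–Altman bias (mean of automated − reference) and limits of
  agreement bias ± m·SD (sample SD, n−1), with m = 1.96 by default and
  2.0 available — at typical printed precision the two are
  indistinguishable.

`sinusvol validate` re-enacts the validation design end to end: generate a
seeded cohort, segment every exam, pair automated volumes with the
analytic truth as reference, and emit the agreement report. Exams whose
segmentation fails are excluded and counted.

## Problem sizes

The shipped tests exercise full-size 80×256×256 phantoms for the 30-exam
cohort check (about 3 s per exam on one core) and a reduced 40×128×128
phantom for the per-operation tests; morphology oracles run on ≤32×32
grids where brute-force enumeration is feasible.

## Known limitations

- Only the maxillary sinuses are modelled; the rule bands would need
  re-tuning for other paranasal sinuses.
- Left/right assignment falls back to the radiological image-column
  convention when orientation metadata is absent.
- The propagation stop rule has no gap tolerance: a single slice that
  fails the rules terminates that direction.
- No resampling: strongly non-uniform slice gaps (>5 % variation) are
  rejected rather than interpolated.
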