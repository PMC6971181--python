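# Methods

## Problem and model

Diffuse low-grade glioma (WHO grade 2) eventually undergoes malignant
transformation: new, significant contrast enhancement on T1-gadolinium
MRI. Where that enhancement appears relative to the previously visible
tumor determines whether loco-regional treatment (resection margins,
radiation fields) could plausibly have covered it. `lggspat` quantifies
that spatial relationship from three co-registered binary masks per
patient:

* `preoperative` — T2/FLAIR hyperintense tumor before first surgery
  (may be absent for historical cases);
* `pre_transformation` — T2/FLAIR tumor on the last scan before
  transformation was detected;
* `transformation` — the new contrast-enhancing volume.

All masks must live on one voxel grid (shapes equal, affines equal to
1e-3 mm per entry). Registration and resampling are deliberately out of
scope: they belong to upstream tools (deformable registration toolkits),
and silently resampling label masks here would hide interpolation
choices that change volumes and distances.

Three read-outs are computed.

**Clinical rule (local / distant / combined).** The transformation mask
is split into 26-connected components ("foci"); components below
0.01 ml are dropped as segmentation noise. Each focus is *local* iff its
minimum surface distance to the pre-transformation tumor is strictly
below 20 mm, *distant* otherwise; a patient with both kinds has a
*combined* transformation. Distance is the minimum voxel-center to
voxel-center Euclidean distance in world millimetres, i.e. an
edge-to-edge measure on the available geometry (the masks); its error
relative to a true sub-voxel surface distance is bounded by one voxel
diagonal and symmetric across cases. The rule is deliberately strict at
the threshold (exactly 20.0 mm → distant), which preserves the
definition "local means < 2 cm" verbatim; the event has measure zero in
practice. Measuring in 3D can differ from a single-slice in-plane
reading on thick-slice acquisitions; with the anisotropic sampling
below, 3D distance is never larger than the in-plane one.

**Overlay model (within / outside).** The transformation is *within*
the reference tumor volume when the masks intersect in at least one
voxel (configurable). Any overlap counts — a clinically combined case
with one overlapping focus is still "within", i.e. overlap takes
precedence. The reference is the preoperative tumor by default and can
be switched to the pre-transformation tumor as a sensitivity analysis.
Cases without a preoperative mask are `not_evaluable` and are excluded
from overlay denominators.

**Unit-cube centroid model.** The preoperative tumor is abstracted as a
unit cube centered on its centroid; the transformation centroid is
expressed as `u_i = (cT_i − cP_i) / h_i`, with `h_i` the preoperative
bounding-box half-extent per world axis, floored at half a voxel so
single-slice tumors stay finite. The scalar `distance_ratio = ‖u‖₂`;
inside/outside the cube is judged by the max-norm. Normalizing by the
bounding-box half-extent is the simplest mapping under which "border of
the cube" means "border of the tumor extent"; a radial ray-to-surface
ratio would be an alternative with different dot positions (but the same
center case) and is not implemented. Multifocal transformations use the
whole-mask centroid with a `multifocal_caveat` flag, since the centroid
of disjoint foci can land where no tumor is. Distant cases are excluded
from the cohort point cloud: their position is unrelated to the
preoperative tumor's geometry.

## Numerical choices

* **Distances.** The exact Euclidean feature transform
  (`scipy.ndimage.distance_transform_edt`) is run with the per-axis
  world spacing as sampling, so thick slices are not treated as
  isotropic. `min_surface_distance` recomputes the final distance from
  the feature transform's index offsets with the same arithmetic as a
  brute-force pairwise scan; the two agree exactly, not merely to a
  tolerance, which the test suite asserts on random anisotropic masks.
  Grids with sheared (non-orthogonal) voxel axes are rejected rather
  than mis-measured.
* **Connected components.** Default connectivity 26: clinical reading
  treats diagonally touching enhancement as one lesion; 6-connectivity
  would inflate multifocality. Components are ordered by decreasing
  volume with ties broken by the lexicographically smallest voxel index,
  so labeling is deterministic.
* **Bounding boxes / unit cube.** Axis-aligned affines only
  (permutations and sign flips allowed). Supporting oblique grids would
  silently change what the cube's axes mean; oblique acquisitions should
  be resampled upstream.
* **Quartiles.** Linear interpolation between order statistics
  (`numpy.percentile` default). Percentages are rounded half-up to whole
  percent, matching clinical-table style.
* **Determinism.** Report files fix column order and format floats at 6
  significant digits, so identical inputs give byte-identical outputs.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not MRI appearance: voxelized ellipsoids and spheres on a 96³ grid at
2 mm isotropic resolution by default. Per case it draws

* preoperative volume log-uniform on 6–150 ml (median 30 ml, quartiles
  ≈ 13–67 ml — the scale regime of adult LGG cohorts), with mild random
  anisotropy at fixed volume and a ±4 mm center jitter;
* a pre-transformation tumor as the same ellipsoid scaled radially by
  1.15 (growth without shrinkage, so the preoperative tumor is always
  contained); the lower volume tail makes a few percent of
  pre-transformation tumors fall below the 10 ml residual cutoff;
* transformation foci with volumes log-uniform on 0.3–6 ml (median
  ≈ 1.3 ml), placed per mode: `inside` and `rim` foci overlap the
  preoperative tumor (ground truth local/within), `near` foci sit at a
  verified surface distance in (0, 18) mm (local/outside), `far` foci at
  more than 22 mm (distant/outside);
* a clinical mixture of 91% local / 7% distant / 2% combined, a second
  focus for 26.4% of local cases (≈ 26% multifocal overall), histology
  at 28/37/30/5% (oligodendroglioma / astrocytoma IDH-mut / IDH-wt /
  NOS), prior resection/chemo/radiotherapy at 49/33/54%, and a missing
  preoperative mask in 16% of cases. The inside/rim/near split of local
  foci (70/15/15%) is a package choice — no clinical source itemizes
  it — and is configurable per recipe.

Near/far placement is rejection-sampled: a direction is drawn, the
sphere is placed at the target distance beyond the pre-transformation
surface, and the *voxelized* distance is measured; the draw is accepted
only if it lands within one voxel diagonal of the target and clear of a
±2 mm exclusion band around the 20 mm threshold. Foci are kept at least
two voxel diagonals of surface separation apart so they can never merge
into one component. Ground truth is therefore unambiguous by
construction, which is what makes the 100%-recovery property a test of
the classifier rather than of luck. Each case uses an independent random
stream derived from (cohort seed, case index), so cohorts are
reproducible case by case.

What the generator does *not* emulate: infiltrative, non-convex tumor
morphology; segmentation disagreement between raters; registration error
beyond optional rigid jitter; post-surgical cavities and gliosis (which
in real data can bias the overlay model by letting tissue collapse into
the former tumor bed). Passing tests on synthetic cohorts demonstrates
that the geometry and bookkeeping are correct under the stated
assumptions — not that any particular clinical percentage generalizes.

## Problem sizes

The bundled checks run a 200-case default-recipe cohort (seed 42) for
classification recovery and the Tables-shaped summaries, 200 random
anisotropic mask pairs against the brute-force distance oracle, 50
random cases for the invariance suite, and 50 point-like cases for the
centroid closed form. `scripts/acceptance.py` regenerates a 200-case
cohort from its `--seed` and recomputes all headline quantities from
scratch.

## Known limitations

* Voxel-center distances under-estimate true surface distances by up to
  one voxel diagonal; at 2 mm isotropic this is 3.5 mm, which is why the
  generator enforces the exclusion band rather than trusting
  quantization.
* The overlay model is binary; it does not grade how much of the
  transformation lies inside the reference volume (the overlap volume is
  reported for that).
* The unit-cube mapping is one of several defensible normalizations of
  an irregular tumor; positions away from the center depend on that
  choice.
* With one shared grid required, longitudinal scans acquired at
  different resolutions must be resampled before import.
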