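# Methods

This note describes the models and numerical choices behind `cammesh`: the
video-processing pipeline itself, the synthetic CAM video generator used to
validate it, and the places where the design was genuinely open.

## Movement correction

Intravital CAM recordings drift slowly in-plane (the blood film floats on
the yolk). Frames are aligned by maximizing the zero-normalized
cross-correlation (ZNCC) of a high-contrast reference square between frame
0 and every later frame. Choices and their reasons:

* **Integer shifts only.** The downstream statistics are per-pixel temporal
  moments; sub-pixel interpolation would low-pass each pixel's time series
  and bias the SD image. Rigid integer translation keeps every sample
  untouched.
* **Incremental search, absolute expression.** Frame *t* is searched in a
  window of `± max_shift_px` around frame *t−1*'s shift (drift is smooth,
  so the window can stay small), but the reported displacement is always
  relative to frame 0. A recovered shift whose magnitude exceeds
  `max_shift_px` raises a registration error naming the frame.
* **ZNCC** is invariant to affine intensity drift (illumination changes
  between frames), which plain SSD is not. A zero-variance window scores
  0; exact ties are broken toward the smallest `|d_row| + |d_col|`, then
  lexicographically, so results are reproducible bit for bit.
* **Valid region, not padding.** After alignment the stack is cropped to
  the rectangle covered by every shifted frame. Padded values would enter
  the temporal statistics as artificial steps.
* The automatic reference-square selector maximizes the square's intensity
  SD over a stride-8 coarse grid with local refinement, keeping a margin
  of `max_shift_px` from the border so the search window never leaves the
  frame. On small frames the square defaults to three quarters of the
  usable side; on full-size recordings it is 256 px (configurable to 512).

## Projection images

* **Vessel (SD) image**: per-pixel *population* standard deviation over
  time (divide-by-T). The population/sample choice only rescales the image
  and is irrelevant after normalization, but it is fixed so oracle tests
  are exact.
* **Perfusion image**: per-pixel sum of absolute successive differences.
  Signed differences would telescope to `I_T − I_0` and lose the
  amplitude-times-frequency meaning, so the absolute value is essential.
  The witness time series (0,0,10,10) vs (0,10,0,10) — equal SD 5,
  perfusion 10 vs 30 — is kept as a permanent regression test of this
  distinction.
* **Normalization** divides by the image maximum only. Both statistics
  have a physically meaningful zero ("no change"), which subtracting a
  minimum would destroy. All-zero images are passed through with a
  warning. Normalized products are relative quantities: nothing in the
  pipeline depends on camera bit depth or gain.
* **Pseudo-color** uses a 256-entry perceptually-uniform LUT
  (dark blue → yellow, strictly monotone luminance) stored as CSV inside
  the package, so renderings are reproducible bit for bit regardless of
  the plotting stack installed.

## Segmentation

The chain is Gaussian enhancement → double threshold → skeletonization →
island extraction, with one connectivity convention throughout:
8-connected foreground, 4-connected background.

* **Enhancement**: `scipy.ndimage.gaussian_filter` with reflective
  boundaries, default `sigma = 0.7 px`. The value was calibrated on the
  synthetic generator (below): larger sigmas widen the detected vessel
  beyond the true lumen and cost overlap accuracy; smaller ones leave
  single-pixel noise.
* **Double threshold**: the union of a global Otsu threshold (main
  vessels) and a local threshold `pixel > local_mean(window) −
  local_offset` (small and secondary vessels). Defaults: window 51 px,
  offset −0.025 on the unit-normalized SD scale, i.e. a pixel must exceed
  its neighborhood mean by 2.5 % of the image maximum. Both were
  calibrated on the generator: the offset is the most permissive value
  that still rejects smoothed tissue noise, because a single missed
  capillary wall merges two tissue islands and corrupts the island count.
  Components under 20 px are pruned; pruning cannot break the
  union-superset-of-global property because any surviving global component
  is contained in an at-least-as-large union component.
  A perfectly flat image has no Otsu threshold and yields an all-false
  mask with a warning.
* **Skeletonization**: homotopic thinning (`skimage.morphology.skeletonize`).
  The contract asserted in tests is topological, not algorithmic: the
  skeleton is a subset of the mask and preserves the 8-connected component
  count and the Euler number, verified against an independent bit-quad
  counting oracle on randomized masks.
* **Tissue islands** are the holes of the vessel mask: 4-connected
  background components that do not touch the image border (enclosure
  cannot be established for border-touching background), cleaned by a
  disk-opening of radius 2 px and filtered at 30 px minimum area.
* **Diameters**: `2·EDT − 1` at skeleton pixels, where EDT is the
  Euclidean distance to background; the −1 accounts for the center pixel
  itself (a 1-px vessel has EDT 1 and diameter 1). Skeleton pixels within
  one local radius of a branch point are excluded, since the distance
  transform at junctions reflects the junction blob, not a vessel width.
* **Perfusion heterogeneity (`perf_cv`)** is the coefficient of variation
  of the perfusion image over vessel pixels *after* smoothing the map with
  a fixed 3-px Gaussian. The raw per-pixel perfusion value in a capillary
  is dominated by the shot noise of individual red-cell passes
  (spatially uncorrelated); smoothing at the capillary scale suppresses
  that term and leaves the between-vessel flow structure, which is what a
  heterogeneity index should measure. Without the smoothing the index
  ranks a noisy isotropic mesh above a network with a dominant vessel.

## Area dynamics

Landmark quads are treated as planar simple polygons; the area is the
shoelace formula (via `shapely`), orientation-independent. Relative-area
traces start at exactly 1.0. Quad interiors are rasterized by a strict
pixel-center-inside test, which makes density additivity over a partition
testable: pixels whose centers fall exactly on a shared edge belong to
neither part, bounding the additivity error by the edge length over the
area (≪ 1 % for the region sizes used).

## Synthetic CAM scenes and videos

The generator produces the statistical structure the pipeline assumes,
with exact ground truth. It does not attempt hemodynamics or biological
remodeling — presets are static snapshots.

**Geometry.** Capillaries are the ridges of a Voronoi tessellation of a
jittered square grid (mean island diameter 48 px at 512×512, the scale of
a ~10× magnified CAM field); mirror points outside the working box keep
all cells finite. Interior cells — those whose walls are all mesh ridges —
are enclosed by capillaries and become tissue islands; border cells are
open to the surround and are deliberately not islands, matching the
pipeline's enclosure rule. Island ground truth is derived from the
rendered lumen raster by the same hole-extraction rule the segmentation
uses, so scoring is symmetric.

**Phase presets.** The maturation of a mesh into a vessel is encoded as
four constructions sharing one fixed "pathway" rectangle (18 px tall,
spanning the field) for comparable metrics:

| preset | construction |
|---|---|
| I | uniform diameters N(3, 0.25) px, flows N(1, 0.05) |
| II | segments crossing the midline: diameter ×2.2, flow ×3 |
| III | midline segments replaced by an 18-px channel (flow 6); feeders widened ×1.8; exactly 2 residual islands punched into the channel |
| IV | 26-px channel (flow 10); adjacent islands merged pairwise (walls removed); capillary flows ×0.6 |

These encode the qualitative phase signatures — rising diameter
heterogeneity, island loss along the pathway, flow concentration — and the
tests assert exactly those orderings, per seed.

**Red cells.** Each segment carries `max(1, Poisson(ρ·L))` particles
(linear density ρ = 0.25/px ≈ single-file capillary hematocrit; the
minimum of one reflects that every capillary of the mesh is perfused),
advected at `1.2 × flow` px/frame with wrap-around, stamped as dark disks
clipped to the lumen. Particle contrast is `15·(3/d)^0.3` intensity units:
decaying with diameter d, so the temporal SD is strongest in the smallest
microvessels (wide vessels additionally saturate — overlapping particles
raise coverage and damp fluctuation), yet gentle enough that the
amplitude×frequency product still grows with flow in wide vessels, as a
perfusion map requires.

**Noise and drift.** Tissue flicker is zero-mean Gaussian (SD 1.5),
uncorrelated in time, restricted to the lumen complement — the minimal
model of the residual tissue brightness changes that alignment cannot
remove, and the cause of the perfusion image's positive values in
avascular areas. Sensor noise (SD 2.0) is added everywhere. Drift is
scripted, not random-walk, so registration recovery can be asserted
exactly; frames are rendered on a padded canvas and windowed, never
wrapped. Frames are quantized to [0, 255].

**What passing does and does not show.** The generator matches the
pipeline's assumptions by construction: rigid drift, static geometry over
one recording, spatially uncorrelated noise, particulate absorbance.
Success on it demonstrates correctness of the computation, not robustness
to real-world effects it does not model — non-rigid tissue motion, focus
drift, illumination gradients, vessel-wall scattering, or temporally
correlated flicker.

## Problem sizes and determinism

Validation runs use 512×512×100-frame videos for end-to-end recovery (five
seeds), 64×64×20 stacks for the registration exactness study (one
noise-free run plus 100 noisy replicates), 200 random masks for the
topology property, and 60-frame noise-free renders for the phase-ordering
metrics; these sizes give stable statistics while keeping the full
validation suite to a couple of minutes on one CPU. The pipeline itself
contains no randomness: identical input and config produce bit-identical
outputs, and all generator randomness flows from explicit seeds.

## Known limitations

* Rotation, scale and non-rigid motion are out of scope; only rigid
  translation is corrected.
* Both image products are relative per recording; values are not
  comparable across videos and are not absolute flow.
* AVI decoding requires an ffmpeg-capable imageio backend at run time;
  multi-page TIFF is the fully supported interchange format.
* Phase presets are discrete snapshots; the package measures descriptors
  but deliberately does not classify ROIs into phases.
* The diameter estimator is biased low by ~0.5 px for vessels whose true
  width is even (no single center pixel), and near junctions it depends on
  the branch-point exclusion radius.
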