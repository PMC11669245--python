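# Methods

`microglia3d` quantifies retinal microglia in 3D from dual-labelled
(IBA-1 / CD68) confocal z-stacks: a random-forest voxel classifier turns the
IBA-1 channel into class probabilities, a watershed chain separates
individual cells, a fixed set of shape descriptors is measured per cell in
3D and on the z-projection, CD68 content is quantified per cell, and group
differences are tested with a normality-gated statistical layer.  Because no
donor imagery ships with the package, a synthetic scene generator with exact
voxel-level ground truth provides the test bed; this note records the models,
conventions and their limits.

## Voxel classification

The classifier is a three-class random forest (microglia / vasculature /
background; 100 trees, unrestricted depth, fixed seed) over a multi-scale
filter bank: raw intensity plus Gaussian smoothing, Laplacian of Gaussian,
Gaussian gradient magnitude, difference of Gaussians, structure-tensor
eigenvalues and Hessian-of-Gaussian eigenvalues, each at scales
{0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10} in voxel units.  Difference of Gaussians
uses consecutive scale pairs; the structure tensor's derivative scale is
fixed at half its integration scale so the channel count never depends on a
second scale list; eigenvalues are sorted descending for rotation
consistency; all filters use reflect boundaries.  Sigmas are interpreted in
index space even though voxels are anisotropic — this mirrors the convention
of the interactive voxel-classification tools this workflow descends from —
and an optional correction that rescales the z-sigma by dx/dz is available
but off by default (it made no measurable difference on synthetic scenes).

Only labelled voxels' features are materialized for training, so sparse
annotations on large stacks never force dense feature storage.  Dense
prediction builds one float32 feature matrix and evaluates the forest in
voxel chunks, which is exactly equivalent to whole-stack evaluation (tested
bit-for-bit).  Training rows are sorted into canonical voxel order, making
the model invariant to annotation order and symmetric under class
relabelling.

On synthetic scenes, annotation is emulated by `annotate_scene`: per class a
few hundred voxels, with background strokes drawn both far from and directly
adjacent to objects and microglia strokes biased toward thin processes, plus
one `refine_annotations` round that adds labels where the live prediction
disagrees with the annotator's view — the synthetic analogue of interactive
active learning.  The adjacency sampling matters: without it the classifier
treats the PSF halo as cell and volumes inflate by ~60%.

## Instance segmentation

The microglia probability map is smoothed (Gaussian, sigma = 1 voxel),
thresholded by Otsu's method on a 256-bin histogram, and voxels whose
vasculature probability reaches 0.5 are removed ("high probability" is not
quantified anywhere authoritative; 0.5 is the package default and is
configurable).  The remaining mask is split by a marker-controlled watershed
over the Sobel gradient magnitude of the binary mask (index-space gradients,
26-connectivity).  Markers are regional maxima of the Euclidean distance
transform after smoothing (sigma = 2 voxels), with two acceptance rules:
maxima closer than 5 um are suppressed, and a marker must lie at least
1.5 um deep (a soma criterion — without it every process blob seeds a basin
and counts over-segment severely).  Components left without a marker are
seeded at their distance maximum so the watershed always partitions the
mask exactly.  A size filter removes labels below 100 um^3 (configurable;
"smaller than typical microglia"), and an optional QC review applies
per-label accept/reject decisions with a persisted log.

## Morphometry conventions

Per cell: volume = voxel count x voxel volume; convex hulls are built on
voxel/pixel **corner** points, so convex digitized solids score solidity
exactly 1 and solidity/convexity are provably <= 1 (the voxel union is a
subset of its corners' hull).  A corner cloud always spans full dimension —
a single voxel contributes a whole cube — so hull degeneracy cannot occur.
One consequence worth knowing: a digitized ball's solidity approaches 1 only
like (r / (r + half a voxel))^3, i.e. ~0.91 at a 16-voxel radius; solidity
values are resolution-dependent for small objects under any corner-based
convention.

2D metrics are measured on the any-hit z-projection: area, perimeter, hull
area/perimeter, solidity (area over hull area), convexity (hull perimeter
over perimeter), circularity (4 pi area / perimeter^2) and the axis lengths
of the moment-equivalent ellipse (exact pixel-union moments, i.e. pixel
centre scatter plus the dx^2/12 square term, so a single pixel degrades to
its unit square with axis ratio 1).  The perimeter estimator is the one
convention this module had to fix by hand: the pixel-corner staircase
boundary is traced (foreground kept on a consistent side; corner-touching
pixels resolved by the tightest turn), simplified by Douglas-Peucker at a
1-pixel tolerance, and floored at the convex-hull perimeter.  This is exact
on axis-aligned rectangles (a 10 x 10 square reports perimeter 40 and
circularity exactly pi/4), within ~2% on large digitized disks, and keeps
circularity and convexity inside (0, 1].  Established estimators fail one or
the other requirement: weighted-chain and Crofton estimators are not exact
on rectangles, and the raw staircase gives a disk circularity of ~0.62.
Holes contribute their boundary to the perimeter; multi-component
projections are measured on the union and flagged.

Count densities are reported in both conventions: cells per lateral field
area (count/mm^2) and cells per stack volume (count/mm^3).

## CD68 colocalization

CD68 is segmented by Otsu thresholding over voxels **inside** segmented
cells (the default scope; a global-Otsu variant exists behind a flag).  Per
cell: CD68 volume, CD68/cell volume ratio, and a CD68+/- flag at a minimum
volume of two voxels, so a single noisy voxel cannot flip a cell's status.
Noiselessly the recovered puncta match ground truth exactly.  At realistic
noise and PSF the Otsu cut sits near a quarter of the blurred punctum peak,
which encloses a PSF shell of roughly 1.3-1.7x the true punctum volume when
the axial PSF sigma (1 um) is comparable to the punctum radius; per-cell
CD68 volumes therefore carry a systematic, bounded blur inflation, while the
CD68+/- classification and the ratio comparisons between groups are robust
to it.  Absolute CD68 volumes should not be compared across instruments or
PSFs without deconvolution.

## Statistics

Every two-sample comparison first runs Shapiro-Wilk on both samples at
alpha = 0.05 (the gating alpha is a package choice; it is configurable).
Both passing selects the classical equal-variance Student's t (Welch behind
a flag); otherwise a two-sided Mann-Whitney U — exact by full enumeration
whenever n*m <= 2000 without ties, otherwise the tie-corrected normal
approximation.  The branch taken is always recorded.  Two-factor designs
(group x CD68 status) use a two-way ANOVA with Type-II sums of squares on
the unbalanced 2x2 design, followed by the four scientifically relevant
pairwise contrasts (between groups within each CD68 status, between
statuses within each group) as pooled-variance t statistics with Bonferroni
multiplication by four, capped at one.  Summaries are mean ± SEM
(sd/sqrt(n), n-1 denominator) with the star convention * <= 0.05 down to
**** <= 1e-4.  The unit of analysis is the caller's explicit declaration:
counts and CD68+ proportions are compared per stack/subject, size and shape
metrics per cell.

Under a two-group null (2000 replicates, mixed normal and lognormal draws,
n = 15 per group) the gated test rejects at alpha = 0.05 in 5 ± 1.5% of
replicates (asserted in the suite).

## Synthetic scenes

The generator emulates the imaging regime the pipeline targets, not any
particular tissue: a 79.9 x 79.9 x 40 um field at 0.312 um lateral pitch
and 1 um z-steps (256 x 256 x 40 voxels; the finer 0.156 um acquisition
pitch is available by passing a custom geometry, at ~5x the compute),
default 30 cells per control field and 21 per AD field (the 0.69 ratio of
the reported group densities), control mean cell volume 1085 um^3 and AD
1754 um^3 with lognormal spread (cv 0.45) rescaled so the sample mean hits
the request exactly, 90% CD68+ cells, two bright vessels that bleed into
the IBA-1 channel, a separable Gaussian PSF of sigma (z, y, x) =
(1.0, 0.3, 0.3) um, Poisson shot noise at 4 photons per intensity unit and
Gaussian read noise of sigma 2 — a clean, line-averaged confocal regime.

A cell is an ellipsoidal soma (radius capped at 7.5 um so the cap does not
bind even in the AD volume tail) plus 2-6 random-walk tube processes
(radius 0.4-1.0 um); an amoeboid score in [0, 1] trades process volume for
soma volume at fixed cell volume.  All linear dimensions of a cell — its
territory radius (18 um at the reference volume of 1085 um^3) and its
maximum process length (35 um at reference) — scale with the cube root of
its volume, so the dimensionless shape metrics are size-invariant and the
two groups differ in volume and count but not in shape, which is exactly
the contrast the statistics layer is meant to detect (a binding cap or a
fixed reach would couple shape to size and fabricate a spurious group
shape difference).  Processes are territorial: beyond ~70% of the
territory radius the walk bends back toward the soma, reflecting the
non-interdigitating arrangement of real microglia — without this,
synthetic processes roam across neighbouring territories and per-cell
segmentation becomes ill-posed in a way real tissue is not.  Cells are
placed by rejection sampling with a
12-um minimum centroid spacing; residual voxel collisions go to the lower
cell index, and vessels only claim voxels no cell holds, so the ground-truth
labels are an exact partition.  CD68+ cells carry 1-8 spherical puncta
(radius 0.5-1.5 um) inside the soma; AD cells carry twice as many (the
direction, not the magnitude, of the reported group difference).  Per-cell
radii are calibrated by fixed-point iteration until the voxelized volume is
within ~2% of its target.

One scale caveat: 30 cells in the 79.9 x 79.9 x 40 um desk field is a
volumetric density an order of magnitude above retinal tissue (the small
field exists to keep single-CPU runs fast while hosting enough cells for
statistics).  Count densities computed on synthetic scenes therefore
characterize the synthetic regime, not tissue; the density *conventions*
(count/mm^2, count/mm^3) and their unit conversions are what the count
module is tested on.

What the generator does *not* emulate: depth-dependent attenuation,
spectral crosstalk, spatially varying PSFs, non-microglial IBA-1+ cells,
DAPI, and real morphological diversity (no branching hierarchies, no
process tapering).  Passing recovery tests therefore demonstrates that the
chain is correct and well-calibrated for tube-and-soma objects under
realistic blur and noise — not that its absolute accuracy transfers to
donor tissue.

## Evaluation scales and known limitations

The recovery suite trains on one scene (one refinement round) and evaluates
six fresh default scenes (~180 cells) in the test suite, four in the
acceptance script; the two-group study in the acceptance script runs three
stacks per group.  These sizes are the package's documented evaluation
scale for a single-CPU desk run.

Measured behaviour at the default conditions:

* detected cell counts are within a few percent of truth (mean absolute
  error well under 10%), and >= 96% of vessel voxels are excluded;
* matched-cell volumes are essentially unbiased in the median (ratio
  ~0.95) but individually spread with an IQR of roughly [0.78, 1.15]: the
  chain estimates unblurred-object voxel volume from a PSF-blurred image
  without deconvolution, so thin (1-2 voxel) processes lose axial extent
  while somas gain a halo shell, and which effect dominates varies per
  cell.  The median absolute relative volume error sits near 20% and
  resisted every design variation tried (denser labels, a second
  refinement round, probability-map elevation for the watershed,
  anisotropy-corrected features and smoothing, finer lateral pitch) — treat
  per-cell absolute volumes as ~20%-accurate at these imaging conditions,
  while group-level volume comparisons remain well-powered;
* CD68 volumes carry the bounded blur inflation described above.

Determinism: scenes are reproducible bit-for-bit from (parameters, seed);
training is deterministic given the seed; two identical pipeline runs
produce byte-identical CSVs (asserted in the suite).
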