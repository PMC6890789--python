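# Methods

This note documents the models and procedures clarimap implements, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic phantoms do and do not demonstrate.

## Coordinate conventions

All in-memory geometry is micrometres.  A `VoxelGrid` maps index `i` to
world position `origin + i·spacing` (voxel centers, 0-based).  NIfTI
headers are millimetres and converted on load/save; TIFF stacks carry no
trustworthy 3D spacing and require it from the caller.  Reorientation
(`orient_to_standard`) is a pure axis permutation plus flips: a flip
reverses the data axis and its anatomical code together, so each voxel
keeps its anatomical location while the index convention changes.
Downsampling is block-mean (anti-aliased) with edge blocks averaging only
the voxels they contain; the output origin shifts to the block centers so
world positions of averaged content are preserved.

## Atlas model

Label volumes carry ontology ids directly (the Allen convention), so no
separate label-to-node map is needed.  `graph_depth` is the distance from
the root; `graph_order` is the depth-first enumeration position, matching
the Allen structure graph.  The ontology JSON loader accepts an alias
table (`parent_structure_id`, `st_level`, …) so real structure-graph
exports load unchanged; where a file carries both `depth` and `st_level`,
`graph_depth` prefers `depth`.  "Grand-parent" grouping of fine labels is
generalized to collapse-to-depth, with an `up_k_levels` convenience mode
(cortical layer → area is k = 2).  Ties in `labels_in_mask` are broken by
ascending id for deterministic output.

## Structure-tensor orientation and tracking

Gradients are derivative-of-Gaussian filtered at σ_dog (µm, converted to
per-axis voxel sigmas, so anisotropic spacing yields anisotropic filter
widths) and divided by the spacing so they are derivatives with respect
to world µm.  The six unique components of ∇I∇Iᵀ are each smoothed at
σ_g.  Defaults σ_dog = 1 µm, σ_g = 2 µm suit tube-like structures of
radius ~3 voxels at unit spacing; both must be rescaled with imaging
resolution and SNR.  The per-voxel orientation is the eigenvector of the
smallest eigenvalue (vectorized `eigh`); voxels whose tensor trace falls
below `coherence_min` × max-trace are flagged invalid.

Tracking is deterministic and seeded at every voxel center of the seed
mask in lexicographic order (capped at `max_streamlines` = 5000, no RNG).
Each seed is tracked both ways along its raw eigenvector and the halves
joined.  Steps are fixed length (default half the smallest voxel size)
with nearest-voxel orientation lookup; the step direction is taken at the
half-step position (midpoint/RK2 rule), sign-aligned to the previous
direction before the angle test.  Plain Euler stepping accumulates an
outward drift of order step²/(2·radius) per step on curved bundles —
about two voxels over a few turns of a radius-20 circle — while the
midpoint rule reduces this to under 0.1 voxel; termination semantics are
unchanged.  A streamline stops when the inter-step turn exceeds
α_thresh = 35°, when it leaves the brain mask or the volume, when it
enters an invalid voxel, or at the length budget.

Terminal maps count both endpoints of every streamline (sum = 2·|S|), so
the injection-side endpoints must be removed before interpreting the map:
the largest 26-connected component of the binarized (> 0, configurable)
terminal map is zeroed, with the safeguard that it must intersect the
seed mask — otherwise the largest seed-intersecting component is removed
instead, with a warning.  Passing-mode region weights are mean tract
density over the region; terminal-mode weights are summed (masked)
endpoint counts; ties rank by ascending region id.

## Segmentation

The chain is per-slice background subtraction, histogram matching of each
slice to slice 0, a percentile stretch saturating 0.35% of voxels, and a
3D median filter (ball radius 2).  Background subtraction uses a
grayscale opening with a disk of the rolling radius (default 50 px) on a
3×3-mean presmoothed copy — the classic rolling-ball behavior including
its presmoothing step; without presmoothing the morphological envelope
sits several noise-SDs below the true background and leaves a pedestal
that defeats the local threshold.  The dense-nuclei variant
(`stain="pi"`) skips the median filter, which at high cell density erases
the intensity minima between touching nuclei.

Phansalkar thresholding uses the standard constants k = 0.25, r = 0.5,
p = 2, q = 10 over a spherical neighborhood (default radius 15 px) with
reflect padding at the volume boundary.  Inputs must be normalized to
[0, 1].

Watershed markers come from regional intensity maxima at the minima
radius (2 px) inside the foreground.  Two cleanups make the marker set
robust on noisy volumes: (1) the foreground mask is binary-opened at the
minima radius, which breaks the thin percolating speckle web a local
threshold leaves in noisy background (26-connected noise percolates at
very low densities, and a basin flooding into that web drags its centroid
far from the cell); (2) when the maxima intensities are bimodal — object
cores versus noise peaks — an Otsu split on the maxima population drops
the noise mode (applied only if the lower mode's mean is below 0.6× the
upper mode's, so clean images are not over-thresholded).  Maxima are then
grouped by dilation at the minima radius so one object yields one marker,
and the watershed (26-connected, on the inverted image, restricted to the
foreground) floods from them.  Foreground unreached by any marker stays
unlabeled.  Objects above `max_object_volume_px` are removed; ids are
relabeled consecutively.

Validation matches object centroids (intensity-weighted when an intensity
volume is given — robust to asymmetric basin growth) to ground-truth
centers greedily, closest pair first, one-to-one, within a radius;
specificity = TP/(TP+FP), detection rate = TP/(TP+FN).

## Voxelized features and group analyses

Centroid-mode voxelization adds 1 to the coarse voxel containing each
object's centroid and conserves the total count exactly; kernel mode
counts distinct object ids intersecting a sphere (default radius 5 µm)
around each coarse voxel center and can count an object in several
voxels, so it is non-conserving and off by default.  Region densities
divide summed counts by the region's physical volume from the label-grid
geometry.  Control normalization divides mean case density by mean
control density per region; the degeneration score is its reciprocal; a
region is flagged when its normalized density falls below the mean minus
two SDs of the evaluated region set.  Incidence maps sum binarized
subject masks; the majority mask keeps voxels strictly above
`threshold_fraction · n`.

Group heat-maps are voxelwise sums of squares (an RMS display mode
exists).  Label-wise hemisphere comparisons use two-sided paired t-tests;
an all-zero difference vector reports t = 0, p = 1 exactly, other
zero-variance cases are flagged degenerate.  No multiple-comparison
correction is applied by default; the p-value map is thresholded at
α = 0.05 for display.  Voxelwise Spearman correlations support an
exclusion mask, per-hemisphere normalization by the contralateral mean,
and optional Gaussian presmoothing (σ = 1 voxel) to absorb registration
error.  Landmark TRE matches landmarks by name and reports per-pair
distances and their RMSE in µm.

## Tract profiles and asymmetry

Streamlines are arc-length resampled to `n_nodes` (default 100) and
sampled by trilinear interpolation (outside samples clamp to the nearest
voxel).  "Adjacent" streamlines are consecutive in seed order — the
tracker seeds deterministically along the mask, so seed order approximates
spatial adjacency — and are averaged in blocks of ten.  Per subject,
asymmetry = mean over nodes of |contra − ipsi| / mean(contra) × 100, with
the contralateral profile sampled from the left-right mirrored volume
using the same streamline geometry; the signed variant
(contra − ipsi)/mean(contra) is also reported.  Groups are compared with
a two-sided two-sample t-test on the per-subject values.

## Part-to-whole section localization

Similarity is the mean squared difference between z-score-normalized
patches (z-scoring absorbs the intensity inhomogeneity of cleared
volumes; a raw-MSD flag disables it).  The search is coarse-to-fine:
round 0 scans the feasible offsets at an increment of section-shape/8 per
axis; each of the remaining rounds (5 total) halves the increment (floor,
min 1) and searches ± the previous increment around the incumbent, which
is always carried forward, making the best similarity non-increasing
across rounds.  Because the normalized MSD at every offset reduces to
sliding-window sums plus one cross-correlation, the full similarity map
is computed once by FFT and the rounds index into it; an increment as
coarse as the section size itself was found to skip the similarity basin
entirely on textured volumes (the basin width is set by the texture
correlation length, not the section size), which motivated the /8
default.  Ties break toward the lexicographically smallest offset.  The
matched segment is expanded 15% per axis (clipped to bounds) to absorb
boundary error before downstream deformable registration, which is out of
scope.

## Synthetic phantoms

All generators are pure functions of a spec plus an integer seed (NumPy
PCG64, pinned).  They emulate geometry and first-order statistics only:

- **Tube phantom**: bright tube (flat core, soft wall: exp(−(d/r)⁴)) on a
  dim background, Gaussian noise at contrast/SNR.  Default 64³, radius 3
  voxels, SNR 8 — tuned to a bundle a few voxels wide at light-sheet
  resolution.  Curved variants arc in-plane.
- **Blob phantom**: Gaussian blobs (radius 2–3 voxels) at dart-throwing
  centers with a 7-voxel minimum separation, a linear illumination
  gradient (20% of amplitude), and noise at SNR 8.  Default 200 blobs in
  96×96×48 — a dense nuclear field.
- **Toy atlas**: a depth-6 nested rectangular hierarchy with left/right
  hemispheres at depth 1 and a seeded random projection table in the
  normalized-projection-volume schema.
- **Asymmetric pair**: a mirror-symmetric smooth field whose right
  hemisphere is multiplied by (1 − fraction) inside a planted ellipsoid,
  plus the exact left-right flip.

What passing tests on these phantoms do **not** show: robustness to
light-sheet stripe artifacts, depth-dependent attenuation, deconvolution
residuals, anisotropic PSFs, registration error between modalities, or
biological shape variability.  The phantoms establish correctness of the
computations under controlled conditions, not performance on real tissue.

## Problem sizes used by the reproduction script

The acceptance script exercises the pipeline at desk scale: a 64³ tube
phantom, a 200-blob 96×96×48 nuclei field, 100 random voxelization
phantoms, 50 random connectivity tables on the depth-6 toy atlas, 20
planted crops in a 100³ textured volume, 10⁴ voxels for the rank
correlation, and 200 Monte-Carlo repeats of the 27%-vs-12% asymmetry
contrast at n = 9 per group with 5% subject SD.
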