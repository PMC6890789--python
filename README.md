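# clarimap

Cleared-brain microscopy to atlas integration: structure-tensor fiber
tractography with terminal-zone mapping, 3D nuclei segmentation with
voxelized feature extraction, hierarchical atlas connectivity analysis,
part-to-whole section localization, and group- and tract-level statistics.

## Who this is for

Labs that image intact cleared mouse brains (CLARITY, iDISCO, CUBIC) with
light-sheet or confocal microscopy and want to analyze those volumes in a
common atlas frame: count and localize cells per atlas region, reconstruct
virally labeled fiber bundles and their termination zones, interrogate
which atlas-connectivity targets of a lesion show cellular change, and
compare histological features along fiber tracts between cohorts.  The
deformable registration itself (e.g. ANTs) and diffusion-MRI model fitting
(e.g. MRtrix3) are external; this package consumes their outputs (NIfTI
volumes, TCK streamlines) and implements everything downstream.

## The core methods

**Structure-tensor analysis (STA).**  Per voxel, the structure tensor is

    S_w(p) = G_σg * ( ∇I(p) ∇I(p)ᵀ ),

with image gradients ∇I computed by derivative-of-Gaussian filters at
scale σ_dog and the outer-product components smoothed with a Gaussian of
scale σ_g.  Along a bright fiber the intensity varies across the wall but
not along the axis, so the **tertiary eigenvector** (smallest eigenvalue)
of S_w points along the fiber.  Deterministic streamlines in the FACT
family are propagated bidirectionally through this axial orientation
field and terminate on a sharp turn (> α_thresh = 35°), on leaving the
brain mask, or on entering a voxel with no valid orientation.  In
unstained tissue the orientation decorrelates voxel to voxel, so the
angular threshold alone stops tracks there — the analog of an FA
threshold in diffusion tractography.  Counting streamline endpoints per
voxel (terminal map) and removing the endpoint cluster at the injection
site separates fibers that *terminate* in a region from fibers that
merely *pass through* — the key distinction for connectivity strength.

**Segmentation.**  Per-slice rolling-ball background subtraction,
histogram matching to the first slice, percentile contrast stretch, 3D
median filter, Phansalkar local threshold
(t = m·(1 + p·e^(−q·m) + k·(s/r − 1)) over a spherical neighborhood), and a
marker-controlled 3D watershed.  Detected objects are validated against
ground-truth centers with specificity = TP/(TP+FP) and detection rate =
TP/(TP+FN).

**Connectivity.**  A projection table (one row per experiment-target, with
normalized projection volume = projection volume / injection volume) is
queried per lesion region; regions without their own injection experiment
fall back to the nearest experiment-bearing ancestor in the atlas
ontology.  Targets are filtered to mid-ontology structures (graph depth
≥ 5 and graph order ≥ 6), stripped of the injection site's descendants,
and ranked by strength.  Per-region cell densities normalized by control
animals flag degeneration below mean − 2·SD.

**Tract profiles.**  Intensity is sampled at N nodes along arc-length
resampled streamlines, averaged over bundles of ten adjacent streamlines,
and hemisphere asymmetry (mean |contra − ipsi| / mean contra, in percent,
using a left-right mirrored volume for the contralateral side) is compared
between groups with a two-sample t-test.

## Worked example

Every input can be simulated with known ground truth:

```python
import numpy as np
from clarimap import synth, sta

grid, centerlines, in_tube = synth.make_tube_phantom(
    synth.TubeSpec(shape=(64, 64, 64), radius_vox=3.0, snr=8.0, seed=1))

params = sta.STAParams(sigma_dog_um=1.0, sigma_g_um=2.0)
field = sta.orientation_field(sta.structure_tensor_field(grid, params))

axis = np.array([0.0, 0.0, 1.0])
cos = np.abs(field.vectors[in_tube] @ axis)
print(f"{100 * np.mean(cos >= np.cos(np.deg2rad(10))):.1f}% of in-tube "
      "voxels within 10 degrees of the true axis")
```

prints

```
100.0% of in-tube voxels within 10 degrees of the true axis
```

meaning that on a tube phantom at signal-to-noise 8 the estimated fiber
orientation at every voxel inside the tube lies within 10° of the planted
tube axis — the accuracy that makes the downstream streamline tracking
and terminal mapping reliable.

The same facilities are scriptable from a shell:

```
clarimap simulate tube --out tube.nii.gz --seed 1
clarimap sta track tube.nii.gz tube.tck --seed seedmask.nii.gz --alpha 35
clarimap sta maps tube.tck tube.nii.gz --mask-seed seedmask.nii.gz
clarimap find-section --whole whole.nii.gz --section cut.nii.gz
```

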