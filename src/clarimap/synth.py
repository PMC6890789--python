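"""Deterministic synthetic phantoms with ground truth.

Every generator is a pure function of its parameters plus an integer seed
(NumPy PCG64 is pinned project-wide), and returns the ground truth needed
by validation code alongside the data itself: tube phantoms return their
centerlines, blob phantoms their planted centers, the toy atlas its full
ontology and projection table.

The phantoms emulate the geometry the real pipeline sees — tubular
fluorescent fiber bundles, dense nuclei fields over an uneven background,
a nested left/right region hierarchy — without attempting realistic
light-sheet optics (no stripes or depth attenuation).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelVolume, OntologyNode, OntologyTree
from .volio import VoxelGrid

__all__ = [
    "TubeSpec",
    "BlobSpec",
    "AtlasSpec",
    "AsymmetrySpec",
    "make_tube_phantom",
    "make_blob_phantom",
    "make_toy_atlas",
    "make_asymmetric_pair",
]


@dataclasses.dataclass
class TubeSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    radius_vox: float = 3.0
    contrast: float = 1.0
    background: float = 0.1
    snr: float = 8.0
    seed: int = 0
    curved: bool = False
    #: radians turned over the full tube length when curved
    total_turn_rad: float = 0.6


@dataclasses.dataclass
class BlobSpec:
    shape: tuple[int, int, int] = (96, 96, 48)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_blobs: int = 200
    radius_vox: tuple[float, float] = (2.0, 3.0)
    min_separation_vox: float = 7.0
    amplitude: float = 1.0
    snr: float = 8.0
    gradient: float = 0.2
    seed: int = 0


@dataclasses.dataclass
class AtlasSpec:
    shape: tuple[int, int, int] = (32, 32, 16)
    spacing_um: tuple[float, float, float] = (25.0, 25.0, 25.0)
    depth: int = 6
    n_experiments: int = 12
    targets_per_experiment: int = 6
    seed: int = 0


@dataclasses.dataclass
class AsymmetrySpec:
    shape: tuple[int, int, int] = (48, 48, 24)
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    fraction: float = 0.2
    noise_sd: float = 0.0
    seed: int = 0


def _polyline_points(spec: TubeSpec) -> np.ndarray:
    """Centerline as voxel-index coordinates running along z."""
    nz = spec.shape[2]
    z = np.arange(nz, dtype=float)
    cx = (spec.shape[0] - 1) / 2.0
    cy = (spec.shape[1] - 1) / 2.0
    if spec.curved:
        # gentle in-plane arc: heading rotates by total_turn_rad over the run
        theta = spec.total_turn_rad * (z / max(nz - 1, 1) - 0.5)
        amp = 0.25 * min(spec.shape[0], spec.shape[1])
        x = cx + amp * np.sin(theta)
        y = np.full_like(z, cy)
    else:
        x = np.full_like(z, cx)
        y = np.full_like(z, cy)
    return np.stack([x, y, z], axis=1)


def make_tube_phantom(spec: TubeSpec) -> tuple[VoxelGrid, list[np.ndarray], np.ndarray]:
    """Bright tube on a dim background plus Gaussian noise.

    Returns ``(grid, centerlines_world_um, in_tube_mask)``.  The tube runs
    along z (optionally arcing in the x–z plane); intensity has a smooth
    radial falloff so the wall carries usable gradients.
    """
    if spec.radius_vox < 1:
        raise ValueError("tube radius must be >= 1 voxel")
    centerline = _polyline_points(spec)
    if np.any(centerline.min(axis=0) < 0) or np.any(
        centerline.max(axis=0) > np.asarray(spec.shape) - 1
    ):
        warnings.warn("tube centerline leaves the volume; clipping", stacklevel=2)
        centerline = np.clip(centerline, 0, np.asarray(spec.shape, dtype=float) - 1)

    # distance of every voxel to the centerline via EDT of rasterized line
    line = np.zeros(spec.shape, dtype=bool)
    idx = np.round(centerline).astype(int)
    line[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    dist = ndimage.distance_transform_edt(~line, sampling=(1, 1, 1))

    profile = np.exp(-((dist / spec.radius_vox) ** 4))  # flat core, soft wall
    img = spec.background + spec.contrast * profile
    rng = np.random.default_rng(spec.seed)
    noise_sd = spec.contrast / spec.snr if spec.snr > 0 else 0.0
    img = img + rng.normal(0.0, noise_sd, size=spec.shape)

    grid = VoxelGrid(img, spec.spacing_um, (0.0, 0.0, 0.0))
    world = grid.index_to_world(centerline)
    in_tube = dist <= spec.radius_vox
    return grid, [world], in_tube


def _poisson_disc(rng: np.random.Generator, shape, n: int, min_sep: float, margin: float) -> np.ndarray:
    """Dart-throwing with a minimum pairwise separation."""
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=float) - 1 - margin
    center = (np.asarray(shape, dtype=float) - 1) / 2
    lo = np.minimum(lo, center)
    hi = np.maximum(hi, center)  # degenerate axis: sample at the center
    pts: list[np.ndarray] = []
    attempts = 0
    max_attempts = 200 * n
    while len(pts) < n and attempts < max_attempts:
        cand = rng.uniform(lo, hi)
        attempts += 1
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    if len(pts) < n:
        warnings.warn(
            f"could only place {len(pts)} of {n} blobs at separation {min_sep}",
            stacklevel=2,
        )
    return np.asarray(pts)


def make_blob_phantom(spec: BlobSpec) -> tuple[VoxelGrid, np.ndarray]:
    """Gaussian blobs at minimum-separation random centers.

    Returns ``(grid, centers_world_um)``.  Optional linear background
    gradient along x emulates illumination falloff; noise SD is
    ``amplitude / snr``.
    """
    if spec.n_blobs < 1:
        raise ValueError("need at least one blob")
    rng = np.random.default_rng(spec.seed)
    margin = max(spec.radius_vox) * 2
    centers = _poisson_disc(rng, spec.shape, spec.n_blobs, spec.min_separation_vox, margin)
    radii = rng.uniform(spec.radius_vox[0], spec.radius_vox[1], size=len(centers))

    img = np.zeros(spec.shape)
    grids = np.indices(spec.shape).astype(float)
    for c, r in zip(centers, radii):
        # only paint inside a local box for speed
        lo = np.maximum(np.floor(c - 4 * r).astype(int), 0)
        hi = np.minimum(np.ceil(c + 4 * r).astype(int) + 1, spec.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        d2 = sum((grids[ax][sl] - c[ax]) ** 2 for ax in range(3))
        img[sl] += spec.amplitude * np.exp(-d2 / (2 * r**2))

    if spec.gradient:
        ramp = np.linspace(0.0, spec.gradient * spec.amplitude, spec.shape[0])
        img = img + ramp[:, None, None]
    if spec.snr > 0:
        img = img + rng.normal(0.0, spec.amplitude / spec.snr, size=spec.shape)

    grid = VoxelGrid(img, spec.spacing_um, (0.0, 0.0, 0.0))
    return grid, grid.index_to_world(centers)


def _subdivide(box, axis):
    lo, hi = box
    mid = (lo[axis] + hi[axis]) // 2
    a_hi, b_lo = list(hi), list(lo)
    a_hi[axis] = mid
    b_lo[axis] = mid
    return (lo, tuple(a_hi)), (tuple(b_lo), hi)


def make_toy_atlas(spec: AtlasSpec) -> tuple[LabelVolume, OntologyTree, pd.DataFrame]:
    """Nested rectangular hierarchy with left/right hemispheres.

    Depth 0 is the root (whole volume); depth 1 splits left/right along x;
    deeper levels bisect alternating axes.  Leaf regions paint the label
    volume.  ``graph_order`` is the depth-first enumeration position, the
    Allen structure-graph convention.  A synthetic projection table draws
    injection experiments at mid-depth nodes with seeded random normalized
    projection volumes.
    """
    if spec.depth < 6:
        raise ValueError("toy atlas requires depth >= 6 so depth/order filters bite")
    n_leaf_per_axis = 2 ** ((spec.depth + 2) // 3)
    if min(spec.shape) < 2 ** max(1, spec.depth // 3):
        raise ValueError(f"shape {spec.shape} too small for depth {spec.depth}")

    rng = np.random.default_rng(spec.seed)
    nodes: list[OntologyNode] = []
    label = np.zeros(spec.shape, dtype=np.int32)
    order_counter = 0
    next_id = 1

    def add_node(acronym, name, parent_id, depth):
        nonlocal order_counter, next_id
        node = OntologyNode(
            id=next_id, acronym=acronym, name=name, parent_id=parent_id,
            graph_depth=depth, graph_order=order_counter,
        )
        nodes.append(node)
        order_counter += 1
        next_id += 1
        return node

    root = add_node("root", "root", None, 0)
    full_box = ((0, 0, 0), spec.shape)

    def build(parent, box, depth, tag):
        if depth == spec.depth:
            lo, hi = box
            label[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = parent.id
            return
        axis = 0 if depth == 0 else depth % 3
        (box_a, box_b) = _subdivide(box, axis)
        suffix = ("L", "R") if depth == 0 else ("a", "b")
        for sub_box, s in zip((box_a, box_b), suffix):
            child = add_node(f"{tag}{s}", f"region {tag}{s}", parent.id, depth + 1)
            build(child, sub_box, depth + 1, f"{tag}{s}")

    build(root, full_box, 0, "")
    tree = OntologyTree(nodes)
    grid = VoxelGrid(label, spec.spacing_um, (0.0, 0.0, 0.0))
    labels = LabelVolume(grid, tree)

    # synthetic projection table: injections at depth >= 3 nodes, targets at
    # deep nodes, weights seeded; normalized = projection / injection volume
    candidates = sorted(
        (n.id for n in nodes if n.graph_depth >= 3), key=lambda i: tree[i].graph_order
    )
    inj_ids = rng.choice(candidates, size=min(spec.n_experiments, len(candidates)), replace=False)
    deep = [n.id for n in nodes if n.graph_depth >= 5]
    rows = []
    for k, inj in enumerate(sorted(int(i) for i in inj_ids)):
        inj_vol = float(rng.uniform(0.05, 0.2))
        n_t = min(spec.targets_per_experiment, len(deep))
        targets = rng.choice(deep, size=n_t, replace=False)
        for t in sorted(int(t) for t in targets):
            proj = float(rng.uniform(0.001, 0.1))
            rows.append(
                {
                    "experiment_id": 1000 + k,
                    "injection_structure_id": inj,
                    "injection_volume_mm3": inj_vol,
                    "target_structure_id": t,
                    "hemisphere": "ipsi",
                    "projection_volume": proj,
                    "normalized_projection_volume": proj / inj_vol,
                    "strain": "C57BL/6J",
                }
            )
    table = pd.DataFrame(rows)
    return labels, tree, table


def make_asymmetric_pair(spec: AsymmetrySpec) -> tuple[VoxelGrid, VoxelGrid, np.ndarray]:
    """Left–right symmetric base volume with a planted right-side deficit.

    The right hemisphere (upper half of the x axis) is multiplied by
    ``1 - fraction`` inside a planted ellipsoidal mask.  Returns
    ``(volume, mirrored_twin, planted_mask)`` where the twin is the exact
    left–right flip of the volume.
    """
    if not 0 <= spec.fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(spec.seed)
    half = spec.shape[0] // 2
    base_half = ndimage.gaussian_filter(
        rng.uniform(0.5, 1.5, size=(half,) + spec.shape[1:]), sigma=2.0
    )
    base = np.concatenate([base_half, base_half[::-1]], axis=0)

    # ellipsoidal deficit mask centered in the right hemisphere
    cx = spec.shape[0] * 3 // 4
    cy, cz = spec.shape[1] // 2, spec.shape[2] // 2
    semi = (spec.shape[0] // 6, spec.shape[1] // 3, spec.shape[2] // 3)
    ii, jj, kk = np.indices(spec.shape)
    mask = (
        ((ii - cx) / semi[0]) ** 2 + ((jj - cy) / semi[1]) ** 2 + ((kk - cz) / semi[2]) ** 2
    ) <= 1.0

    vol = base.copy()
    vol[mask] *= 1.0 - spec.fraction
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    mirrored = vol[::-1].copy()
    grid = VoxelGrid(vol, spec.spacing_um, (0.0, 0.0, 0.0))
    twin = VoxelGrid(mirrored, spec.spacing_um, (0.0, 0.0, 0.0))
    return grid, twin, mask


def save_atlas_fixture(out_dir: str | Path, spec: AtlasSpec) -> None:
    """Write the toy atlas (NIfTI labels + ontology JSON + projection CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels, tree, table = make_toy_atlas(spec)
    from .volio import write_volume

    write_volume(labels.grid, out / "labels.nii.gz")
    tree.save(out / "ontology.json")
    table.to_csv(out / "projection.csv", index=False)
    (out / "spec.json").write_text(json.dumps(dataclasses.asdict(spec)))
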