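"""Atlas-resolution feature maps from full-resolution segmentations.

Segmented cells live on a µm-scale grid; group analyses happen on the
coarse atlas grid (typically 25 µm).  ``voxelize_counts`` bridges the two:
centroid mode drops each object into the coarse voxel containing its
centroid (exactly conserving the total count), kernel mode counts the
distinct objects intersecting a sphere around each coarse voxel center
(non-conserving — an object can straddle several spheres — but closer to a
convolution-with-spherical-kernel reading of the protocol).

Per-region tables, control-normalized degeneration flagging, and
lesion-incidence maps round out the group-analysis toolkit.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import LabelVolume
from .segmentation import object_centroids
from .volio import VoxelGrid

__all__ = [
    "voxelize_counts",
    "region_features",
    "normalize_and_flag",
    "incidence_map",
]


def voxelize_counts(
    seg: VoxelGrid,
    target: VoxelGrid,
    mode: str = "centroid",
    kernel_radius_um: float = 5.0,
) -> VoxelGrid:
    """Object counts of a fine segmentation on a coarse target grid."""
    if mode not in {"centroid", "kernel"}:
        raise ValueError(f"mode must be 'centroid' or 'kernel', got {mode!r}")
    if np.any(target.spacing_um < seg.spacing_um - 1e-9):
        raise ValueError("target grid must be at least as coarse as the segmentation")
    counts = np.zeros(target.shape, dtype=np.int32)

    if mode == "centroid":
        cents = object_centroids(seg)
        if len(cents) == 0:
            return target.like(counts)
        idx = np.round(target.world_to_index(cents)).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(target.shape)), axis=1)
        if not inside.all():
            warnings.warn(
                f"{int((~inside).sum())} object centroids fall outside the target grid",
                stacklevel=2,
            )
        for i, j, k in idx[inside]:
            counts[i, j, k] += 1
        return target.like(counts)

    # kernel mode: distinct ids within a sphere around each coarse center
    fg = np.argwhere(seg.data > 0)
    if len(fg) == 0:
        return target.like(counts)
    ids = seg.data[fg[:, 0], fg[:, 1], fg[:, 2]]
    world = seg.index_to_world(fg)
    frac = target.world_to_index(world)
    # a fine voxel at distance <= r from a coarse center contributes its id;
    # enumerate candidate coarse voxels within the radius in index units
    reach = np.ceil(kernel_radius_um / target.spacing_um).astype(int)
    sets: dict[tuple[int, int, int], set[int]] = {}
    base = np.round(frac).astype(int)
    offsets = np.array(
        [
            (di, dj, dk)
            for di in range(-reach[0], reach[0] + 1)
            for dj in range(-reach[1], reach[1] + 1)
            for dk in range(-reach[2], reach[2] + 1)
        ]
    )
    for off in offsets:
        cand = base + off
        centers = target.index_to_world(cand)
        dist = np.linalg.norm(centers - world, axis=1)
        ok = (
            (dist <= kernel_radius_um)
            & np.all(cand >= 0, axis=1)
            & np.all(cand < np.asarray(target.shape), axis=1)
        )
        for (i, j, k), oid in zip(cand[ok], ids[ok]):
            sets.setdefault((int(i), int(j), int(k)), set()).add(int(oid))
    for (i, j, k), id_set in sets.items():
        counts[i, j, k] = len(id_set)
    return target.like(counts)


def region_features(
    voxelized: VoxelGrid,
    labels: LabelVolume,
    intensity: VoxelGrid | None = None,
) -> pd.DataFrame:
    """Per-region object count, density (per mm³) and mean intensity.

    Density divides the summed voxelized count by the region's physical
    volume computed from the label-volume geometry.
    """
    if not labels.grid.same_geometry(voxelized):
        raise ValueError("voxelized map and label volume geometries differ")
    if intensity is not None and not labels.grid.same_geometry(intensity):
        raise ValueError("intensity map and label volume geometries differ")
    voxel_mm3 = float(np.prod(labels.grid.spacing_um / 1000.0))
    rows = []
    for rid in labels.region_ids():
        sel = labels.data == rid
        nvox = int(sel.sum())
        if nvox == 0:
            warnings.warn(f"region {rid} has zero volume; skipped", stacklevel=2)
            continue
        count = float(voxelized.data[sel].sum())
        vol = nvox * voxel_mm3
        row = {
            "region_id": rid,
            "acronym": labels.ontology[rid].acronym,
            "object_count": count,
            "volume_mm3": vol,
            "density_per_mm3": count / vol,
        }
        if intensity is not None:
            row["mean_intensity"] = float(intensity.data[sel].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def normalize_and_flag(
    case_tables: list[pd.DataFrame],
    control_tables: list[pd.DataFrame],
    value_col: str = "density_per_mm3",
) -> pd.DataFrame:
    """Control-normalized density with a 2-SD degeneration flag.

    Per region: normalized = mean case density / mean control density;
    degeneration = its reciprocal (so larger = more cell loss); flagged
    where normalized < mean(normalized) − 2·SD over the evaluated regions.
    Regions whose control mean is zero are excluded with a warning.
    """
    if not control_tables:
        raise ValueError("need at least one control table")
    if not case_tables:
        raise ValueError("need at least one case table")

    def mean_by_region(tables: list[pd.DataFrame]) -> pd.Series:
        stacked = pd.concat(tables, ignore_index=True)
        return stacked.groupby("region_id")[value_col].mean()

    case = mean_by_region(case_tables)
    control = mean_by_region(control_tables)
    common = case.index.intersection(control.index)
    case, control = case.loc[common], control.loc[common]
    zero = control == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} regions have zero control density; excluded", stacklevel=2
        )
        case, control = case[~zero], control[~zero]

    normalized = case / control
    mu = float(normalized.mean())
    sd = float(normalized.std(ddof=1)) if len(normalized) > 1 else 0.0
    with np.errstate(divide="ignore"):
        degeneration = 1.0 / normalized
    out = pd.DataFrame(
        {
            "region_id": normalized.index,
            "normalized_density": normalized.values,
            "degeneration": degeneration.values,
            "flagged": (normalized < mu - 2 * sd).values,
        }
    )
    return out.reset_index(drop=True)


def incidence_map(
    masks: list[VoxelGrid], threshold_fraction: float = 0.5
) -> tuple[VoxelGrid, VoxelGrid]:
    """Voxelwise lesion incidence across subjects and its majority mask.

    Returns ``(incidence, mask)`` where incidence counts how many input
    masks cover each voxel and mask selects voxels with incidence strictly
    above ``threshold_fraction * n_subjects``.
    """
    if not masks:
        raise ValueError("need at least one mask")
    first = masks[0]
    total = np.zeros(first.shape, dtype=np.int32)
    for m in masks:
        if not first.same_geometry(m):
            raise ValueError("all masks must share geometry")
        total += m.data.astype(bool).astype(np.int32)
    thresh = threshold_fraction * len(masks)
    return first.like(total), first.like(total > thresh)
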