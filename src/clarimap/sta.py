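"""Structure-tensor orientation estimation and deterministic tractography.

Fluorescently labeled axon bundles appear as bright tubular textures.  The
local fiber orientation at a voxel is recovered from the structure tensor

    S_w(p) = G_{sigma_g} * S_0(p),     S_0(p) = grad I(p) grad I(p)^T

where the image gradients are computed by derivative-of-Gaussian filtering
at scale ``sigma_dog`` and the outer-product components are smoothed with a
Gaussian of scale ``sigma_g``.  Along a tube the intensity varies across
the wall but not along the axis, so the *tertiary* eigenvector (smallest
eigenvalue) of S_w points along the fiber.

Streamlines are propagated through this axial orientation field with a
deterministic fixed-step scheme in the spirit of FACT (fiber assignment by
continuous tracking): at each step the orientation of the containing voxel
is sign-aligned to the previous direction, and the track stops on a sharp
turn (> ``alpha_thresh_deg``), on leaving the brain mask, or on entering a
voxel with no valid orientation.  In unlabeled tissue the tensor is noise
and the orientation decorrelates voxel to voxel, so the angular threshold
by itself terminates tracks there — it plays the role an FA threshold plays
in diffusion tractography.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

from .atlas import LabelVolume
from .volio import VoxelGrid

__all__ = [
    "STAParams",
    "TensorField",
    "OrientationField",
    "StreamlineSet",
    "structure_tensor_field",
    "orientation_field",
    "fact_track",
    "density_and_terminal_maps",
    "mask_injection_component",
    "filter_streamlines",
    "region_connectivity",
    "write_tck",
    "read_tck",
]


@dataclasses.dataclass
class STAParams:
    """Scales, stopping criteria and budgets for STA tracking.

    sigma_dog_um
        Derivative-of-Gaussian scale for the image gradients, µm.
    sigma_g_um
        Gaussian window for tensor smoothing, µm; sets the neighborhood
        over which gradient evidence is pooled.
    alpha_thresh_deg
        Maximum inter-step turning angle before a streamline terminates.
    step_um
        Propagation step; when None, half the smallest voxel size.
    """

    sigma_dog_um: float = 1.0
    sigma_g_um: float = 2.0
    alpha_thresh_deg: float = 35.0
    step_um: float | None = None
    max_streamlines: int = 5000
    max_length_um: float = 1e5

    def __post_init__(self) -> None:
        if self.sigma_dog_um <= 0 or self.sigma_g_um <= 0:
            raise ValueError("sigma scales must be positive")
        if not 0 < self.alpha_thresh_deg < 90:
            raise ValueError("alpha_thresh_deg must be in (0, 90)")


@dataclasses.dataclass
class TensorField:
    """Per-voxel symmetric 3x3 structure tensor, shape (X, Y, Z, 3, 3)."""

    tensors: np.ndarray
    spacing_um: np.ndarray
    origin_um: np.ndarray


@dataclasses.dataclass
class OrientationField:
    """Per-voxel unit axial vector (sign-free) with a validity mask."""

    vectors: np.ndarray  # (X, Y, Z, 3), unit norm where valid
    valid: np.ndarray  # (X, Y, Z) bool
    spacing_um: np.ndarray
    origin_um: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.valid.shape


@dataclasses.dataclass
class StreamlineSet:
    """Ordered 3D polylines in world µm with their seed indices."""

    lines: list[np.ndarray]
    seed_indices: list[int]

    def __len__(self) -> int:
        return len(self.lines)


def structure_tensor_field(img: VoxelGrid, params: STAParams) -> TensorField:
    """Smoothed gradient outer-product tensor at every voxel.

    Sigmas are given in µm and converted to voxels per axis, so anisotropic
    spacing is handled by anisotropic filter widths.
    """
    if img.data.ndim != 3:
        raise ValueError("structure tensor requires a 3D volume")
    data = img.data.astype(float)
    sig_dog = params.sigma_dog_um / img.spacing_um
    sig_g = params.sigma_g_um / img.spacing_um

    grads = []
    for ax in range(3):
        order = [0, 0, 0]
        order[ax] = 1
        # derivative w.r.t. world µm, not voxel index
        g = ndimage.gaussian_filter(data, sigma=sig_dog, order=order) / img.spacing_um[ax]
        grads.append(g)

    tensors = np.empty(data.shape + (3, 3))
    for i in range(3):
        for j in range(i, 3):
            comp = ndimage.gaussian_filter(grads[i] * grads[j], sigma=sig_g)
            tensors[..., i, j] = comp
            tensors[..., j, i] = comp
    return TensorField(tensors, img.spacing_um.copy(), img.origin_um.copy())


def orientation_field(T: TensorField, coherence_min: float = 0.0) -> OrientationField:
    """Tertiary (smallest-eigenvalue) eigenvector of the structure tensor.

    Voxels whose tensor trace falls below ``coherence_min`` times the
    maximum trace are flagged invalid (background / no gradient evidence).
    """
    w, v = np.linalg.eigh(T.tensors)  # ascending eigenvalues
    vectors = v[..., :, 0]
    trace = np.trace(T.tensors, axis1=-2, axis2=-1)
    max_trace = float(trace.max()) if trace.size else 0.0
    valid = trace > coherence_min * max_trace if max_trace > 0 else np.zeros_like(trace, bool)
    norms = np.linalg.norm(vectors, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        vectors = np.where(norms > 0, vectors / norms, 0.0)
    return OrientationField(vectors, valid, T.spacing_um.copy(), T.origin_um.copy())


def _containing_voxel(pos: np.ndarray, F: OrientationField) -> tuple[int, int, int] | None:
    idx = np.round((pos - F.origin_um) / F.spacing_um).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.asarray(F.shape)):
        return None
    return tuple(idx)


def _track_one_direction(
    start: np.ndarray,
    first_dir: np.ndarray,
    F: OrientationField,
    brain: np.ndarray | None,
    step: float,
    cos_thresh: float,
    max_steps: int,
) -> list[np.ndarray]:
    """Walk from ``start`` along the field; returns points after the seed.

    Midpoint (RK2) stepping: the step direction is the field orientation at
    the half-step position, sign-aligned to the previous direction.  This
    keeps the per-voxel nearest-neighbor lookup but removes the outward
    drift a plain Euler step accumulates on curved bundles.
    """

    def aligned_dir(at: np.ndarray, ref: np.ndarray) -> np.ndarray | None:
        vox = _containing_voxel(at, F)
        if vox is None or not F.valid[vox]:
            return None
        if brain is not None and not brain[vox]:
            return None
        d = F.vectors[vox]
        return -d if np.dot(d, ref) < 0 else d  # axial symmetry

    points: list[np.ndarray] = []
    pos = start.copy()
    prev_dir = first_dir / np.linalg.norm(first_dir)
    for _ in range(max_steps):
        d_half = aligned_dir(pos + prev_dir * (step / 2.0), prev_dir)
        d = d_half if d_half is not None else prev_dir
        nxt = pos + d * step
        vox = _containing_voxel(nxt, F)
        if vox is None:
            break
        if brain is not None and not brain[vox]:
            break
        if not F.valid[vox]:
            break
        d_new = F.vectors[vox]
        if np.dot(d_new, prev_dir) < 0:
            d_new = -d_new
        if np.dot(d_new, prev_dir) < cos_thresh:
            break  # sharp turn
        pos = nxt
        points.append(pos.copy())
        prev_dir = d_new
    return points


def fact_track(
    F: OrientationField,
    seed_mask: VoxelGrid,
    brain_mask: VoxelGrid | None,
    params: STAParams,
) -> StreamlineSet:
    """Deterministic bidirectional streamline tracking through the field.

    Seeds are the voxel centers of ``seed_mask`` in lexicographic order,
    truncated at ``max_streamlines``.  Each seed is tracked both ways along
    its raw eigenvector; the two half-tracks are joined.  Termination:
    inter-step turn above the angular threshold, leaving the brain mask,
    entering an invalid voxel, or exceeding the length budget.
    """
    seeds = np.argwhere(seed_mask.data.astype(bool))
    if seeds.size == 0:
        raise ValueError("seed mask is empty")
    if not F.valid.any():
        raise ValueError("orientation field has no valid voxels")
    if tuple(F.shape) != tuple(seed_mask.shape):
        raise ValueError("orientation field and seed mask shapes differ")
    brain = brain_mask.data.astype(bool) if brain_mask is not None else None

    step = params.step_um if params.step_um is not None else float(F.spacing_um.min()) / 2.0
    cos_thresh = float(np.cos(np.deg2rad(params.alpha_thresh_deg)))
    max_steps = int(params.max_length_um / step)

    lines: list[np.ndarray] = []
    seed_idx: list[int] = []
    for si, vox in enumerate(seeds[: params.max_streamlines]):
        vox = tuple(int(v) for v in vox)
        if not F.valid[vox]:
            continue
        if brain is not None and not brain[vox]:
            continue
        start = F.origin_um + np.asarray(vox) * F.spacing_um
        d0 = F.vectors[vox]
        fwd = _track_one_direction(start, d0, F, brain, step, cos_thresh, max_steps)
        bwd = _track_one_direction(start, -d0, F, brain, step, cos_thresh, max_steps)
        pts = bwd[::-1] + [start] + fwd
        if len(pts) >= 2:
            lines.append(np.asarray(pts))
            seed_idx.append(si)
    return StreamlineSet(lines, seed_idx)


def _visited_voxels(line: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    idx = np.round(grid.world_to_index(line)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
    return idx[inside]


def density_and_terminal_maps(
    S: StreamlineSet, grid: VoxelGrid
) -> tuple[VoxelGrid, VoxelGrid]:
    """Tract-density image and streamline-endpoint (terminal) map.

    The TDI counts each streamline once per voxel it visits; the terminal
    map counts endpoints, two per streamline, so its sum is 2·|S| when all
    endpoints fall inside the grid.
    """
    tdi = np.zeros(grid.shape, dtype=np.int32)
    term = np.zeros(grid.shape, dtype=np.int32)
    clipped = 0
    for line in S.lines:
        vox = _visited_voxels(line, grid)
        if len(vox) < len(line):
            clipped += len(line) - len(vox)
        if len(vox):
            uniq = np.unique(vox, axis=0)
            tdi[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
        for endpoint in (line[0], line[-1]):
            idx = np.round(grid.world_to_index(endpoint)[0]).astype(int)
            if np.all(idx >= 0) and np.all(idx < np.asarray(grid.shape)):
                term[tuple(idx)] += 1
            else:
                clipped += 1
    if clipped:
        warnings.warn(f"{clipped} streamline points fell outside the grid", stacklevel=2)
    return grid.like(tdi), grid.like(term)


def mask_injection_component(
    terminals: VoxelGrid, seed_mask: VoxelGrid, binarize_thresh: float = 0.0
) -> VoxelGrid:
    """Zero out the injection-site endpoint cluster.

    Endpoints pile up around the seed (short tracks, spill-over); the
    largest 26-connected component of the binarized terminal map — which
    must intersect the seed — is removed so only remote, long-range
    terminal zones remain.
    """
    binary = terminals.data > binarize_thresh
    structure = np.ones((3, 3, 3), dtype=bool)
    comp, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return terminals.like(terminals.data.copy())
    sizes = ndimage.sum_labels(binary, comp, index=np.arange(1, n + 1))
    seed = seed_mask.data.astype(bool)
    order = np.argsort(sizes)[::-1] + 1  # component labels, largest first
    chosen = None
    largest = int(order[0])
    if (comp[seed] == largest).any():
        chosen = largest
    else:
        for lab in order[1:]:
            if (comp[seed] == int(lab)).any():
                chosen = int(lab)
                warnings.warn(
                    "largest terminal component does not touch the seed; "
                    "masking the largest seed-intersecting component instead",
                    stacklevel=2,
                )
                break
    if chosen is None:
        warnings.warn("no terminal component intersects the seed; map unchanged", stacklevel=2)
        return terminals.like(terminals.data.copy())
    out = terminals.data.copy()
    out[comp == chosen] = 0
    return terminals.like(out)


def filter_streamlines(
    S: StreamlineSet, region_mask: VoxelGrid, mode: str = "passing"
) -> StreamlineSet:
    """Select streamlines passing through or terminating in a region.

    ``passing`` keeps lines with at least one point inside the region;
    ``terminating`` keeps lines whose first or last point lies inside, so
    the terminating set is always a subset of the passing set.
    """
    if mode not in {"passing", "terminating"}:
        raise ValueError(f"mode must be 'passing' or 'terminating', got {mode!r}")
    region = region_mask.data.astype(bool)
    lines, idx = [], []
    for line, si in zip(S.lines, S.seed_indices):
        if mode == "passing":
            vox = _visited_voxels(line, region_mask)
            hit = len(vox) > 0 and region[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        else:
            hit = False
            for endpoint in (line[0], line[-1]):
                iv = np.round(region_mask.world_to_index(endpoint)[0]).astype(int)
                if np.all(iv >= 0) and np.all(iv < np.asarray(region_mask.shape)):
                    hit = hit or bool(region[tuple(iv)])
        if hit:
            lines.append(line)
            idx.append(si)
    return StreamlineSet(lines, idx)


def region_connectivity(
    labels: LabelVolume,
    tdi: VoxelGrid | None = None,
    terminals: VoxelGrid | None = None,
    mode: str = "terminal",
):
    """Per-region connection weights from streamline maps.

    ``passing`` mode scores a region by its mean tract density;
    ``terminal`` mode by the total endpoint count inside it.  Returns a
    DataFrame sorted by weight descending (ties by id) with 1-based ranks.
    """
    import pandas as pd

    if mode == "passing":
        if tdi is None:
            raise ValueError("passing mode needs a tract-density map")
        src = tdi
        reducer = np.mean
    elif mode == "terminal":
        if terminals is None:
            raise ValueError("terminal mode needs a terminal map")
        src = terminals
        reducer = np.sum
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not labels.grid.same_geometry(src):
        raise ValueError("label volume and map geometries differ")

    rows = []
    for rid in labels.region_ids():
        sel = labels.data == rid
        weight = float(reducer(src.data[sel])) if sel.any() else 0.0
        rows.append({"region_id": rid, "acronym": labels.ontology[rid].acronym, "weight": weight})
    df = pd.DataFrame(rows).sort_values(
        ["weight", "region_id"], ascending=[False, True], kind="mergesort"
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def write_tck(S: StreamlineSet, path) -> None:
    """Write streamlines as TCK (world coordinates in mm per the format)."""
    from nibabel.streamlines import Tractogram, save as nib_save
    from nibabel.streamlines.tck import TckFile

    tractogram = Tractogram([line / 1000.0 for line in S.lines], affine_to_rasmm=np.eye(4))
    nib_save(TckFile(tractogram), str(path))


def read_tck(path) -> StreamlineSet:
    """Read a TCK file into a StreamlineSet (converted to µm)."""
    from nibabel.streamlines import load as nib_load

    tck = nib_load(str(path))
    lines = [np.asarray(s) * 1000.0 for s in tck.streamlines]
    return StreamlineSet(lines, list(range(len(lines))))
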