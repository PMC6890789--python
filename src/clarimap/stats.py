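"""Group-level maps and statistics linking modalities.

Four operations cover the group analyses: sum-of-squares heat-maps across
registered subjects, label-wise paired t-tests between hemispheres,
voxelwise Spearman rank correlation between modality maps, and landmark
target-registration error (TRE).
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .atlas import LabelVolume
from .volio import VoxelGrid

__all__ = [
    "StatMap",
    "group_heatmap",
    "labelwise_paired_ttest",
    "voxelwise_spearman",
    "landmark_tre",
    "load_landmarks",
]


@dataclasses.dataclass
class StatMap:
    grid: VoxelGrid
    statistic: str
    n: int


def group_heatmap(volumes: list[VoxelGrid], mode: str = "sum_sq") -> StatMap:
    """Voxelwise sum of squares across subjects (optionally RMS for display)."""
    if not volumes:
        raise ValueError("need at least one volume")
    first = volumes[0]
    acc = np.zeros(first.shape, dtype=float)
    for v in volumes:
        if not first.same_geometry(v):
            raise ValueError("all volumes must share geometry")
        acc += v.data.astype(float) ** 2
    if mode == "rms":
        acc = np.sqrt(acc / len(volumes))
    elif mode != "sum_sq":
        raise ValueError(f"unknown mode {mode!r}")
    return StatMap(first.like(acc), mode, len(volumes))


def labelwise_paired_ttest(
    ipsi: list[pd.DataFrame],
    contra: list[pd.DataFrame],
    labels: LabelVolume | None = None,
    value_col: str = "density_per_mm3",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, StatMap | None]:
    """Two-sided paired t-test per atlas label between hemispheres.

    ``ipsi``/``contra`` are per-subject region tables (same subjects, same
    order).  When a label volume is supplied, a p-value map is painted:
    each label's voxels take its p, thresholded at ``alpha`` (voxels of
    non-significant labels are set to 1).  All-zero difference vectors get
    t = 0, p = 1 exactly; other zero-variance cases are flagged degenerate.
    """
    if len(ipsi) != len(contra) or not ipsi:
        raise ValueError("ipsi and contra must be equal-length, non-empty lists")

    def pivot(tables: list[pd.DataFrame]) -> pd.DataFrame:
        return pd.DataFrame(
            {i: t.set_index("region_id")[value_col] for i, t in enumerate(tables)}
        )

    a, b = pivot(ipsi), pivot(contra)
    common = a.index.intersection(b.index)
    rows = []
    for rid in common:
        x = a.loc[rid].to_numpy(dtype=float)
        y = b.loc[rid].to_numpy(dtype=float)
        diff = x - y
        degenerate = False
        if np.allclose(diff, 0.0):
            t_stat, p_val = 0.0, 1.0
        elif np.isclose(diff.std(ddof=1), 0.0):
            t_stat, p_val, degenerate = np.inf * np.sign(diff.mean()), 0.0, True
        else:
            t_stat, p_val = sps.ttest_rel(x, y)
        rows.append(
            {
                "region_id": int(rid),
                "t": float(t_stat),
                "p": float(p_val),
                "n": len(x),
                "degenerate": degenerate,
            }
        )
    table = pd.DataFrame(rows)

    stat_map = None
    if labels is not None:
        pmap = np.ones(labels.grid.shape, dtype=float)
        for _, rec in table.iterrows():
            if rec["p"] <= alpha:
                pmap[labels.data == rec["region_id"]] = rec["p"]
        stat_map = StatMap(labels.grid.like(pmap), "p", len(ipsi))
    return table, stat_map


def _contralateral_normalize(data: np.ndarray) -> np.ndarray:
    """Divide each hemisphere by the mean of its mirror (x is left-right)."""
    half = data.shape[0] // 2
    out = data.astype(float).copy()
    for sl_this, sl_other in (
        (np.s_[:half], np.s_[data.shape[0] - half :]),
        (np.s_[data.shape[0] - half :], np.s_[:half]),
    ):
        ref = float(np.abs(data[sl_other]).mean())
        if ref > 0:
            out[sl_this] = data[sl_this] / ref
    return out


def voxelwise_spearman(
    a: VoxelGrid,
    b: VoxelGrid,
    mask: VoxelGrid | None = None,
    normalize_contralateral: bool = False,
    exclude_mask: VoxelGrid | None = None,
    presmooth_sigma_vox: float | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation between two maps over in-mask voxels.

    Options mirror common practice: per-hemisphere normalization by the
    contralateral mean, exclusion masks (e.g. ventricles), and an optional
    Gaussian pre-smoothing (sigma in voxels) to absorb small registration
    errors.  Constant inputs yield (nan, nan).
    """
    if not a.same_geometry(b):
        raise ValueError("maps must share geometry")
    da, db = a.data.astype(float), b.data.astype(float)
    if presmooth_sigma_vox:
        da = ndimage.gaussian_filter(da, presmooth_sigma_vox)
        db = ndimage.gaussian_filter(db, presmooth_sigma_vox)
    if normalize_contralateral:
        da = _contralateral_normalize(da)
        db = _contralateral_normalize(db)
    sel = np.ones(a.shape, dtype=bool) if mask is None else mask.data.astype(bool)
    if exclude_mask is not None:
        sel &= ~exclude_mask.data.astype(bool)
    if sel.sum() < 3:
        raise ValueError("need at least 3 in-mask voxels")
    x, y = da[sel], db[sel]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input; Spearman undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def load_landmarks(path: str | Path) -> pd.DataFrame:
    """Landmark CSV with columns name, x, y, z (world µm)."""
    df = pd.read_csv(path)
    missing = {"name", "x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"landmark file missing columns: {sorted(missing)}")
    return df


def landmark_tre(moved: pd.DataFrame, reference: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-landmark Euclidean distances and their RMSE, in µm.

    Landmarks are matched by name; a name mismatch between the two sets is
    an error.  Symmetric in its arguments.
    """
    m = moved.set_index("name")[["x", "y", "z"]].sort_index()
    r = reference.set_index("name")[["x", "y", "z"]].sort_index()
    if not m.index.equals(r.index):
        raise ValueError("landmark name sets differ between moved and reference")
    d = np.linalg.norm(m.to_numpy(float) - r.to_numpy(float), axis=1)
    distances = pd.Series(d, index=m.index, name="distance_um")
    rmse = float(np.sqrt(np.mean(d**2)))
    return distances, rmse
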