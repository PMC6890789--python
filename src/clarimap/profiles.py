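"""Along-tract intensity profiles and hemisphere asymmetry.

A tract profile samples an intensity volume at a fixed number of nodes
along each streamline (arc-length resampled, trilinear interpolation),
then averages consecutive blocks of streamlines into bundles.  The
hemisphere-asymmetry statistic compares ipsilateral against contralateral
profiles per subject — the contralateral profile is obtained by sampling a
left-right mirrored volume with the same streamline geometry — and tests
group differences with a two-sample t-test on per-subject mean asymmetry.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .sta import StreamlineSet
from .volio import VoxelGrid

__all__ = ["TractProfile", "sample_profiles", "hemisphere_asymmetry"]


@dataclasses.dataclass
class TractProfile:
    """Bundle × node matrix of mean intensity along a tract."""

    values: np.ndarray  # (n_bundles, n_nodes)
    n_streamlines: int
    bundle_size: int
    subject: str = ""
    hemisphere: str = ""
    group: str = ""


def _resample_arclength(line: np.ndarray, n_nodes: int) -> np.ndarray:
    """Resample a polyline to n_nodes equally spaced along its arc length."""
    seg = np.linalg.norm(np.diff(line, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return np.repeat(line[:1], n_nodes, axis=0)
    t = np.linspace(0.0, total, n_nodes)
    return np.stack([np.interp(t, s, line[:, ax]) for ax in range(3)], axis=1)


def sample_profiles(
    intensity: VoxelGrid,
    S: StreamlineSet,
    n_nodes: int = 100,
    bundle_size: int = 10,
    subject: str = "",
    hemisphere: str = "",
    group: str = "",
) -> TractProfile:
    """Mean intensity along every bundle of ``bundle_size`` streamlines.

    Streamlines are taken in seed order (the tracker seeds deterministically
    along the mask, so consecutive seeds are spatially adjacent) and grouped
    into consecutive blocks; each block's profile is the per-node mean of
    its members' trilinear samples.  Samples outside the volume are clipped
    to the nearest voxel.
    """
    if len(S) == 0:
        raise ValueError("empty streamline set")
    if len(S) < bundle_size:
        warnings.warn(
            f"only {len(S)} streamlines for bundle size {bundle_size}; single partial bundle",
            stacklevel=2,
        )
    order = np.argsort(np.asarray(S.seed_indices), kind="mergesort")
    samples = np.empty((len(S), n_nodes))
    upper = np.asarray(intensity.shape, dtype=float) - 1
    for row, li in enumerate(order):
        nodes = _resample_arclength(S.lines[li], n_nodes)
        idx = intensity.world_to_index(nodes)
        idx = np.clip(idx, 0.0, upper)
        samples[row] = ndimage.map_coordinates(
            intensity.data.astype(float), idx.T, order=1, mode="nearest"
        )
    bundles = [
        samples[i : i + bundle_size].mean(axis=0) for i in range(0, len(S), bundle_size)
    ]
    return TractProfile(
        np.asarray(bundles), len(S), bundle_size, subject=subject, hemisphere=hemisphere, group=group
    )


def _subject_asymmetry(ipsi: TractProfile, contra: TractProfile) -> tuple[float, np.ndarray]:
    """Mean |contra − ipsi| / mean(contra) × 100 over nodes, plus signed curve."""
    if ipsi.values.shape != contra.values.shape:
        raise ValueError("ipsi and contra profiles must have matching shape")
    i_curve = ipsi.values.mean(axis=0)
    c_curve = contra.values.mean(axis=0)
    denom = float(c_curve.mean())
    if denom == 0:
        raise ZeroDivisionError("contralateral mean is zero")
    absolute = float(np.mean(np.abs(c_curve - i_curve)) / denom * 100.0)
    signed = (c_curve - i_curve) / denom * 100.0
    return absolute, signed


def hemisphere_asymmetry(
    ipsi_profiles: dict[str, TractProfile],
    contra_profiles: dict[str, TractProfile],
    groups: dict[str, str],
) -> tuple[pd.DataFrame, dict]:
    """Per-subject hemisphere asymmetry and a two-sample group test.

    ``ipsi_profiles``/``contra_profiles`` map subject id to its profile;
    ``groups`` maps subject id to a group tag (exactly two groups).  Per
    subject the asymmetry is the node-mean of |contra − ipsi| divided by
    the contralateral mean, in percent.  Subjects with a zero contralateral
    mean are excluded with a warning.  Returns the per-subject table and a
    dict with the two-sided two-sample t-test between groups.
    """
    if set(ipsi_profiles) != set(contra_profiles):
        raise ValueError("ipsi and contra subject sets differ")
    rows = []
    signed_curves = {}
    for sid in sorted(ipsi_profiles):
        try:
            asym, signed = _subject_asymmetry(ipsi_profiles[sid], contra_profiles[sid])
        except ZeroDivisionError:
            warnings.warn(f"subject {sid}: contralateral mean is zero; excluded", stacklevel=2)
            continue
        rows.append({"subject": sid, "group": groups[sid], "asymmetry_pct": asym})
        signed_curves[sid] = signed
    table = pd.DataFrame(rows)
    names = sorted(table["group"].unique())
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    x = table.loc[table["group"] == names[0], "asymmetry_pct"].to_numpy()
    y = table.loc[table["group"] == names[1], "asymmetry_pct"].to_numpy()
    if min(len(x), len(y)) < 2:
        raise ValueError("need at least two subjects per group")
    t_stat, p_val = sps.ttest_ind(x, y)
    test = {
        "groups": names,
        "means_pct": [float(x.mean()), float(y.mean())],
        "t": float(t_stat),
        "p": float(p_val),
        "signed_curves": signed_curves,
    }
    return table, test
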