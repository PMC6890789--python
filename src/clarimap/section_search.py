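"""Locate a cut tissue section inside a whole-brain volume.

Thick sections cut from a cleared brain must be mapped back to their
position in the whole-brain scan before registration can proceed.  The
similarity between the input section and a candidate sub-volume is the
mean squared difference (MSD) between z-score-normalized patches;
normalization makes the match robust to the intensity inhomogeneity
typical of cleared volumes.  The search is a coarse-to-fine sliding
window: round 0 scans the whole volume at a coarse increment, and every
later round halves the increment and searches a window around the
incumbent best offset.  For efficiency the normalized MSD is evaluated
for every feasible offset in one pass with FFT cross-correlation plus
sliding-window sums, and the rounds index into that map.  The final
matched segment is expanded by a margin to absorb boundary errors before
the downstream deformable registration (out of scope here).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.signal import fftconvolve

from .volio import VoxelGrid

__all__ = ["SearchResult", "pyramid_search"]


@dataclasses.dataclass
class SearchResult:
    offset_vox: tuple[int, int, int]
    segment_shape: tuple[int, int, int]
    similarity: float
    round_trace: list[dict]


def _msd_map(whole: np.ndarray, section: np.ndarray, raw: bool) -> np.ndarray:
    """Normalized (or raw) MSD against the section at every valid offset.

    For z-scored patches, MSD(o) = 2 * (1 - NCC(o)); NCC and the sliding
    patch mean/variance come from three FFT correlations.
    """
    w = whole.astype(float)
    s = section.astype(float)
    n = s.size
    kernel = np.ones(s.shape)
    flip = tuple(slice(None, None, -1) for _ in range(3))
    sum1 = fftconvolve(w, kernel, mode="valid")
    sum2 = fftconvolve(w**2, kernel, mode="valid")
    mu = sum1 / n
    var = np.maximum(sum2 / n - mu**2, 0.0)
    if raw:
        cross = fftconvolve(w, s[flip], mode="valid")
        return sum2 / n - 2.0 * cross / n + float(np.mean(s**2))
    s_sd = s.std()
    if s_sd == 0:
        raise ValueError("all-constant section: z-scored similarity is degenerate")
    zs = (s - s.mean()) / s_sd
    cross = fftconvolve(w, zs[flip], mode="valid")
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        ncc = np.where(sd > 0, cross / (n * sd), -np.inf)
    return np.maximum(2.0 * (1.0 - ncc), 0.0)


def _exact_msd(whole: np.ndarray, section: np.ndarray, off, raw: bool) -> float:
    sl = tuple(slice(o, o + s) for o, s in zip(off, section.shape))
    a = whole[sl].astype(float)
    b = section.astype(float)
    if not raw:
        if a.std() == 0 or b.std() == 0:
            return float("inf")
        a = (a - a.mean()) / a.std()
        b = (b - b.mean()) / b.std()
    return float(np.mean((a - b) ** 2))


def _axis_grid(lo: int, hi: int, step: int, extra: list[int]) -> np.ndarray:
    vals = sorted(set(list(range(lo, hi + 1, max(step, 1))) + [v for v in extra if lo <= v <= hi] + [hi]))
    return np.asarray(vals, dtype=int)


def pyramid_search(
    whole: VoxelGrid,
    section: VoxelGrid,
    rounds: int = 5,
    expand: float = 0.15,
    raw_msd: bool = False,
    initial_stride_divisor: int = 8,
) -> tuple[SearchResult, VoxelGrid]:
    """Coarse-to-fine MSD search for the best-matching sub-volume.

    Round 0 scans the whole volume at an increment of
    ``section_shape // initial_stride_divisor`` per axis (minimum 1, with
    the boundary offset always included); each subsequent round halves the
    increment (floor, minimum 1) and searches a window of ± the previous
    increment around the incumbent best offset.  The incumbent is carried
    into every window, so the best similarity is non-increasing across
    rounds.  Ties break toward the lexicographically smallest offset.

    Returns the search result (offset, similarity, per-round trace) and
    the extracted segment, expanded by ``expand`` per axis and clipped to
    the volume bounds.
    """
    wshape = np.asarray(whole.shape)
    sshape = np.asarray(section.shape)
    if np.any(sshape > wshape):
        raise ValueError(f"section shape {tuple(sshape)} exceeds whole {tuple(wshape)}")
    limits = wshape - sshape  # largest valid offset per axis

    mmap = _msd_map(whole.data, section.data, raw_msd)

    def pick(ix, iy, iz, incumbent=None):
        sub = mmap[np.ix_(ix, iy, iz)]
        flat = int(np.argmin(sub))
        i, j, k = np.unravel_index(flat, sub.shape)
        cand = (int(ix[i]), int(iy[j]), int(iz[k]))
        if incumbent is not None and mmap[incumbent] <= mmap[cand]:
            if mmap[incumbent] < mmap[cand] or incumbent < cand:
                return incumbent
        return cand

    stride = np.maximum(sshape // initial_stride_divisor, 1)
    axes = [_axis_grid(0, int(limits[ax]), int(stride[ax]), []) for ax in range(3)]
    incumbent = pick(*axes)
    trace = [
        {
            "round": 0,
            "offset": incumbent,
            "stride": tuple(int(s) for s in stride),
            "similarity": float(mmap[incumbent]),
        }
    ]

    for rnd in range(1, rounds):
        window = stride.copy()
        stride = np.maximum(stride // 2, 1)
        axes = [
            _axis_grid(
                max(incumbent[ax] - int(window[ax]), 0),
                min(incumbent[ax] + int(window[ax]), int(limits[ax])),
                int(stride[ax]),
                [incumbent[ax]],
            )
            for ax in range(3)
        ]
        incumbent = pick(*axes, incumbent=incumbent)
        trace.append(
            {
                "round": rnd,
                "offset": incumbent,
                "stride": tuple(int(s) for s in stride),
                "similarity": float(mmap[incumbent]),
            }
        )

    best_off = incumbent
    best_sim = _exact_msd(whole.data, section.data, best_off, raw_msd)

    margin = np.round(sshape * expand / 2).astype(int)
    seg_lo = np.maximum(np.asarray(best_off) - margin, 0)
    seg_hi = np.minimum(np.asarray(best_off) + sshape + margin, wshape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(seg_lo, seg_hi))
    segment = VoxelGrid(
        whole.data[sl].copy(),
        whole.spacing_um.copy(),
        whole.origin_um + seg_lo * whole.spacing_um,
        whole.axis_codes,
    )
    result = SearchResult(
        offset_vox=tuple(int(o) for o in best_off),
        segment_shape=tuple(int(b - a) for a, b in zip(seg_lo, seg_hi)),
        similarity=best_sim,
        round_trace=trace,
    )
    return result, segment
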