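"""Replicate-correlation tools: overlap management and misalignment correction.

Two species whose isotopic envelopes overlap in m/z still vary independently
in abundance from replicate to replicate.  The cross-replicate Pearson
correlation between the reference peak and any other position therefore
separates positions belonging to the same ID (high correlation) from foreign,
overlapping ones (low correlation).  These correlations are used (i) as
weights in the fitting score, so overlapped positions barely contribute, and
(ii) to remove from the candidate vector, together with a fitted ID, all
peaks strongly correlated with its reference peak.

Replicate misalignment (e.g. per-scan calibration jitter) broadens the
representative spectrum and degrades the effective resolution; within the
region of each analyzed ID, every replicate is shifted by the integer number
of grid steps that maximizes its correlation with the representative
spectrum, evaluated only on the most correlated points of the region.
"""

from __future__ import annotations

import warnings

import numpy as np

from .detect import Peak
from .io import ReplicateSet

__all__ = ["correlation_weights", "overlap_aware_removal", "align_replicates"]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def correlation_weights(rs: ReplicateSet, ref_peak: Peak,
                        tid_positions: np.ndarray) -> np.ndarray:
    """Cross-replicate correlation weights for TID positions.

    For every position the Pearson correlation across replicates between the
    intensity at the reference-peak grid point and the intensity at that
    position is computed and clamped at zero; the reference position itself
    gets weight 1.  Zero-variance columns (no replicate variation to exploit)
    fall back to weight 1 with a warning.  Requires at least 3 replicates.
    """
    if rs.n_replicates < 3:
        raise ValueError("correlation weights need at least 3 replicates")
    ref_row = rs.matrix[ref_peak.grid_index, :]
    positions = np.atleast_1d(np.asarray(tid_positions, dtype=float))
    idx = np.clip(np.searchsorted(rs.grid, positions), 0, rs.grid.size - 1)
    left = np.clip(idx - 1, 0, rs.grid.size - 1)
    closer_left = np.abs(rs.grid[left] - positions) < np.abs(rs.grid[idx] - positions)
    idx = np.where(closer_left, left, idx)

    weights = np.empty(positions.size)
    warned = False
    for i, gi in enumerate(idx):
        if gi == ref_peak.grid_index:
            weights[i] = 1.0
            continue
        r = _pearson(ref_row, rs.matrix[gi, :])
        if np.isnan(r):
            weights[i] = 1.0
            warned = True
        else:
            weights[i] = max(0.0, r)
    if warned:
        warnings.warn("zero-variance replicate column(s): weight fell back to 1",
                      stacklevel=2)
    return weights


def overlap_aware_removal(candidates: list[Peak], ref_peak: Peak, rs: ReplicateSet,
                          corr_cut: float = 0.8) -> list[Peak]:
    """Drop candidates highly correlated with the reference peak across replicates.

    A candidate with cross-replicate Pearson correlation >= ``corr_cut``
    against the reference peak is considered part of the same ID and removed.
    Zero-variance candidates are retained.
    """
    ref_row = rs.matrix[ref_peak.grid_index, :]
    kept = []
    for c in candidates:
        if c.grid_index == ref_peak.grid_index:
            continue
        r = _pearson(ref_row, rs.matrix[c.grid_index, :])
        if np.isnan(r) or r < corr_cut:
            kept.append(c)
    return kept


def align_replicates(rs: ReplicateSet, region: tuple[int, int], max_shift: int,
                     top_fraction: float = 0.5) -> np.ndarray:
    """Shift each replicate within a region to best match the representative.

    ``region`` is a half-open grid index range; ``max_shift`` the shift bound
    in grid steps.  Point selection: within the region, points are ranked by
    the cross-replicate correlation between their intensities and the
    replicates' regional totals, and the correlation objective is evaluated
    on the top ``top_fraction`` of points.  Shift 0 is always a candidate, so
    the correlation with the representative never decreases.  The matrix is
    edited in place and the representative recomputed over the region; the
    applied shifts are returned.  A region shorter than twice the shift bound
    is skipped with a warning (all-zero shifts).
    """
    lo, hi = region
    n, m = rs.matrix.shape
    lo, hi = max(0, int(lo)), min(n, int(hi))
    max_shift = int(max_shift)
    shifts = np.zeros(m, dtype=int)
    if max_shift < 1:
        return shifts
    if hi - lo < 2 * max_shift + 2:
        warnings.warn("alignment region shorter than twice the shift bound; skipped",
                      stacklevel=2)
        return shifts

    rep = rs.representative[lo:hi].copy()
    sub = rs.matrix[lo:hi, :]
    totals = sub.sum(axis=0)
    point_corr = np.empty(hi - lo)
    for i in range(hi - lo):
        r = _pearson(sub[i, :], totals)
        point_corr[i] = -np.inf if np.isnan(r) else r
    k = max(2, int(np.ceil(top_fraction * (hi - lo))))
    if np.isfinite(point_corr).sum() < k:
        # no cross-replicate intensity variation to rank by (e.g. identical
        # scan intensities): fall back to the strongest-signal points
        point_corr = rep
    sel = np.sort(np.argsort(point_corr, kind="stable")[-k:])

    base_idx = np.arange(lo, hi)
    for j in range(m):
        col = rs.matrix[:, j]
        best_corr, best_shift = -np.inf, 0
        for shift in range(-max_shift, max_shift + 1):
            # edge-clamped source indices so boundary regions stay shiftable
            segment = col[np.clip(base_idx - shift, 0, n - 1)]
            r = _pearson(segment[sel], rep[sel])
            if np.isnan(r):
                r = -np.inf
            if r > best_corr or (r == best_corr and abs(shift) < abs(best_shift)):
                best_corr, best_shift = r, shift
        shifts[j] = best_shift
        if best_shift != 0:
            rs.matrix[lo:hi, j] = col[np.clip(base_idx - best_shift, 0, n - 1)]
    rs.recompute_representative(lo, hi)
    return shifts
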