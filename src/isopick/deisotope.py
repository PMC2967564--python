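"""Monoisotoping and charge-state determination by iterative TID fitting.

The extraction loop repeatedly takes the lowest-m/z surviving candidate peak,
discards it if it sits below the intensity threshold, and otherwise fits
theoretical isotopic distributions (TIDs) to the surrounding spectrum for
every charge 1..ZMax and every configured reference residue:

* If isotopic peaks are resolvable at this mass and charge
  (m/z / RP < 1/Z), the candidate is treated as the monoisotopic peak;
  otherwise the candidate is the most-likely (apex) peak and the
  monoisotopic mass is recovered through the inverse regression of the
  most-likely model — the "double model" that makes the same procedure work
  from low-resolution TOF to FTICR data.
* The TID is pruned to peaks above 1/1000 of its maximum, rendered as a sum
  of Gaussians (sigma = m/z / (2.35482 * RP)) scaled so the curve matches
  the candidate intensity at the reference position, on top of the region's
  minimum intensity as a local residual baseline.
* The rendered TID is shifted coarsely by whole isotope positions (left by
  k* positions for a monoisotopic reference whose true monoisotopic peak may
  have been thresholded away; +/-1 position for a most-likely reference, to
  absorb regression error) and finely over a fraction of the peak FWHM at
  grid resolution.
* The fit score is the weighted mean absolute difference between the
  normalized TID curve and the normalized spectrum at a small stencil of
  evaluation points; the best (lowest) score wins, with ties broken toward
  lower charge and the first configured residue.

An accepted fit (score below the threshold) is emitted as a peak-list entry
(monoisotopic mass, charge, summed TID intensity), subtracted from the
representative spectrum, and all candidate peaks it explains (TID fitting
above 80% of the observed peak) are removed; a rejected candidate is simply
dropped.  Each iteration removes at least one candidate, so the loop always
terminates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .averagine import MostLikelyModel, TIDTable, tid_at_mass
from .detect import DetectionParams, Peak, ThresholdCurve, build_threshold, find_peaks
from .io import PeakListEntry, ReplicateSet
from .isotopes import FWHM_OVER_SIGMA, ISOTOPE_SPACING, PROTON_MASS

__all__ = [
    "FitParams",
    "TIDFit",
    "choose_reference_model",
    "prune_tid",
    "render_tid",
    "fit_score",
    "best_fit_for_peak",
    "extract_peak_list",
]


@dataclass
class FitParams:
    """Parameters of the TID fitting and acceptance step."""

    score_threshold: float = 0.35
    tid_prune_ratio: float = 1e-3
    removal_fit_ratio: float = 0.8
    charge_prior_lambda: float = 0.05
    fine_shift_halfwidth: float = 0.25  # fraction of the peak FWHM
    esi_mode: bool = False
    overlap_corr_cut: float = 0.8

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be positive")
        if not 0 < self.removal_fit_ratio <= 1:
            raise ValueError("removal_fit_ratio must lie in (0, 1]")


@dataclass
class TIDFit:
    """One rendered-and-scored TID placement."""

    residue: str
    z: int
    ref_model: str              # "monoisotopic" | "most_likely"
    score: float
    monoisotopic_mass: float    # neutral mass implied by the final placement
    anchor_mz: float            # m/z where the reference position sits
    k_ref: int                  # TID position index used as reference
    sigma: float
    region: tuple[int, int]     # grid slice [i0, i1) of the fitted region
    positions: np.ndarray       # m/z of the kept TID sticks
    sticks: np.ndarray          # scaled stick intensities
    curve: np.ndarray           # rendered curve over the region grid
    offset: float               # local residual baseline
    intensity: float            # sum of scaled TID stick intensities
    eval_idx: np.ndarray        # absolute grid indices scored


def choose_reference_model(mz: float, z: int, rp_est: float) -> str:
    """Monoisotopic reference iff isotopes are resolved: m/z / RP < 1/Z."""
    if mz <= 0 or z < 1 or rp_est <= 0:
        raise ValueError("mz, z and rp_est must be positive")
    return "monoisotopic" if mz / rp_est < 1.0 / z else "most_likely"


def prune_tid(abundances: np.ndarray, ratio: float = 1e-3) -> tuple[int, np.ndarray]:
    """Keep the contiguous run of positions above ``ratio`` of the TID maximum.

    Returns (index of the first kept position, kept abundances).
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0 or a.max() <= 0:
        raise ValueError("pruning removed every TID position")
    keep = np.nonzero(a >= ratio * a.max())[0]
    return int(keep[0]), a[keep[0]: keep[-1] + 1].copy()


def render_tid(abundances: np.ndarray, z: int, ref_mz: float, ref_intensity: float,
               rp_est: float, grid: np.ndarray, baseline_offset: float,
               k_ref: int = 0, position_spacing: float = ISOTOPE_SPACING,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Render a pruned TID as a Gaussian-bell sum over ``grid``.

    Position ``k_ref`` of ``abundances`` is placed at ``ref_mz``; the other
    positions follow at spacing ``position_spacing / z``.  Every position
    contributes a Gaussian with sigma = ref_mz / (2.35482 * RP).  The curve
    is scaled so its value at the reference position equals
    ``ref_intensity``, after adding the local residual baseline
    ``baseline_offset``.  Returns (curve, stick positions, scaled sticks,
    scale factor).
    """
    a = np.asarray(abundances, dtype=float)
    if a.size == 0:
        raise ValueError("cannot render an empty TID")
    if not 0 <= k_ref < a.size:
        raise ValueError("reference position outside the pruned TID")
    positions = ref_mz + (np.arange(a.size) - k_ref) * position_spacing / z
    sigma = ref_mz / (FWHM_OVER_SIGMA * rp_est)
    unit = np.exp(-((grid[:, None] - positions[None, :]) ** 2) / (2.0 * sigma**2)) @ a
    ref_unit = float(np.exp(-((ref_mz - positions) ** 2) / (2.0 * sigma**2)) @ a)
    if ref_unit <= 0:
        raise ValueError("reference position carries no TID intensity")
    scale = max(ref_intensity - baseline_offset, 0.0) / ref_unit
    curve = baseline_offset + scale * unit
    return curve, positions, scale * a, scale


def fit_score(curve: np.ndarray, spectrum: np.ndarray, points: np.ndarray,
              weights: np.ndarray, ref_intensity: float, z: int, z_ref: int,
              esi_mode: bool = False, charge_prior_lambda: float = 0.05) -> float:
    """Weighted mean absolute difference between normalized curve and spectrum.

    Both traces are divided by the reference-peak intensity, making the score
    dimensionless and the acceptance threshold transferable across spectra.
    In ESI mode the score is inflated for low charges (low charge states are
    unlikely for electrosprayed species).
    """
    points = np.asarray(points, dtype=int)
    if points.size == 0:
        raise ValueError("at least one evaluation point is required")
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    if wsum == 0:
        warnings.warn("all evaluation weights are zero; score is 0", stacklevel=2)
        return 0.0
    if ref_intensity <= 0:
        return float("inf")
    diff = np.abs(curve[points] - spectrum[points]) / ref_intensity
    score = float((weights * diff).sum() / wsum)
    if esi_mode and z_ref > 0:
        score *= 1.0 + charge_prior_lambda * (z_ref - z) / z_ref
    return score


def _anchor_configs(mz: float, z: int, ref_model: str, model: MostLikelyModel,
                    spacing: float) -> list[tuple[float, int]]:
    """Coarse-shift anchor configurations: (monoisotopic mass, reference index)."""
    neutral = z * (mz - PROTON_MASS)
    configs: list[tuple[float, int]] = []
    if ref_model == "monoisotopic":
        configs.append((neutral, 0))
        # the true monoisotopic peak may have been thresholded away and the
        # candidate may really be the most-likely peak: shift left by k*
        m0 = model.predict_monoisotopic(neutral)
        k = model.k_star(m0)
        if k > 0:
            configs.append((m0, k))
    else:
        for s in (0, -1, 1):  # +/-1 position absorbs regression error
            m0 = model.predict_monoisotopic(neutral + s * spacing)
            k = model.k_star(m0) - s
            if k >= 0:
                configs.append((m0, k))
    return configs


def best_fit_for_peak(peak: Peak, rep: np.ndarray, grid: np.ndarray, rp_est: float,
                      det_params: DetectionParams, fit_params: FitParams,
                      tables: dict[str, TIDTable], models: dict[str, MostLikelyModel],
                      weights_fn=None, full_stencil: bool = False) -> TIDFit | None:
    """Best TID fit for one candidate over charges, residues and shifts.

    ``weights_fn(positions, ref_index)``, when given, supplies per-stick
    weights (replicate-correlation overlap handling).  ``full_stencil``
    forces evaluation over the whole TID even when ZMax = 1 (used by the
    resolution-power estimation, which needs the complete envelope shape).
    Returns ``None`` when no placement could be evaluated.
    """
    best: TIDFit | None = None
    for z in range(1, det_params.z_max + 1):
        for name, table in tables.items():
            model = models[name]
            spacing = table.position_spacing
            ref_model = choose_reference_model(peak.mz, z, rp_est)
            for m0, k_ref in _anchor_configs(peak.mz, z, ref_model, model, spacing):
                if not table.masses[0] <= m0 <= table.masses[-1]:
                    continue
                tid = tid_at_mass(table, m0)
                try:
                    k0, kept = prune_tid(tid.abundances, fit_params.tid_prune_ratio)
                except ValueError:
                    continue
                k_rel = k_ref - k0
                if not 0 <= k_rel < kept.size:
                    continue
                fit = _fine_scan(peak, rep, grid, rp_est, z, name, ref_model, kept,
                                 k_rel, k0, spacing, det_params, fit_params, weights_fn,
                                 full_stencil)
                if fit is not None and (best is None or fit.score < best.score):
                    best = fit
    return best


def _fine_scan(peak: Peak, rep: np.ndarray, grid: np.ndarray, rp_est: float, z: int,
               residue: str, ref_model: str, kept: np.ndarray, k_rel: int, k0: int,
               spacing: float, det_params: DetectionParams, fit_params: FitParams,
               weights_fn, full_stencil: bool = False) -> TIDFit | None:
    """Slide one anchored TID over +/- a fraction of the FWHM at grid resolution."""
    fwhm = peak.mz / rp_est
    half = fit_params.fine_shift_halfwidth * fwhm
    j0 = np.searchsorted(grid, peak.mz - half)
    j1 = np.searchsorted(grid, peak.mz + half, side="right")
    deltas = np.unique(np.append(grid[j0:j1] - peak.mz, 0.0))

    best: TIDFit | None = None
    for delta in deltas:
        anchor = peak.mz + delta
        sigma = anchor / (FWHM_OVER_SIGMA * rp_est)
        lo_mz = anchor - k_rel * spacing / z - 3.0 * sigma
        hi_mz = anchor + (kept.size - 1 - k_rel) * spacing / z + 3.0 * sigma
        i0 = int(np.searchsorted(grid, lo_mz))
        i1 = int(np.searchsorted(grid, hi_mz, side="right"))
        if i1 - i0 < 2:
            continue
        seg_grid = grid[i0:i1]
        seg_rep = rep[i0:i1]
        offset = float(seg_rep.min())
        ref_intensity = float(np.interp(anchor, seg_grid, seg_rep))
        if ref_intensity <= offset:
            continue
        try:
            curve, positions, sticks, scale = render_tid(
                kept, z, anchor, ref_intensity, rp_est, seg_grid, offset,
                k_ref=k_rel, position_spacing=spacing)
        except ValueError:
            continue

        stencil_z_max = 2 if full_stencil else det_params.z_max
        eval_rel, eval_w = _evaluation_stencil(
            seg_grid, positions, k_rel, k0, z, anchor, fwhm, stencil_z_max,
            weights_fn)
        if eval_rel.size == 0:
            continue
        score = fit_score(curve, seg_rep, eval_rel, eval_w, ref_intensity, z,
                          det_params.z_max, fit_params.esi_mode,
                          fit_params.charge_prior_lambda)
        if best is None or score < best.score:
            # k_rel is relative to the pruned TID; k0 positions were pruned
            # off its front, so the monoisotopic position is k_rel + k0 steps
            # left of the anchor
            mono_mz = anchor - (k_rel + k0) * spacing / z
            best = TIDFit(
                residue=residue, z=z, ref_model=ref_model, score=score,
                monoisotopic_mass=z * (mono_mz - PROTON_MASS), anchor_mz=anchor,
                k_ref=k_rel, sigma=sigma, region=(i0, i1), positions=positions,
                sticks=sticks, curve=curve, offset=offset,
                intensity=float(sticks.sum()), eval_idx=eval_rel + i0)
    return best


def _evaluation_stencil(seg_grid: np.ndarray, positions: np.ndarray, k_rel: int,
                        k0: int, z: int, anchor: float, fwhm: float, z_max: int,
                        weights_fn) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation-point indices (relative to the region) and their weights.

    ZMax = 1: the reference position plus three points left of the estimated
    monoisotopic peak (overlap usually comes from the right).  ZMax > 1: the
    apex of every kept TID position plus the two midpoints toward its
    neighbors — the midpoints are what distinguish charge states, because a
    z-fold coarser comb placed on a finer envelope leaves real isotopic
    peaks sitting in the fitted comb's valleys.
    """
    n = seg_grid.size
    stick_w = np.ones(positions.size)
    if weights_fn is not None:
        stick_w = np.asarray(weights_fn(positions, k_rel), dtype=float)
    if z_max == 1:
        spacing_z = positions[1] - positions[0] if positions.size > 1 else ISOTOPE_SPACING / z
        mono_mz = anchor - (k_rel + k0) * spacing_z
        # left points straddle the one-isotope-left position: if the true
        # monoisotopic peak was thresholded away and the anchor is really a
        # higher isotope, a real peak lurks there and rejects the placement
        pts_mz = [anchor, mono_mz - fwhm / 2.0, mono_mz - spacing_z,
                  mono_mz - 2.0 * spacing_z]
        w = [float(stick_w[k_rel])] + [1.0, 1.0, 1.0]
    else:
        half = ISOTOPE_SPACING / (2.0 * z)
        flank = min(fwhm / 2.0, half / 2.0)
        pts_mz, w = [], []
        for p, wp in zip(positions, stick_w):
            pts_mz.extend([p - half, p - flank, p, p + flank, p + half])
            w.extend([wp] * 5)
    idx = np.searchsorted(seg_grid, np.asarray(pts_mz))
    idx = np.clip(idx, 0, n - 1)
    left = np.clip(idx - 1, 0, n - 1)
    use_left = np.abs(seg_grid[left] - pts_mz) < np.abs(seg_grid[idx] - pts_mz)
    idx = np.where(use_left, left, idx)
    inside = (np.asarray(pts_mz) >= seg_grid[0]) & (np.asarray(pts_mz) <= seg_grid[-1])
    idx, w = idx[inside], np.asarray(w)[inside]
    uniq, first = np.unique(idx, return_index=True)
    return uniq, np.asarray(w)[first]


def extract_peak_list(rs: ReplicateSet, det_params: DetectionParams,
                      fit_params: FitParams, tables: dict[str, TIDTable],
                      models: dict[str, MostLikelyModel], *,
                      peaks: list[Peak] | None = None,
                      threshold: ThresholdCurve | None = None,
                      use_overlap: bool = False, use_align: bool = False,
                      ) -> list[PeakListEntry]:
    """Run the full monoisotoping loop; edits the representative in place.

    Detection and thresholding are computed here when not supplied.  The
    optional replicate functionalities require M >= 3 (overlap weights) and
    M >= 2 (alignment) and are silently disabled otherwise.
    """
    from .replicates import align_replicates, correlation_weights, overlap_aware_removal

    rp_est = det_params.rp_est if det_params.rp_est is not None else det_params.rp_in
    rep = rs.representative
    grid = rs.grid
    if peaks is None:
        peaks = find_peaks(rs.representative_spectrum(), rp_est,
                           det_params.min_window_points)
    if threshold is None:
        density = None
        if det_params.density_file:
            from .detect import load_mass_density
            density = load_mass_density(det_params.density_file)
        threshold = build_threshold(peaks, rs.representative_spectrum(), density)
    use_overlap = use_overlap and rs.n_replicates >= 3
    use_align = use_align and rs.n_replicates >= 2

    subtracted = np.zeros_like(rep)
    candidates = sorted(peaks, key=lambda p: p.mz)
    entries: list[PeakListEntry] = []
    while candidates:
        peak = candidates.pop(0)
        gi = peak.grid_index
        lo_n, hi_n = max(0, gi - 2), min(grid.size, gi + 3)
        current = float(rep[lo_n:hi_n].max())
        if current < threshold.curve[gi]:
            continue

        if use_align:
            fwhm = peak.mz / rp_est
            step = grid[min(gi + 1, grid.size - 1)] - grid[min(gi, grid.size - 2)]
            max_shift = max(1, int(round(fwhm / max(step, 1e-12))))
            halfspan = 33.0 * ISOTOPE_SPACING + 2.0 * fwhm
            a0 = int(np.searchsorted(grid, peak.mz - halfspan))
            a1 = int(np.searchsorted(grid, peak.mz + halfspan, side="right"))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                align_replicates(rs, (a0, a1), max_shift)
            # re-apply earlier TID subtractions over the recomputed rows
            rep[a0:a1] = np.maximum(rep[a0:a1] - subtracted[a0:a1], 0.0)
            current = float(rep[lo_n:hi_n].max())

        peak_now = Peak(peak.mz, current, gi)
        weights_fn = None
        if use_overlap:
            def weights_fn(positions, k_rel, _peak=peak_now):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    w = correlation_weights(rs, _peak, positions)
                w[k_rel] = 1.0
                return w

        fit = best_fit_for_peak(peak_now, rep, grid, rp_est, det_params, fit_params,
                                tables, models, weights_fn)
        if fit is None or fit.score >= fit_params.score_threshold:
            continue

        entries.append(PeakListEntry(fit.monoisotopic_mass, fit.z, fit.intensity,
                                     fit.residue, fit.score))
        i0, i1 = fit.region
        pre = rep[i0:i1].copy()
        rep[i0:i1] = np.maximum(rep[i0:i1] - (fit.curve - fit.offset), 0.0)
        subtracted[i0:i1] += pre - rep[i0:i1]

        # step 12 cleanup: candidates the fitted TID explains are consumed
        half_spacing = ISOTOPE_SPACING / (2.0 * fit.z)
        survivors: list[Peak] = []
        consumed_region: list[Peak] = []
        for c in candidates:
            if i0 <= c.grid_index < i1:
                near = np.min(np.abs(fit.positions - c.mz)) <= half_spacing
                rid = pre[c.grid_index - i0]
                fitted = fit.curve[c.grid_index - i0]
                if near and rid > 0 and fitted >= fit_params.removal_fit_ratio * rid:
                    continue
                consumed_region.append(c)
            survivors.append(c)
        candidates = survivors
        if use_overlap and consumed_region:
            kept = overlap_aware_removal(consumed_region, peak_now, rs,
                                         fit_params.overlap_corr_cut)
            dropped = {id(c) for c in consumed_region} - {id(c) for c in kept}
            candidates = [c for c in candidates if id(c) not in dropped]
    return entries
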