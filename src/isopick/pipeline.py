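"""End-to-end peak-list extraction from raw spectra.

Glues the stages together in the canonical order: per-spectrum baseline
correction (twice), replicate-matrix assembly and quality control, TID-table
preparation, resolution-power estimation, peak detection, intensity
thresholding, and the monoisotoping loop.
"""

from __future__ import annotations

import numpy as np

from .averagine import (MostLikelyModel, TIDTable, build_tid_table,
                        fit_most_likely_model, get_residue)
from .deisotope import FitParams, extract_peak_list
from .detect import (DetectionParams, build_threshold, estimate_rp, find_peaks,
                     load_mass_density)
from .io import PeakListEntry, ReplicateSet, Spectrum, build_replicate_set, qc_filter
from .isotopes import ISOTOPE_SPACING, PROTON_MASS
from .preprocess import preprocess

__all__ = ["prepare_models", "run_pipeline"]

#: TID tables cover 20 kDa by default; built out to 170 kDa only when the
#: input mass range requires it.
DEFAULT_MASS_LIMIT = 20000.0
EXTENDED_MASS_LIMIT = 170000.0


def prepare_models(residues: tuple[str, ...], mass_limit: float,
                   cache: bool = False) -> tuple[dict[str, TIDTable], dict[str, MostLikelyModel]]:
    """Build (or reload) TID tables and most-likely models for the residues."""
    tables: dict[str, TIDTable] = {}
    models: dict[str, MostLikelyModel] = {}
    for name in residues:
        table = build_tid_table(get_residue(name), mass_limit, cache=cache)
        tables[name] = table
        models[name] = fit_most_likely_model(table)
    return tables, models


def run_pipeline(spectra: list[Spectrum], det_params: DetectionParams,
                 fit_params: FitParams | None = None, *,
                 residues: tuple[str, ...] = ("ave", "leu", "avu"),
                 baseline_window: float = 0.05, baseline_passes: int = 2,
                 smoothing: str | None = None, qc_min_corr: float = 0.4,
                 use_overlap: bool = False, use_align: bool = False,
                 estimate_resolution: bool = True, table_cache: bool = False,
                 ) -> tuple[list[PeakListEntry], dict]:
    """Full extraction; returns the peak list and a run report."""
    if fit_params is None:
        fit_params = FitParams()
    report: dict = {"n_input_spectra": len(spectra), "residues": list(residues)}

    processed = [preprocess(s, baseline_window, baseline_passes, smoothing)
                 for s in spectra]
    rs = build_replicate_set(processed)
    if rs.n_replicates >= 2:
        rs = qc_filter(rs, qc_min_corr)
    report["n_replicates_after_qc"] = rs.n_replicates

    max_neutral = det_params.z_max * (rs.grid[-1] - PROTON_MASS)
    limit = DEFAULT_MASS_LIMIT if max_neutral + 35 * ISOTOPE_SPACING <= DEFAULT_MASS_LIMIT \
        else EXTENDED_MASS_LIMIT
    tables, models = prepare_models(residues, limit, cache=table_cache)
    report["tid_mass_limit"] = limit

    if estimate_resolution and det_params.rp_est is None:
        det_params.rp_est = estimate_rp(rs, det_params, tables, models, fit_params)
    rp_est = det_params.rp_est if det_params.rp_est is not None else det_params.rp_in
    det_params.rp_est = rp_est
    report["rp_in"] = det_params.rp_in
    report["rp_est"] = rp_est

    peaks = find_peaks(rs.representative_spectrum(), rp_est,
                       det_params.min_window_points)
    report["n_detected_peaks"] = len(peaks)
    density = load_mass_density(det_params.density_file) if det_params.density_file else None
    threshold = build_threshold(peaks, rs.representative_spectrum(), density)
    report["n_above_threshold"] = int(sum(not threshold.is_noise(p) for p in peaks))

    entries = extract_peak_list(rs, det_params, fit_params, tables, models,
                                peaks=peaks, threshold=threshold,
                                use_overlap=use_overlap, use_align=use_align)
    report["n_extracted"] = len(entries)
    report["parameters"] = {
        "z_max": det_params.z_max, "score_threshold": fit_params.score_threshold,
        "esi_mode": fit_params.esi_mode, "use_overlap": use_overlap,
        "use_align": use_align, "baseline_passes": baseline_passes,
    }
    return entries, report
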