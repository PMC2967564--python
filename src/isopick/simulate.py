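"""Synthetic profile-mode spectra and replicate sets with known ground truth.

Each species is rendered through the same TID machinery the extractor uses:
its theoretical isotopic distribution at the stated monoisotopic mass is
placed at proton-adduct m/z positions and convolved with Gaussian peak shapes
of the stated resolution power.  On top of the signal an exponentially
decaying baseline (matrix/chemical background) and additive Gaussian noise
are applied.  Replicates emulate scan-to-scan variation: per-species
log-normal abundance factors (independent across species — the decorrelation
the overlap weights exploit), a whole-spectrum integer-grid m/z jitter, and
fresh noise per scan.

Truth tables record everything needed to score a pipeline run (masses,
charges, per-replicate abundance factors and applied shifts), so recovery
rates and false-discovery rates can be computed against a mass tolerance
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .averagine import BUILTIN_RESIDUES, TIDTable, build_tid_table, get_residue, tid_at_mass
from .deisotope import prune_tid
from .io import PeakListEntry, ReplicateSet, Spectrum
from .isotopes import FWHM_OVER_SIGMA, ISOTOPE_SPACING, PROTON_MASS

__all__ = [
    "SpeciesSpec",
    "make_grid",
    "simulate_spectrum",
    "simulate_replicates",
    "score_peak_list",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """A peptide-like species to render: monoisotopic mass, charge, abundance."""

    monoisotopic_mass: float
    charge: int = 1
    abundance: float = 1.0
    residue: str = "ave"

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic mass must be positive")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


def make_grid(mz_lo: float, mz_hi: float, rp: float, points_per_fwhm: float = 10.0) -> np.ndarray:
    """Uniform m/z grid sampling the narrowest peak with ``points_per_fwhm`` points."""
    step = mz_lo / (rp * points_per_fwhm)
    return np.arange(mz_lo, mz_hi + step, step)


def _species_tables(species: list[SpeciesSpec],
                    tables: dict[str, TIDTable] | None) -> dict[str, TIDTable]:
    tables = dict(tables) if tables else {}
    for sp in species:
        if sp.residue not in tables:
            limit = 20000.0
            neutral_max = max(s.monoisotopic_mass for s in species if s.residue == sp.residue)
            if neutral_max + 35 * ISOTOPE_SPACING > limit:
                limit = 170000.0
            tables[sp.residue] = build_tid_table(get_residue(sp.residue), limit)
    return tables


def _render_species(sp: SpeciesSpec, grid: np.ndarray, rp: float, table: TIDTable,
                    abundance: float, prune_ratio: float = 1e-3,
                    ) -> tuple[np.ndarray, float, int]:
    """Signal of one species on the grid; returns (curve, apex m/z, apex index)."""
    tid = tid_at_mass(table, sp.monoisotopic_mass)
    k0, kept = prune_tid(tid.abundances, prune_ratio)
    positions = (sp.monoisotopic_mass + (np.arange(kept.size) + k0) * tid.position_spacing
                 ) / sp.charge + PROTON_MASS
    ml_rel = int(np.argmax(kept))
    ml_mz = float(positions[ml_rel])
    if positions[0] < grid[0] or positions[-1] > grid[-1]:
        raise ValueError(f"species at {sp.monoisotopic_mass:.1f} Da (z={sp.charge}) "
                         f"falls outside the grid [{grid[0]:.1f}, {grid[-1]:.1f}]")
    sigma = ml_mz / (FWHM_OVER_SIGMA * rp)
    heights = abundance * kept / kept.max()
    curve = np.exp(-((grid[:, None] - positions[None, :]) ** 2) / (2 * sigma**2)) @ heights
    return curve, ml_mz, k0 + ml_rel


def simulate_spectrum(species: list[SpeciesSpec], rp: float, grid: np.ndarray,
                      *, baseline: tuple[float, float] | None = None,
                      noise_sigma: float = 0.0, seed: int | None = None,
                      tables: dict[str, TIDTable] | None = None,
                      ) -> tuple[Spectrum, pd.DataFrame]:
    """Render species on ``grid`` at resolution power ``rp``.

    ``baseline`` is (amplitude, decay scale in Da) of an exponentially
    decaying additive background; Gaussian noise of the given sigma is added
    when ``noise_sigma`` > 0.  Returns the spectrum and a truth table with one
    row per species (mass, charge, abundance, apex m/z and isotope index).
    """
    tables = _species_tables(species, tables)
    rng = np.random.default_rng(seed)
    signal = np.zeros_like(grid)
    rows = []
    for sp in species:
        curve, ml_mz, ml_index = _render_species(sp, grid, rp, tables[sp.residue],
                                                 sp.abundance)
        signal += curve
        rows.append((sp.monoisotopic_mass, sp.charge, sp.abundance, sp.residue,
                     ml_mz, ml_index))
    if baseline is not None:
        amp, decay = baseline
        signal = signal + amp * np.exp(-(grid - grid[0]) / decay)
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma, grid.size)
    truth = pd.DataFrame(rows, columns=["monoisotopic_mass", "charge", "abundance",
                                        "residue", "most_likely_mz", "most_likely_index"])
    return Spectrum(grid.copy(), signal), truth


def simulate_replicates(species: list[SpeciesSpec], rp: float, grid: np.ndarray,
                        n_replicates: int, *, jitter_sigma: float = 0.0,
                        intensity_cv: float = 0.3,
                        baseline: tuple[float, float] | None = None,
                        noise_sigma: float = 0.0, seed: int | None = None,
                        tables: dict[str, TIDTable] | None = None,
                        ) -> tuple[ReplicateSet, dict]:
    """Simulate M replicate scans of the same sample.

    Per replicate, each species' abundance is multiplied by an independent
    log-normal factor of the given coefficient of variation (mean 1), the
    whole scan is shifted by a rounded Gaussian number of grid steps
    (``jitter_sigma`` in steps), and fresh baseline/noise is added.  The
    truth dict records the species table, the applied integer shifts and the
    abundance factors.
    """
    if n_replicates < 1:
        raise ValueError("at least one replicate is required")
    tables = _species_tables(species, tables)
    rng = np.random.default_rng(seed)
    sigma_log = np.sqrt(np.log1p(intensity_cv**2))
    n = grid.size
    matrix = np.empty((n, n_replicates))
    shifts = np.zeros(n_replicates, dtype=int)
    factors = np.ones((n_replicates, len(species)))
    truth_rows = []
    base_curves = []
    for sp in species:
        curve, ml_mz, ml_index = _render_species(sp, grid, rp, tables[sp.residue],
                                                 sp.abundance)
        base_curves.append(curve)
        truth_rows.append((sp.monoisotopic_mass, sp.charge, sp.abundance, sp.residue,
                           ml_mz, ml_index))
    for j in range(n_replicates):
        if intensity_cv > 0:
            factors[j] = rng.lognormal(-0.5 * sigma_log**2, sigma_log, len(species))
        signal = np.zeros(n)
        for curve, f in zip(base_curves, factors[j]):
            signal += f * curve
        if jitter_sigma > 0:
            shifts[j] = int(round(rng.normal(0.0, jitter_sigma)))
        if shifts[j] != 0:
            shifted = np.zeros(n)
            if shifts[j] > 0:
                shifted[shifts[j]:] = signal[:n - shifts[j]]
            else:
                shifted[:shifts[j]] = signal[-shifts[j]:]
            signal = shifted
        if baseline is not None:
            amp, decay = baseline
            signal = signal + amp * np.exp(-(grid - grid[0]) / decay)
        if noise_sigma > 0:
            signal = signal + rng.normal(0.0, noise_sigma, n)
        matrix[:, j] = signal
    truth = {
        "species": pd.DataFrame(truth_rows, columns=["monoisotopic_mass", "charge",
                                                     "abundance", "residue",
                                                     "most_likely_mz",
                                                     "most_likely_index"]),
        "shifts": shifts,
        "abundance_factors": factors,
    }
    return ReplicateSet(grid.copy(), matrix), truth


def score_peak_list(truth: pd.DataFrame, entries: list[PeakListEntry],
                    mass_tolerance: float = 0.01, *, relative: bool = True,
                    require_charge: bool = True) -> dict:
    """Recovery/FDR of a peak list against a truth table.

    A truth species is recovered if some entry matches its monoisotopic mass
    within the tolerance (relative fraction by default, absolute Da
    otherwise), and its charge when ``require_charge``.  FDR is the fraction
    of entries matching no truth species.
    """
    matched = np.zeros(len(truth), dtype=bool)
    false_entries = 0
    for e in entries:
        hit = False
        for i, row in truth.reset_index(drop=True).iterrows():
            tol = mass_tolerance * row.monoisotopic_mass if relative else mass_tolerance
            if abs(e.monoisotopic_mass - row.monoisotopic_mass) <= tol and \
                    (not require_charge or e.charge == row.charge):
                matched[i] = True
                hit = True
        if not hit:
            false_entries += 1
    n_entries = len(entries)
    return {
        "recovered": int(matched.sum()),
        "n_truth": len(truth),
        "sensitivity": float(matched.mean()) if len(truth) else float("nan"),
        "fdr": false_entries / n_entries if n_entries else float("nan"),
        "n_entries": n_entries,
    }
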