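"""Spectrum reading/writing, the replicate matrix, and peak-list output.

A profile-mode spectrum is a pair of equal-length vectors (m/z strictly
increasing, intensity).  When M replicate spectra are available (scans of one
spot, or correlated spectra of many samples) they are resampled onto a common
m/z grid into an N x M intensity matrix whose row sums form the
*representative spectrum* — the signal the rest of the pipeline operates on.
No normalization is applied, so each replicate contributes in proportion to
its total ion current.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "ReplicateSet",
    "PeakListEntry",
    "read_spectrum",
    "read_ascii_spectrum",
    "read_mzxml_spectrum",
    "write_ascii_spectrum",
    "build_replicate_set",
    "qc_filter",
    "write_peak_list",
]


@dataclass
class Spectrum:
    """A profile-mode mass spectrum: m/z (Da, strictly increasing) and intensity."""

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D vectors of equal length")
        if self.mz.size < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be strictly increasing")

    def __len__(self) -> int:
        return self.mz.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy())


@dataclass
class ReplicateSet:
    """Replicates on a common grid; representative = row sums of the matrix."""

    grid: np.ndarray
    matrix: np.ndarray  # shape (N, M)
    representative: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.grid.size:
            raise ValueError("matrix must be N x M with N = grid length")
        if self.matrix.shape[1] < 1:
            raise ValueError("at least one replicate is required")
        self.representative = self.matrix.sum(axis=1)

    @property
    def n_replicates(self) -> int:
        return self.matrix.shape[1]

    def recompute_representative(self, lo: int = 0, hi: int | None = None) -> None:
        """Restore the row-sum identity after a matrix edit (optionally on a slice)."""
        hi = self.grid.size if hi is None else hi
        self.representative[lo:hi] = self.matrix[lo:hi].sum(axis=1)

    def representative_spectrum(self) -> Spectrum:
        return Spectrum(self.grid.copy(), self.representative.copy())


@dataclass
class PeakListEntry:
    """One extracted biomolecule: monoisotopic mass, charge, summed ID intensity."""

    monoisotopic_mass: float
    charge: int
    intensity: float
    residue_used: str
    score: float


def _repair_mz_order(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z and average duplicate m/z values, warning if a repair occurred."""
    order = np.argsort(mz, kind="stable")
    if not np.array_equal(order, np.arange(mz.size)):
        warnings.warn("m/z values were not sorted; repairing", stacklevel=3)
    mz, intensity = mz[order], intensity[order]
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if uniq.size != mz.size:
        warnings.warn("duplicate m/z values were averaged", stacklevel=3)
        summed = np.bincount(inverse, weights=intensity)
        intensity = summed / counts
        mz = uniq
    return mz, intensity


def read_ascii_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column ASCII spectrum (whitespace, comma or semicolon separated)."""
    mz, intensity = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(";", " ").replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"cannot parse spectrum line {raw!r} in {path}")
        try:
            mz.append(float(parts[0]))
            intensity.append(float(parts[1]))
        except ValueError:
            # tolerate a single header line of labels
            if not mz:
                continue
            raise
    if len(mz) < 2:
        raise ValueError(f"{path}: fewer than two data points; not a profile spectrum")
    return Spectrum(*_repair_mz_order(np.asarray(mz), np.asarray(intensity)))


def read_mzxml_spectrum(path: str | Path) -> Spectrum:
    """Read an mzXML file; multiple profile scans are summed like replicates."""
    from pyteomics import mzxml

    scans = []
    with mzxml.read(str(path)) as reader:
        for scan in reader:
            mz = np.asarray(scan["m/z array"], dtype=float)
            intensity = np.asarray(scan["intensity array"], dtype=float)
            if scan.get("centroided") in (True, "1", "true"):
                raise ValueError(f"{path}: centroided scan; profile mode is required")
            if mz.size < 2:
                raise ValueError(f"{path}: scan with fewer than two points")
            scans.append(Spectrum(*_repair_mz_order(mz, intensity)))
    if not scans:
        raise ValueError(f"{path}: no scans found")
    if len(scans) == 1:
        return scans[0]
    return build_replicate_set(scans).representative_spectrum()


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum:
    """Read a spectrum from ASCII or mzXML (auto-detected from the suffix)."""
    path = Path(path)
    if format is None:
        format = "mzxml" if path.suffix.lower() == ".mzxml" else "ascii"
    if format == "ascii":
        return read_ascii_spectrum(path)
    if format == "mzxml":
        return read_mzxml_spectrum(path)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_ascii_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    np.savetxt(Path(path), np.column_stack([spectrum.mz, spectrum.intensity]),
               fmt="%.6f\t%.8g")


def build_replicate_set(spectra: list[Spectrum]) -> ReplicateSet:
    """Resample replicates onto a common grid and sum them row-wise.

    The grid is the first spectrum's m/z vector clipped to the intersection of
    all m/z ranges; the other replicates are linearly resampled onto it.
    """
    if not spectra:
        raise ValueError("at least one spectrum is required")
    lo = max(s.mz[0] for s in spectra)
    hi = min(s.mz[-1] for s in spectra)
    if lo >= hi:
        raise ValueError("replicate m/z ranges do not overlap")
    ref = spectra[0]
    keep = (ref.mz >= lo) & (ref.mz <= hi)
    grid = ref.mz[keep]
    if grid.size < 2:
        raise ValueError("common m/z range contains fewer than two grid points")
    matrix = np.empty((grid.size, len(spectra)))
    matrix[:, 0] = ref.intensity[keep]
    for j, s in enumerate(spectra[1:], start=1):
        matrix[:, j] = np.interp(grid, s.mz, s.intensity)
    return ReplicateSet(grid, matrix)


def qc_filter(rs: ReplicateSet, min_corr: float = 0.4, *, iterate: bool = False) -> ReplicateSet:
    """Drop replicates poorly correlated (Pearson < ``min_corr``) with the representative.

    The representative is recomputed once after dropping (or until stable with
    ``iterate``).  Raises if every replicate would be dropped.
    """
    matrix = rs.matrix
    while True:
        rep = matrix.sum(axis=1)
        corrs = np.array([_pearson(matrix[:, j], rep) for j in range(matrix.shape[1])])
        keep = corrs >= min_corr
        if keep.all():
            return ReplicateSet(rs.grid, matrix)
        if not keep.any():
            raise ValueError("quality control dropped every replicate")
        matrix = matrix[:, keep]
        if not iterate:
            return ReplicateSet(rs.grid, matrix)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def write_peak_list(entries: list[PeakListEntry], path: str | Path) -> None:
    """Write a tab-separated peak list (mass, charge, intensity, residue, score)."""
    import pandas as pd

    frame = pd.DataFrame(
        [(e.monoisotopic_mass, e.charge, e.intensity, e.residue_used, e.score)
         for e in entries],
        columns=["monoisotopic_mass", "charge", "intensity", "residue", "score"],
    )
    frame.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
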