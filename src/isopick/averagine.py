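"""Reference-residue models and precomputed theoretical isotopic distributions.

A theoretical isotopic distribution (TID) at an arbitrary monoisotopic mass is
approximated by the ID of an artificial homopolymer of a reference residue
with (about) that mass.  Because computing an ID per query is expensive, IDs
of all n-residue artificial sequences up to a mass limit are computed once,
stored, and the TID at any intermediate mass is obtained by position-wise
linear interpolation between the two bracketing rows.

Three built-in reference residues are provided:

* ``ave`` — the classical Averagine average residue
  (C4.9384 H7.7583 N1.3577 O1.4773 S0.0417, 111.054 Da monoisotopic);
* ``leu`` — Leucine (C6H11NO, 113.084 Da), the most frequent real residue,
  sharing its formula with Isoleucine;
* ``avu`` — an updated average residue refit on a more recent proteome
  composition (C4.949 H7.833 O1.473 N1.361 S0.038, 111.116 Da monoisotopic).

The most-likely model maps a monoisotopic mass to the index of the most
abundant isotope position (``k*``) and, inversely, a most-likely-peak mass
back to the monoisotopic mass via piecewise-linear regression through the
table rows.  This inverse is what makes monoisotoping possible at low
resolution, where only the envelope apex is observable.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .isotopes import (
    DEFAULT_ISOTOPE_TABLE,
    ISOTOPE_SPACING,
    IsotopicDistribution,
    combine_formulas,
    formula_distribution,
    monoisotopic_mass,
    scale_formula,
)

__all__ = [
    "WATER",
    "ReferenceResidue",
    "BUILTIN_RESIDUES",
    "get_residue",
    "TIDTable",
    "MostLikelyModel",
    "build_tid_table",
    "tid_at_mass",
    "fit_most_likely_model",
    "save_tid_table",
    "load_tid_table",
    "default_cache_dir",
]

_CACHE_VERSION = 1

#: Terminal group added to each artificial sequence (peptide convention).
WATER: dict[str, float] = {"H": 2.0, "O": 1.0}


@dataclass(frozen=True)
class ReferenceResidue:
    """An amino-acid (or average-residue) building block for TIDs."""

    name: str
    formula: dict[str, float]

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)


BUILTIN_RESIDUES: dict[str, ReferenceResidue] = {
    "ave": ReferenceResidue("ave", {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}),
    "leu": ReferenceResidue("leu", {"C": 6.0, "H": 11.0, "N": 1.0, "O": 1.0}),
    "avu": ReferenceResidue("avu", {"C": 4.949, "H": 7.833, "O": 1.473, "N": 1.361, "S": 0.038}),
}


def get_residue(name: str) -> ReferenceResidue:
    try:
        return BUILTIN_RESIDUES[name.lower()]
    except KeyError:
        raise KeyError(f"unknown reference residue {name!r}; "
                       f"choose from {sorted(BUILTIN_RESIDUES)}") from None


@dataclass
class TIDTable:
    """Precomputed IDs of n-residue artificial sequences, n = 1..N.

    ``masses[n-1]`` is the monoisotopic mass of the n-residue sequence
    (fractional counts used directly, terminal water included when
    ``include_water``); ``abundances[n-1]`` its ID truncated to at most 30
    positions (zero-padded).
    """

    residue: ReferenceResidue
    mass_limit: float
    masses: np.ndarray
    abundances: np.ndarray
    include_water: bool = True
    position_spacing: float = ISOTOPE_SPACING

    @property
    def n_rows(self) -> int:
        return self.masses.size

    def row(self, n: int) -> IsotopicDistribution:
        """ID of the n-residue sequence (1-based), trailing zeros stripped."""
        if not 1 <= n <= self.n_rows:
            raise IndexError(f"row {n} outside 1..{self.n_rows}")
        a = self.abundances[n - 1]
        keep = np.nonzero(a)[0]
        return IsotopicDistribution(float(self.masses[n - 1]), a[: keep[-1] + 1].copy(),
                                    self.position_spacing)


@dataclass
class MostLikelyModel:
    """Monoisotopic <-> most-likely-peak mass mapping for one residue model.

    ``k_star`` (index of the most abundant isotope position) is made
    non-decreasing across the table; the inverse map is a piecewise-linear
    interpolation through the (most-likely mass, monoisotopic mass) pairs of
    all rows, hence exact at the knots.
    """

    residue_name: str
    mono_masses: np.ndarray
    k_star_rows: np.ndarray
    position_spacing: float = ISOTOPE_SPACING
    ml_masses: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ml_masses = self.mono_masses + self.k_star_rows * self.position_spacing

    def k_star(self, m0: float) -> int:
        """Most-likely position index at monoisotopic mass ``m0`` (nearest row)."""
        idx = int(np.clip(np.searchsorted(self.mono_masses, m0), 0, self.mono_masses.size - 1))
        if idx > 0 and abs(self.mono_masses[idx - 1] - m0) < abs(self.mono_masses[idx] - m0):
            idx -= 1
        return int(self.k_star_rows[idx])

    def most_likely_mass(self, m0: float) -> float:
        """Neutral mass of the most-likely peak for monoisotopic mass ``m0``."""
        return float(np.interp(m0, self.mono_masses, self.ml_masses))

    def predict_monoisotopic(self, ml_mass: float) -> float:
        """Monoisotopic mass from an observed most-likely-peak mass."""
        return float(np.interp(ml_mass, self.ml_masses, self.mono_masses))


def _sequence_formula(residue: ReferenceResidue, n: int, include_water: bool) -> dict[str, float]:
    f = scale_formula(residue.formula, float(n))
    return combine_formulas(f, WATER) if include_water else f


def build_tid_table(residue: ReferenceResidue,
                    mass_limit: float = 20000.0,
                    *,
                    include_water: bool = True,
                    isotope_table: dict | None = None,
                    max_positions: int = 30,
                    cache: bool = False,
                    cache_dir: str | Path | None = None) -> TIDTable:
    """Compute (or reload from cache) the TID table of one reference residue.

    Rows cover n = 1..N with N = ceil(mass_limit / residue mass), so the last
    row mass reaches the limit to within one residue mass.  With ``cache``
    enabled the table is serialized to ``cache_dir`` (default
    ``~/.cache/isopick`` or ``$ISOPICK_CACHE``) and reloaded on subsequent
    calls; the cache key includes the isotope table, so changing it
    regenerates the file.
    """
    isotope_table = DEFAULT_ISOTOPE_TABLE if isotope_table is None else isotope_table
    res_mass = monoisotopic_mass(residue.formula, isotope_table)
    if mass_limit <= res_mass:
        raise ValueError(f"mass_limit {mass_limit} must exceed the residue mass {res_mass:.3f}")

    if cache:
        path = _cache_path(residue, mass_limit, include_water, isotope_table, cache_dir)
        if path.exists():
            try:
                return load_tid_table(path)
            except Exception:
                path.unlink(missing_ok=True)

    n_rows = int(np.ceil(mass_limit / res_mass))
    masses = np.empty(n_rows)
    abundances = np.zeros((n_rows, max_positions))
    water_mass = monoisotopic_mass(WATER, isotope_table) if include_water else 0.0
    for n in range(1, n_rows + 1):
        formula = _sequence_formula(residue, n, include_water)
        dist = formula_distribution(formula, isotope_table, max_positions=max_positions)
        masses[n - 1] = n * res_mass + water_mass
        abundances[n - 1, : dist.abundances.size] = dist.abundances
    table = TIDTable(residue, mass_limit, masses, abundances, include_water)

    if cache:
        save_tid_table(table, path)
    return table


def tid_at_mass(table: TIDTable, m0: float) -> IsotopicDistribution:
    """TID at monoisotopic mass ``m0`` by row-wise linear interpolation.

    Exact at stored row masses; raises for ``m0`` outside the table range.
    """
    masses = table.masses
    if not masses[0] <= m0 <= masses[-1]:
        raise ValueError(f"mass {m0:.3f} outside table range "
                         f"[{masses[0]:.3f}, {masses[-1]:.3f}]")
    hi = int(np.searchsorted(masses, m0))
    if hi == 0 or masses[hi - 1] == m0:
        row = hi if hi == 0 else hi - 1
        a = table.abundances[row].copy()
    else:
        lo = hi - 1
        t = (m0 - masses[lo]) / (masses[hi] - masses[lo])
        a = (1.0 - t) * table.abundances[lo] + t * table.abundances[hi]
    keep = np.nonzero(a)[0]
    return IsotopicDistribution(m0, a[: keep[-1] + 1], table.position_spacing)


def fit_most_likely_model(table: TIDTable) -> MostLikelyModel:
    """Fit the monoisotopic <-> most-likely mapping on all table rows."""
    k = np.argmax(table.abundances, axis=1)
    k = np.maximum.accumulate(k)  # physically non-decreasing with mass
    return MostLikelyModel(table.residue.name, table.masses.copy(), k.astype(int),
                           table.position_spacing)


def default_cache_dir() -> Path:
    env = os.environ.get("ISOPICK_CACHE")
    if env:
        return Path(env)
    return Path.home() / ".cache" / "isopick"


def _cache_path(residue: ReferenceResidue, mass_limit: float, include_water: bool,
                isotope_table: dict, cache_dir: str | Path | None) -> Path:
    base = Path(cache_dir) if cache_dir is not None else default_cache_dir()
    key = json.dumps({"formula": residue.formula, "limit": mass_limit,
                      "water": include_water, "isotopes": isotope_table,
                      "version": _CACHE_VERSION}, sort_keys=True)
    digest = hashlib.sha1(key.encode()).hexdigest()[:12]
    return base / f"tid_{residue.name}_{int(mass_limit)}_{digest}.npz"


def save_tid_table(table: TIDTable, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"version": _CACHE_VERSION, "name": table.residue.name,
                       "formula": table.residue.formula, "limit": table.mass_limit,
                       "water": table.include_water, "spacing": table.position_spacing})
    np.savez(path, masses=table.masses, abundances=table.abundances,
             meta=np.array(meta))


def load_tid_table(path: str | Path) -> TIDTable:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if meta.get("version") != _CACHE_VERSION:
            raise ValueError("incompatible table cache version")
        residue = ReferenceResidue(meta["name"], meta["formula"])
        return TIDTable(residue, meta["limit"], data["masses"].copy(),
                        data["abundances"].copy(), meta["water"], meta["spacing"])
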