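"""Isotopic distributions of molecules from elemental isotope abundances.

The isotopic distribution (ID) of a molecule is computed with an iterative
matrix approach: the molecule is assembled atom by atom, and at each step the
joint distribution of the current molecule and the next atom is formed as an
outer product whose anti-diagonals (configurations sharing the same nominal
mass shift, i.e. the same neutron excess) are summed into the new abundance
vector.  Grouping is by integer neutron count; fine isotopic structure
(e.g. separating a ``13C`` from a ``15N`` substitution at the same nominal
shift) is deliberately not resolved.

Molecular formulas may carry fractional element counts, as used by
Averagine-type "average residue" models.  Monoisotopic masses are linear in
the counts and therefore accept fractional counts directly; distribution
computation first integerizes the formula (see :func:`integerize_formula`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ISOTOPE_SPACING",
    "PROTON_MASS",
    "FWHM_OVER_SIGMA",
    "DEFAULT_ISOTOPE_TABLE",
    "UnknownElementError",
    "IsotopicDistribution",
    "parse_formula",
    "scale_formula",
    "combine_formulas",
    "load_isotope_table",
    "validate_isotope_table",
    "convolve",
    "monoisotopic_mass",
    "integerize_formula",
    "formula_distribution",
]

#: Average mass spacing between successive isotope positions of a peptide,
#: dominated by the 13C-12C difference (Da).
ISOTOPE_SPACING = 1.00235

#: Mass of a proton (Da); positive ions are modelled as proton adducts,
#: observed m/z = (M0 + Z * PROTON_MASS) / Z.
PROTON_MASS = 1.00727646688

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian peak (~2.35482).
FWHM_OVER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Built-in isotope table (IUPAC-style masses in Da and natural abundances as
#: fractions), per element ordered by increasing isotope mass.
DEFAULT_ISOTOPE_TABLE: dict[str, list[tuple[float, float]]] = {
    "H": [(1.0078250319, 0.999885), (2.0141017780, 0.000115)],
    "C": [(12.0000000000, 0.9893), (13.0033548378, 0.0107)],
    "N": [(14.0030740052, 0.99632), (15.0001088984, 0.00368)],
    "O": [(15.9949146221, 0.99757), (16.9991315000, 0.00038), (17.9991604000, 0.00205)],
    "S": [(31.9720706900, 0.9493), (32.9714585000, 0.0076), (33.9678668300, 0.0429), (35.9670808800, 0.0002)],
}


class UnknownElementError(KeyError):
    """A formula references an element absent from the isotope table."""


@dataclass
class IsotopicDistribution:
    """Relative abundances at successive isotope positions.

    Parameters
    ----------
    monoisotopic_mass
        Neutral mass (Da) of the all-lightest-isotopes species, anchoring
        position 0.
    abundances
        Relative probability of each isotope position, starting at the
        monoisotopic one.
    position_spacing
        Mass difference between consecutive positions (Da).
    """

    monoisotopic_mass: float
    abundances: np.ndarray
    position_spacing: float = ISOTOPE_SPACING

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 1 or self.abundances.size == 0:
            raise ValueError("abundances must be a non-empty 1-D vector")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")

    @property
    def most_likely_index(self) -> int:
        """Index of the most abundant isotope position."""
        return int(np.argmax(self.abundances))

    @property
    def most_likely_mass(self) -> float:
        """Neutral mass (Da) of the most abundant isotopologue."""
        return self.monoisotopic_mass + self.most_likely_index * self.position_spacing

    def position_masses(self) -> np.ndarray:
        """Neutral masses (Da) of all stored isotope positions."""
        return self.monoisotopic_mass + np.arange(self.abundances.size) * self.position_spacing


def parse_formula(text: str) -> dict[str, float]:
    """Parse a Hill-style formula such as ``"C6H11N1O1S0"``.

    Counts may be fractional (``"C4.9384H7.7583..."``); an omitted count
    means 1.  Zero counts are kept out of the returned dict.
    """
    import re

    tokens = re.findall(r"([A-Z][a-z]?)(\d*\.?\d*)", text)
    if not tokens or "".join(sym + cnt for sym, cnt in tokens) != text:
        raise ValueError(f"cannot parse formula {text!r}")
    formula: dict[str, float] = {}
    for sym, cnt in tokens:
        value = float(cnt) if cnt else 1.0
        if value != 0.0:
            formula[sym] = formula.get(sym, 0.0) + value
    if not formula:
        raise ValueError(f"formula {text!r} has no atoms")
    return formula


def scale_formula(formula: dict[str, float], factor: float) -> dict[str, float]:
    """Multiply every element count by ``factor``."""
    return {el: cnt * factor for el, cnt in formula.items()}


def combine_formulas(*formulas: dict[str, float]) -> dict[str, float]:
    """Element-wise sum of formulas."""
    out: dict[str, float] = {}
    for f in formulas:
        for el, cnt in f.items():
            out[el] = out.get(el, 0.0) + cnt
    return {el: cnt for el, cnt in out.items() if cnt != 0.0}


def validate_isotope_table(table: dict[str, list[tuple[float, float]]]) -> None:
    """Check abundance normalization and mass ordering per element."""
    for el, rows in table.items():
        masses = [m for m, _ in rows]
        abundances = [a for _, a in rows]
        if any(a < 0 or a > 1 for a in abundances):
            raise ValueError(f"element {el}: abundances must lie in [0, 1]")
        if abs(sum(abundances) - 1.0) > 1e-9:
            raise ValueError(f"element {el}: abundances sum to {sum(abundances)}, not 1")
        if any(m2 <= m1 for m1, m2 in zip(masses, masses[1:])):
            raise ValueError(f"element {el}: isotope masses must be strictly increasing")


def load_isotope_table(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    """Read an isotope table from a plain-text file.

    One line per isotope: ``element mass abundance`` (whitespace separated;
    ``#`` starts a comment).  The result is validated.
    """
    table: dict[str, list[tuple[float, float]]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed isotope table line: {raw!r}")
        el, mass, abundance = parts[0], float(parts[1]), float(parts[2])
        table.setdefault(el, []).append((mass, abundance))
    for el in table:
        table[el].sort(key=lambda t: t[0])
    validate_isotope_table(table)
    return table


def convolve(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Convolve two abundance vectors via the joint-distribution matrix.

    The outer product of ``a`` and ``b`` is the joint distribution of the two
    partial molecules; summing its anti-diagonals merges isotopologue
    configurations with the same nominal mass shift.  The result has length
    ``len(a) + len(b) - 1`` and total probability ``sum(a) * sum(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("abundance vectors must be non-empty")
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("abundance vectors must be non-negative")
    joint = np.outer(a, b)
    shifts = np.add.outer(np.arange(a.size), np.arange(b.size))
    return np.bincount(shifts.ravel(), weights=joint.ravel(), minlength=a.size + b.size - 1)


def _element_vector(el: str, table: dict[str, list[tuple[float, float]]]) -> np.ndarray:
    """Abundance vector of a single atom, indexed by nominal mass shift."""
    if el not in table:
        raise UnknownElementError(el)
    rows = table[el]
    base = rows[0][0]
    shifts = [int(round(m - base)) for m, _ in rows]
    vec = np.zeros(max(shifts) + 1)
    for s, (_, abundance) in zip(shifts, rows):
        vec[s] += abundance
    return vec


def _element_power(el: str, count: int, table: dict[str, list[tuple[float, float]]],
                   max_positions: int) -> np.ndarray:
    """Distribution of ``count`` atoms of one element, by squaring."""
    single = _element_vector(el, table)
    result = np.array([1.0])
    power = single
    n = count
    while n > 0:
        if n & 1:
            result = convolve(result, power)[:max_positions]
        n >>= 1
        if n:
            power = convolve(power, power)[:max_positions]
    return result


def monoisotopic_mass(formula: dict[str, float],
                      table: dict[str, list[tuple[float, float]]] | None = None) -> float:
    """Monoisotopic mass (Da): sum of count x lightest-isotope mass.

    Linear in the counts, so fractional (Averagine-type) counts are allowed.
    """
    table = DEFAULT_ISOTOPE_TABLE if table is None else table
    if not formula or all(c == 0 for c in formula.values()):
        raise ValueError("formula must contain at least one atom")
    if any(c < 0 for c in formula.values()):
        raise ValueError("element counts must be non-negative")
    total = 0.0
    for el, count in formula.items():
        if el not in table:
            raise UnknownElementError(el)
        total += count * table[el][0][0]
    return total


def integerize_formula(formula: dict[str, float],
                       table: dict[str, list[tuple[float, float]]] | None = None) -> dict[str, int]:
    """Resolve fractional element counts to an integer formula.

    Every count is rounded to the nearest integer; the hydrogen count is then
    adjusted so the integer formula's monoisotopic mass matches the fractional
    formula's mass to within half a hydrogen mass (the standard fractional-
    Averagine practice).  Already-integer formulas pass through unchanged.
    """
    table = DEFAULT_ISOTOPE_TABLE if table is None else table
    target = monoisotopic_mass(formula, table)
    rounded = {el: int(round(cnt)) for el, cnt in formula.items()}
    rounded = {el: cnt for el, cnt in rounded.items() if cnt > 0}
    if not rounded:
        raise ValueError("formula integerizes to zero atoms")
    h_mass = table["H"][0][0] if "H" in table else 1.0078250319
    current = monoisotopic_mass(rounded, table)
    delta_h = int(round((target - current) / h_mass))
    if delta_h:
        rounded["H"] = rounded.get("H", 0) + delta_h
        if rounded["H"] < 0:
            rounded["H"] = 0
        elif rounded["H"] == 0:
            del rounded["H"]
    return rounded


def formula_distribution(formula: dict[str, float],
                         table: dict[str, list[tuple[float, float]]] | None = None,
                         max_positions: int = 30) -> IsotopicDistribution:
    """Isotopic distribution of a molecule, truncated to ``max_positions``.

    Fractional counts are integerized first (:func:`integerize_formula`); the
    reported monoisotopic mass, however, uses the fractional counts directly.
    """
    table = DEFAULT_ISOTOPE_TABLE if table is None else table
    if max_positions < 1:
        raise ValueError("max_positions must be >= 1")
    mono = monoisotopic_mass(formula, table)
    counts = integerize_formula(formula, table)
    dist = np.array([1.0])
    for el, count in counts.items():
        dist = convolve(dist, _element_power(el, count, table, max_positions))[:max_positions]
    return IsotopicDistribution(monoisotopic_mass=mono, abundances=dist)
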