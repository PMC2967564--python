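"""Independent brute-force oracles used only by the test suite."""

from itertools import product
from math import factorial, prod

import numpy as np


def convolve_by_enumeration(a, b):
    """Joint enumeration over every index pairing (i, j)."""
    out = np.zeros(len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


def _compositions(n, k):
    """All k-tuples of non-negative integers summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def _multinomial(n, counts):
    return factorial(n) // prod(factorial(c) for c in counts)


def isotopologue_distribution(formula, table):
    """Exhaustive enumeration of isotopologues grouped by nominal mass shift.

    For each element every assignment of isotope counts to its atoms is
    enumerated (as count multisets with multinomial multiplicities); element
    results are combined by exhausting all cross-element pairings.  Entirely
    independent of the convolution implementation.
    """
    per_element = []
    for el, n in formula.items():
        isotopes = table[el]
        base_mass = isotopes[0][0]
        shifts = [int(round(m - base_mass)) for m, _ in isotopes]
        outcomes = {}
        for counts in _compositions(n, len(isotopes)):
            p = _multinomial(n, counts) * prod(
                a ** c for (_, a), c in zip(isotopes, counts))
            s = sum(c * sh for c, sh in zip(counts, shifts))
            outcomes[s] = outcomes.get(s, 0.0) + p
        per_element.append(outcomes)

    acc = {0: 1.0}
    for outcomes in per_element:
        nxt = {}
        for s0, p0 in acc.items():
            for s, p in outcomes.items():
                nxt[s0 + s] = nxt.get(s0 + s, 0.0) + p0 * p
        acc = nxt
    out = np.zeros(max(acc) + 1)
    for s, p in acc.items():
        out[s] = p
    return out


def all_chnos_formulas(max_atoms):
    """Every CHNOS composition with 1..max_atoms atoms in total."""
    elements = ("C", "H", "N", "O", "S")
    for counts in product(range(max_atoms + 1), repeat=5):
        total = sum(counts)
        if 1 <= total <= max_atoms:
            yield {el: c for el, c in zip(elements, counts) if c > 0}
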