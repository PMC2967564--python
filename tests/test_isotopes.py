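import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import convolve_by_enumeration, isotopologue_distribution
from isopick.isotopes import (DEFAULT_ISOTOPE_TABLE, FWHM_OVER_SIGMA,
                              UnknownElementError, convolve,
                              formula_distribution, integerize_formula,
                              load_isotope_table, monoisotopic_mass,
                              parse_formula, scale_formula,
                              validate_isotope_table)

AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}


class TestConvolve:
    def test_two_isotope_worked_example(self):
        # building a 2-atom molecule from atoms with 99%/1% isotopes
        result = convolve([0.99, 0.01], [0.99, 0.01])
        assert np.allclose(result, [0.9801, 0.0198, 0.0001], atol=1e-12)

    def test_identity_element(self):
        v = np.array([0.6, 0.3, 0.1])
        assert np.allclose(convolve(v, [1.0]), v, atol=0)

    @pytest.mark.parametrize("a,b", [
        ([0.5, 0.3, 0.2], [0.9, 0.1]),
        ([0.7, 0.2, 0.1], [0.5, 0.25, 0.25]),
        ([1.0], [0.4, 0.6]),
    ])
    def test_matches_pairwise_enumeration(self, a, b):
        assert np.allclose(convolve(a, b), convolve_by_enumeration(a, b), atol=1e-14)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            convolve([], [0.5, 0.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6),
           st.lists(st.floats(0, 1), min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_total_probability_conserved(self, a, b):
        assert convolve(a, b).sum() == pytest.approx(np.sum(a) * np.sum(b), abs=1e-12)

    @given(st.lists(st.floats(0.01, 1), min_size=1, max_size=5),
           st.lists(st.floats(0.01, 1), min_size=1, max_size=5),
           st.lists(st.floats(0.01, 1), min_size=1, max_size=5))
    @settings(derandomize=True, max_examples=50)
    def test_commutative_and_associative(self, a, b, c):
        assert np.allclose(convolve(a, b), convolve(b, a), atol=1e-12)
        assert np.allclose(convolve(convolve(a, b), c),
                           convolve(a, convolve(b, c)), atol=1e-12)


class TestFormulaDistribution:
    def test_water_matches_enumeration(self):
        dist = formula_distribution({"H": 2, "O": 1})
        oracle = isotopologue_distribution({"H": 2, "O": 1}, DEFAULT_ISOTOPE_TABLE)
        assert np.allclose(dist.abundances, oracle[: dist.abundances.size], atol=1e-12)

    def test_single_atom_is_table_row(self):
        dist = formula_distribution({"H": 1})
        expected = [a for _, a in DEFAULT_ISOTOPE_TABLE["H"]]
        assert np.allclose(dist.abundances, expected, atol=0)

    def test_low_mass_peptide_monoisotopic_dominates(self):
        dist = formula_distribution({"C": 50, "H": 100, "N": 20, "O": 20})
        assert dist.most_likely_index == 0

    def test_unknown_element(self):
        with pytest.raises(UnknownElementError):
            formula_distribution({"Xx": 1})

    def test_truncation_discards_only_negligible_positions(self):
        # the 30-position cut loses < 1e-6 per position at 10 kDa and stays
        # below 1e-4 per position even at the 20 kDa table limit
        for target, bound in ((10000.0, 1e-6), (20000.0, 1e-4)):
            scale = target / monoisotopic_mass(AVERAGINE)
            full = formula_distribution(scale_formula(AVERAGINE, scale),
                                        max_positions=60)
            assert np.all(full.abundances[30:] < bound)


class TestMonoisotopicMass:
    def test_leucine_residue(self):
        assert round(monoisotopic_mass(parse_formula("C6H11N1O1S0")), 3) == 113.084

    def test_averagine_residue_full_precision(self):
        assert round(monoisotopic_mass(AVERAGINE), 3) == 111.054

    def test_linearity_in_counts(self):
        f = {"C": 2.5, "H": 3.25}
        assert monoisotopic_mass(scale_formula(f, 2.0)) == pytest.approx(
            2.0 * monoisotopic_mass(f), abs=1e-12)

    def test_unknown_element(self):
        with pytest.raises(UnknownElementError):
            monoisotopic_mass({"Zz": 1.0})


class TestIntegerize:
    @pytest.mark.parametrize("target_mass", [800.0, 2000.0, 5000.0])
    def test_hydrogen_adjustment_bounds_error(self, target_mass):
        scale = target_mass / monoisotopic_mass(AVERAGINE)
        formula = scale_formula(AVERAGINE, scale)
        counts = integerize_formula(formula)
        h_mass = DEFAULT_ISOTOPE_TABLE["H"][0][0]
        err = abs(monoisotopic_mass(counts) - monoisotopic_mass(formula))
        assert err <= h_mass / 2 + 1e-9

    def test_integer_formula_unchanged(self):
        assert integerize_formula({"C": 6, "H": 11, "N": 1, "O": 1}) == \
            {"C": 6, "H": 11, "N": 1, "O": 1}


class TestIsotopeTableIO:
    def test_parse_formula_fractional(self):
        assert parse_formula("C4.9384H7.7583N1.3577O1.4773S0.0417") == AVERAGINE

    def test_validate_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            validate_isotope_table({"X": [(1.0, 0.6), (2.0, 0.3)]})

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "isotopes.txt"
        lines = ["# custom table"]
        for el, rows in DEFAULT_ISOTOPE_TABLE.items():
            lines += [f"{el} {m:.10f} {a:.6f}" for m, a in rows]
        path.write_text("\n".join(lines))
        table = load_isotope_table(path)
        assert set(table) == set(DEFAULT_ISOTOPE_TABLE)
        assert table["C"][1][0] == pytest.approx(13.0033548378, abs=1e-9)
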