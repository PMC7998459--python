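"""Composition and mass arithmetic against published values and oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclomine import chem
from cyclomine.chem import (
    Adduct,
    ElementalComposition,
    InvalidSequenceError,
    ModificationError,
    ModificationState,
    Peptide,
    adduct_mz,
    apply_modifications,
    composition_of,
    immonium_mz,
    isotopic_distribution,
    monoisotopic_mass,
    peptide_mass,
    ppm_delta,
)

AA = sorted(chem.RESIDUE_TABLE)


def brute_force_mass(seq: str, topology: str) -> float:
    """Independent oracle: expand the peptide into individual atoms and sum."""
    atoms = []
    for aa in seq:
        for el, n in chem.RESIDUE_TABLE[aa].counts.items():
            atoms.extend([el] * n)
    if topology == "linear":
        atoms.extend(["H", "H", "O"])
    return math.fsum(chem.ELEMENT_MASS[el] for el in atoms)


class TestElementalComposition:
    def test_addition_is_elementwise(self):
        a = ElementalComposition({"C": 2, "H": 3})
        b = ElementalComposition({"C": 1, "O": 2})
        assert (a + b).counts == {"C": 3, "H": 3, "O": 2}

    def test_subtraction_never_goes_negative(self):
        a = ElementalComposition({"C": 1})
        with pytest.raises(ValueError):
            a - ElementalComposition({"C": 2})

    def test_formula_roundtrip(self):
        comp = composition_of("TFLPPLFVPP", "cyclic")
        assert comp.formula() == "C59H84N10O11"
        assert ElementalComposition.from_formula("C59H84N10O11") == comp

    def test_rejects_negative_and_unknown(self):
        with pytest.raises(ValueError):
            ElementalComposition({"C": -1})
        with pytest.raises(ValueError):
            ElementalComposition({"Se": 1})


class TestCompositionOf:
    @pytest.mark.parametrize("seq,topology,formula", [
        ("TFLPPLFVPP", "cyclic", "C59H84N10O11"),
        ("MHILAPPP", "cyclic", "C41H64N10O8S"),
        ("AFFPPFFIPP", "cyclic", "C65H80N10O10"),
        ("GG", "linear", "C4H8N2O3"),
    ])
    def test_published_formulas(self, seq, topology, formula):
        assert composition_of(seq, topology).formula() == formula

    def test_unknown_residue_names_position(self):
        with pytest.raises(InvalidSequenceError, match="'B' at position 2"):
            composition_of("AABAA", "linear")

    def test_cyclic_is_linear_minus_water(self):
        lin = composition_of("AWDSKHP", "linear")
        cyc = composition_of("AWDSKHP", "cyclic")
        assert (lin - cyc).counts == {"H": 2, "O": 1}


class TestMonoisotopicMass:
    @pytest.mark.parametrize("seq,expected", [
        ("TFLPPLFVPP", 1108.6321),
        ("AWDSKHP", 821.3820),
        ("GGGGGGG", 399.1503),  # 7 glycine residues, brute-force sum
    ])
    def test_published_cyclic_masses(self, seq, expected):
        assert peptide_mass(seq, "cyclic") == pytest.approx(expected, abs=5e-4)

    def test_reference_table_masses(self, reference_rows):
        """Every printed unmodified cyclic mass is reproduced to 0.5 mDa
        from its core; toxin rows require their modification state."""
        from cyclomine.tables import TOXIN_STATES

        for _, row in reference_rows.iterrows():
            n_oh, sulf, bridge = TOXIN_STATES.get(row["label"], (0, False, False))
            mods = ModificationState(n_oh, sulf, bridge)
            mass = peptide_mass(row["core"], "cyclic", mods)
            assert mass == pytest.approx(row["printed_mass"], abs=5e-4), row["core"]

    def test_oracle_equivalence_random_peptides(self, random_peptides):
        """Composition-based mass equals per-atom brute-force sum to 1e-9."""
        for seq in random_peptides(1000):
            for topology in ("linear", "cyclic"):
                ours = monoisotopic_mass(composition_of(seq, topology))
                assert ours == pytest.approx(brute_force_mass(seq, topology),
                                             abs=1e-9)

    def test_pyteomics_cross_check(self, random_peptides):
        """Linear masses agree with an independent library implementation."""
        from pyteomics import mass as pytmass

        for seq in random_peptides(50):
            theirs = pytmass.calculate_mass(sequence=seq)
            assert peptide_mass(seq, "linear") == pytest.approx(theirs, abs=2e-4)

    def test_mass_additivity_exact(self):
        a = composition_of("AW", "linear")
        b = composition_of("KH", "cyclic")
        assert monoisotopic_mass(a + b) == monoisotopic_mass(a) + monoisotopic_mass(b)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.text(alphabet=AA, min_size=2, max_size=14))
def test_water_loss_on_cyclization(seq):
    assert (peptide_mass(seq, "linear") - peptide_mass(seq, "cyclic")
            == pytest.approx(18.010565, abs=1e-6))


class TestModifications:
    @pytest.mark.parametrize("seq,mods,expected", [
        ("IWGIGCNP", ModificationState(4, True, True), 918.3541),   # alpha-amanitin
        ("IWGIGCDP", ModificationState(4, True, True), 919.3382),   # beta-amanitin
        ("AWLVDCP", ModificationState(4, False, True), 846.3217),   # phallacidin
        ("AWLATCP", ModificationState(3, False, True), 788.3160),   # phalloidin
    ])
    def test_toxin_masses(self, seq, mods, expected):
        comp = apply_modifications(composition_of(seq, "cyclic"), mods, seq)
        assert monoisotopic_mass(comp) == pytest.approx(expected, abs=5e-4)

    def test_identity_state(self):
        comp = composition_of("AWLVDCP", "cyclic")
        assert apply_modifications(comp, ModificationState(), "AWLVDCP") == comp

    def test_composition_deltas(self):
        comp = composition_of("IWGIGCNP", "cyclic")
        hydroxylated = apply_modifications(comp, ModificationState(2), "IWGIGCNP")
        assert (hydroxylated - comp).counts == {"O": 2}
        bridged = apply_modifications(comp, ModificationState(0, False, True),
                                      "IWGIGCNP")
        assert (comp - bridged).counts == {"H": 2}

    def test_sulfoxide_requires_cys_and_trp(self):
        comp = composition_of("TFLPPLFVPP", "cyclic")
        with pytest.raises(ModificationError):
            apply_modifications(comp, ModificationState(0, True, False),
                                "TFLPPLFVPP")

    def test_hydroxyl_ceiling(self):
        with pytest.raises(ModificationError):
            ModificationState(5)


class TestAdductsAndPpm:
    @pytest.mark.parametrize("neutral,kind,expected", [
        (1108.6321, "H", 1109.6394),
        (1213.6284, "H", 1214.6357),
        (1108.6321, "Na", 1131.6213),
        (1108.6321, "K", 1147.5953),
    ])
    def test_adduct_mz(self, neutral, kind, expected):
        assert adduct_mz(neutral, Adduct(kind)) == pytest.approx(expected, abs=5e-4)

    def test_doubly_charged(self):
        assert adduct_mz(1000.0, Adduct("H", charge=2)) == pytest.approx(501.007276)

    @pytest.mark.parametrize("theo,meas,expected", [
        (1109.6394, 1109.6398, 0.36),
        (1161.6132, 1161.6161, 2.50),
        (1109.6394, 1109.6394, 0.00),
    ])
    def test_published_ppm(self, theo, meas, expected):
        assert round(ppm_delta(theo, meas), 2) == expected

    def test_ppm_symmetric_in_sign(self):
        assert ppm_delta(1000.0, 1000.001) == ppm_delta(1000.0, 999.999)
        assert ppm_delta(942.5196, 942.5191) > 0  # measured below theoretical


class TestImmonium:
    @pytest.mark.parametrize("residue,expected", [
        ("P", 70.0651), ("F", 120.0808), ("L", 86.0964), ("I", 86.0964),
    ])
    def test_diagnostic_masses(self, residue, expected):
        assert immonium_mz(residue) == pytest.approx(expected, abs=5e-4)

    def test_unknown_residue(self):
        with pytest.raises(InvalidSequenceError):
            immonium_mz("Z")


class TestIsotopicDistribution:
    def test_single_carbon(self):
        peaks = isotopic_distribution(ElementalComposition({"C": 1}))
        assert peaks[0] == (pytest.approx(12.0), pytest.approx(0.9893))
        assert peaks[1] == (pytest.approx(13.00335, abs=1e-4),
                            pytest.approx(0.0107))

    def test_water_most_abundant_peak(self):
        peaks = isotopic_distribution(composition_of("GG", "linear")
                                      - ElementalComposition({"C": 4, "H": 6,
                                                              "N": 2, "O": 2}))
        best = max(peaks, key=lambda t: t[1])
        assert best[0] == pytest.approx(18.0106, abs=1e-3)

    def test_normalization_and_monoisotopic_first(self):
        comp = composition_of("IWGIGCNP", "cyclic")
        peaks = isotopic_distribution(comp)
        assert sum(p for _, p in peaks) == pytest.approx(1.0, abs=1e-9)
        assert peaks[0][0] == pytest.approx(monoisotopic_mass(comp), abs=2e-3)


def test_peptide_validation():
    with pytest.raises(InvalidSequenceError):
        Peptide("A")  # too short
    with pytest.raises(InvalidSequenceError):
        Peptide("ag")  # lowercase
    with pytest.raises(ValueError):
        Peptide("AG", "branched")
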