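"""Mass table, modification chemistry and b-ion ladder checks.

The oracle here is an independently hardcoded residue table (standard
IUPAC monoisotopic and average masses) and a plain summation, kept apart
from the package's pyteomics-derived table.
"""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppiiafp import (
    CARBAMIDOMETHYL,
    DEFAULT_TABLE,
    DISULFIDE,
    HYDROXYLATION,
    PYROGLUTAMATE,
    b_ion_ladder,
    peptide_mh,
    peptide_mz,
    peptide_neutral_mass,
    protein_average_mass,
)

from conftest import TABLE1_VERIFIED_ROWS

# Independent oracle: IUPAC residue masses, typed in by hand.
ORACLE_MONO = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}
ORACLE_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
ORACLE_WATER_MONO = 18.010565
ORACLE_WATER_AVG = 18.01528
ORACLE_PROTON = 1.007276


def oracle_neutral(seq, scale="mono"):
    table = ORACLE_MONO if scale == "mono" else ORACLE_AVG
    water = ORACLE_WATER_MONO if scale == "mono" else ORACLE_WATER_AVG
    return sum(table[r] for r in seq) + water


residues = st.text(alphabet=sorted(ORACLE_MONO), min_size=1, max_size=30)


class TestResidueTable:
    def test_covers_standard_residues_and_mono_below_average(self):
        for r in ORACLE_MONO:
            assert DEFAULT_TABLE.mono[r] <= DEFAULT_TABLE.avg[r]
            assert DEFAULT_TABLE.mono[r] == pytest.approx(ORACLE_MONO[r], abs=1e-4)
            # average masses depend on the isotope-abundance table; 5 mDa
            # per residue is far below intact-mass matching tolerances
            assert DEFAULT_TABLE.avg[r] == pytest.approx(ORACLE_AVG[r], abs=5e-3)

    def test_constants(self):
        assert DEFAULT_TABLE.water_mono == pytest.approx(18.0106, abs=1e-4)
        assert DEFAULT_TABLE.proton_mono == pytest.approx(1.00728, abs=1e-4)

    def test_modification_deltas(self):
        assert PYROGLUTAMATE.delta_mono == pytest.approx(-17.0265, abs=1e-3)
        assert HYDROXYLATION.delta_mono == pytest.approx(15.9949, abs=1e-4)
        assert DISULFIDE.delta_mono == pytest.approx(-2 * 1.00783, abs=1e-4)


class TestNeutralMass:
    def test_single_glycine(self):
        assert peptide_neutral_mass("G") == pytest.approx(75.032, abs=1e-3)

    @pytest.mark.parametrize("seq,printed", sorted(TABLE1_VERIFIED_ROWS.items()))
    def test_verified_fragment_rows(self, seq, printed):
        """Printed [M+H]+ of every fully sequenced fragment, free Cys."""
        assert peptide_mh(seq) == pytest.approx(printed, abs=0.1)

    def test_pyroglutamate_row(self):
        assert peptide_mh("QCTTGVR", {PYROGLUTAMATE: 1}) == pytest.approx(
            747.3, abs=0.1
        )
        assert peptide_neutral_mass(
            "QCTTGVR", {PYROGLUTAMATE: 1}
        ) == pytest.approx(746.34, abs=0.05)

    def test_unknown_residue_names_position(self):
        with pytest.raises(ValueError, match=r"'Z' at position 2"):
            peptide_neutral_mass("GAZK")

    def test_unsatisfiable_site_rules_rejected(self):
        with pytest.raises(ValueError, match="pyroglutamate"):
            peptide_neutral_mass("GACK", {PYROGLUTAMATE: 1})
        with pytest.raises(ValueError, match="hydroxylation"):
            peptide_neutral_mass("GPAG", {HYDROXYLATION: 1})  # P not before G

    def test_carbamidomethyl_optin(self):
        delta = peptide_neutral_mass("CK", {CARBAMIDOMETHYL: 1}) - peptide_neutral_mass("CK")
        assert delta == pytest.approx(57.0215, abs=1e-3)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(a=residues, b=residues)
    def test_additivity(self, a, b):
        """Concatenation: mass(A+B) = mass(A) + mass(B) − water."""
        lhs = peptide_neutral_mass(a + b)
        rhs = (
            peptide_neutral_mass(a)
            + peptide_neutral_mass(b)
            - DEFAULT_TABLE.water_mono
        )
        assert lhs == pytest.approx(rhs, abs=1e-9)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(seq=residues)
    def test_oracle_equivalence_and_scale_order(self, seq):
        assert peptide_neutral_mass(seq) == pytest.approx(
            oracle_neutral(seq), abs=1e-4
        )
        assert peptide_neutral_mass(seq) < peptide_neutral_mass(seq, scale="avg")

    def test_hydroxylation_scales_with_sites(self):
        base = peptide_neutral_mass("APGAPGAPG")
        for k in (1, 2, 3):
            modded = peptide_neutral_mass("APGAPGAPG", {HYDROXYLATION: k})
            assert modded - base == pytest.approx(k * 15.9949, abs=1e-3)


class TestChargeStates:
    def test_mh_is_neutral_plus_proton(self):
        seq = "GGVGAPGGK"
        assert peptide_mh(seq) == pytest.approx(
            peptide_neutral_mass(seq) + DEFAULT_TABLE.proton_mono, abs=1e-9
        )

    def test_doubly_charged(self):
        """m/2z of a doubly protonated species, as seen for intact AFPs."""
        seq = "GGVGAPGGK"
        n = peptide_neutral_mass(seq)
        assert peptide_mz(seq, 2) == pytest.approx(
            (n + 2 * DEFAULT_TABLE.proton_mono) / 2, abs=1e-9
        )
        with pytest.raises(ValueError):
            peptide_mz(seq, 0)


class TestProteinAverageMass:
    def test_gly_gly_hand_sum(self):
        assert protein_average_mass("GG", 0) == pytest.approx(132.12, abs=0.01)

    def test_disulfide_delta(self):
        seq = "CGGGGC"
        free = protein_average_mass(seq, 0)
        bonded = protein_average_mass(seq, 1)
        assert free - bonded == pytest.approx(2.016, abs=0.01)

    def test_default_pairs_all_cysteines(self):
        seq = "CGGCGGCGGC"
        assert protein_average_mass(seq) == pytest.approx(
            protein_average_mass(seq, 2), abs=1e-9
        )

    def test_excess_disulfides_rejected(self):
        with pytest.raises(ValueError, match="cysteine"):
            protein_average_mass("CGGC", 2)


class TestBIonLadder:
    def test_hand_summed_dipeptide(self):
        ladder = b_ion_ladder("GA")
        assert ladder[0] == pytest.approx(58.03, abs=0.01)
        assert ladder[1] == pytest.approx(129.07, abs=0.01)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seq=st.text(alphabet=sorted(ORACLE_MONO), min_size=2, max_size=25))
    def test_ladder_monotone_and_terminal_identity(self, seq):
        ladder = b_ion_ladder(seq)
        assert len(ladder) == len(seq)
        assert all(b > a for a, b in zip(ladder, ladder[1:]))
        assert ladder[-1] == pytest.approx(
            peptide_mh(seq) - DEFAULT_TABLE.water_mono, abs=1e-9
        )

    def test_terminal_identity_against_printed_mass(self):
        # 1118.5 is the rounded printed [M+H]+, so allow printing slack
        assert b_ion_ladder("GADGAAGGGFPGGK")[-1] == pytest.approx(
            1118.5 - 18.01, abs=0.05
        )

    def test_pyroglutamate_shifts_all_rungs(self):
        plain = b_ion_ladder("QCTTGVR")
        cyc = b_ion_ladder("QCTTGVR", {PYROGLUTAMATE: 1})
        for a, b in zip(plain, cyc):
            assert a - b == pytest.approx(17.0265, abs=1e-3)
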