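"""Formula bookkeeping, adduct m/z arithmetic and fragment catalogues."""

import pytest
from hypothesis import given, settings, strategies as st

from marado.chem import (
    ADDUCTS,
    AcylChain,
    FormulaError,
    MolecularFormula,
    TREHALOSE,
    TREHALOSE_FRAGMENT_2H2O,
    TREHALOSE_FRAGMENT_H2O,
    TrehaloseLipid,
    WATER,
    adduct_mz,
    build_formula,
    monoisotopic_mass,
    parse_lipid_name,
    theoretical_fragments,
)

MZ_TOL = 0.0005  # absorbs last-digit truncation of printed values


def mar(a, b):
    return TrehaloseLipid("Mar", (AcylChain(*a), AcylChain(*b)))


class TestMolecularFormula:
    def test_ester_formulas(self):
        assert str(build_formula(mar((14, 0), (14, 0)))) == "C40H74O13"
        assert str(build_formula(mar((16, 0), (16, 0)))) == "C44H82O13"
        lyso = TrehaloseLipid("LysoMar", (AcylChain(17, 0),))
        assert str(build_formula(lyso)) == "C29H54O12"

    def test_monoisotopic_masses(self):
        assert monoisotopic_mass(WATER) == pytest.approx(18.0106, abs=1e-4)
        assert monoisotopic_mass(TREHALOSE) == pytest.approx(342.1162, abs=1e-4)

    def test_masses_agree_with_pyteomics(self):
        """Independent cross-check of the atomic-mass table."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for f in ("C40H74O13", "C44H82O13", "C29H54O12", "C12H22O11"):
            assert MolecularFormula.from_str(f).mass == pytest.approx(
                pyteomics_mass.calculate_mass(formula=f), abs=1e-6
            )

    def test_empty_formula_rejected(self):
        with pytest.raises(FormulaError):
            MolecularFormula({})

    def test_negative_subtraction_rejected(self):
        with pytest.raises(FormulaError):
            WATER - TREHALOSE

    def test_unsupported_element_rejected(self):
        with pytest.raises(FormulaError):
            MolecularFormula({"P": 1})


class TestAdductMz:
    @pytest.mark.parametrize(
        "lipid, adduct, printed",
        [
            (mar((14, 0), (14, 0)), "[M+NH4]+", 780.5467),
            (mar((14, 0), (18, 1)), "[M+Na]+", 839.5491),
            (mar((16, 0), (16, 0)), "[M+FA-H]-", 863.5737),
            (mar((15, 0), (15, 0)), "[M+FA-H]-", 835.5424),
            (mar((14, 0), (14, 0)), "[M+FA-H]-", 807.5111),
        ],
    )
    def test_reference_adduct_mz(self, lipid, adduct, printed):
        assert adduct_mz(lipid.mass, adduct) == pytest.approx(printed, abs=MZ_TOL)

    def test_unknown_adduct_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(800.0, "[M+K]+")

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            adduct_mz(0.0, "[M+Na]+")

    def test_all_adducts_singly_charged(self):
        assert all(abs(a.charge) == 1 for a in ADDUCTS.values())


class TestFragments:
    def test_trehalose_head_fragments(self):
        assert TREHALOSE_FRAGMENT_H2O == pytest.approx(323.0984, abs=MZ_TOL)
        assert TREHALOSE_FRAGMENT_2H2O == pytest.approx(305.0878, abs=MZ_TOL)

    def test_acyl_17_0_carboxylate_nominal_269(self):
        lyso = TrehaloseLipid("LysoMar", (AcylChain(17, 0),))
        frags = {f.kind: f.mz for f in theoretical_fragments(lyso, "[M+FA-H]-")}
        assert round(frags["[RCOO]-"]) == 269

    def test_symmetric_lipid_emits_single_neutral_loss(self):
        sym = theoretical_fragments(mar((14, 0), (14, 0)), "[M+FA-H]-")
        asym = theoretical_fragments(mar((14, 0), (18, 1)), "[M+FA-H]-")
        assert sum(f.kind == "[M-RCOOH]-" for f in sym) == 1
        assert sum(f.kind == "[M-RCOOH]-" for f in asym) == 2

    def test_lyso_lacks_doubly_dehydrated_head_fragment(self):
        lyso = TrehaloseLipid("LysoMar", (AcylChain(17, 0),))
        kinds = {f.kind for f in theoretical_fragments(lyso, "[M+FA-H]-")}
        assert "[Tre-H2O-H]-" in kinds
        assert "[Tre-2H2O-H]-" not in kinds

    def test_loss_fragments_below_precursor(self):
        lipid = mar((16, 0), (18, 1))
        precursor = adduct_mz(lipid.mass, "[M+FA-H]-")
        for f in theoretical_fragments(lipid, "[M+FA-H]-"):
            assert f.mz < precursor
            assert f.charge == -1

    def test_positive_mode_fragments(self):
        frags = theoretical_fragments(mar((14, 0), (14, 0)), "[M+NH4]+")
        kinds = {f.kind for f in frags}
        assert kinds == {"[M-H2O+H]+", "[RCO]+"}
        assert all(f.charge == +1 for f in frags)


class TestLipidIdentity:
    def test_acyl_order_invariance(self):
        a, b = mar((14, 0), (18, 1)), mar((18, 1), (14, 0))
        assert a == b
        assert a.name == b.name == "Mar(14:0/18:1)"
        fa = [(f.kind, f.mz) for f in theoretical_fragments(a, "[M+FA-H]-")]
        fb = [(f.kind, f.mz) for f in theoretical_fragments(b, "[M+FA-H]-")]
        assert fa == fb

    def test_isobars_share_formula_but_stay_distinct(self):
        a, b = mar((16, 0), (16, 0)), mar((15, 0), (17, 0))
        assert str(a.formula) == str(b.formula)
        assert a.mass == pytest.approx(b.mass, abs=1e-12)
        assert a != b and a.name != b.name

    def test_cyclopropane_ring_counts_as_one_dbe(self):
        straight = AcylChain(19, 1)
        ring = AcylChain(19, 1, cyclopropane=True)
        assert str(straight.free_acid) == str(ring.free_acid)

    def test_name_roundtrip(self):
        for name in ("Mar(14:0/18:1)", "LysoMar(17:0)", "Mar(15:0/15:0)"):
            assert parse_lipid_name(name).name == name

    def test_wrong_acyl_count_rejected(self):
        with pytest.raises(ValueError):
            TrehaloseLipid("Mar", (AcylChain(14, 0),))
        with pytest.raises(ValueError):
            TrehaloseLipid("LysoMar", (AcylChain(14, 0), AcylChain(14, 0)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    c1=st.integers(10, 24), d1=st.integers(0, 3),
    c2=st.integers(10, 24), d2=st.integers(0, 3),
)
def test_mass_conservation_property(c1, d1, c2, d2):
    """mass(Mar(a/b)) = mass(trehalose) + mass(FA_a) + mass(FA_b) - 2*mass(H2O)."""
    lipid = mar((c1, d1), (c2, d2))
    expected = (
        TREHALOSE.mass
        + AcylChain(c1, d1).free_acid.mass
        + AcylChain(c2, d2).free_acid.mass
        - 2 * WATER.mass
    )
    assert lipid.mass == pytest.approx(expected, abs=1e-9)
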