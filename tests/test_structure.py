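"""Lanthipeptide structure model: formulas, species variants, core extraction."""

import math

import pytest

from lanthimass import (
    ElementalFormula,
    LanthipeptideStructure,
    StructureError,
    extract_core,
    ion_mz,
    linear_peptide_formula,
    load_structure,
    packaged_structures,
    read_precursors,
)
from lanthimass.formula import MONOISOTOPIC_MASS, WATER


class TestLinearPeptideFormula:
    @pytest.mark.parametrize(
        "seq, hill",
        [
            ("G", "C2H5NO2"),  # glycine: residue + water
            ("GG", "C4H8N2O3"),
            ("ACDEFGHIKLMNPQRSTVWY", "C107H159N29O30S2"),
        ],
    )
    def test_known_formulas(self, seq, hill):
        assert linear_peptide_formula(seq) == ElementalFormula.parse(hill)

    def test_unknown_residue_and_empty_sequence(self):
        with pytest.raises(StructureError):
            linear_peptide_formula("GXG")
        with pytest.raises(StructureError):
            linear_peptide_formula("")


class TestMatureFormula:
    def test_kyamicin_mature_formula(self, kyamicin):
        """4 dehydrations, 3 thioethers, lysinoalanine and Asp15 hydroxyl
        must land exactly on the published molecular formula."""
        assert kyamicin.mature_formula().hill() == "C76H108N20O25S3"

    def test_kyamicin_deoxy_formula(self, kyamicin):
        assert kyamicin.mature_formula(hydroxylated=False).hill() == "C76H108N20O24S3"

    def test_duramycin_mature_formula(self, duramycin):
        assert duramycin.mature_formula().hill() == "C89H125N23O25S3"

    def test_bridging_is_mass_neutral(self, kyamicin):
        """Mature minus linear is exactly −4·H2O + O: thioether and
        lysinoalanine cyclisation move no atoms."""
        delta_removed = kyamicin.linear_formula() - kyamicin.mature_formula()
        assert delta_removed + ElementalFormula(O=1) == 4 * WATER

    def test_deoxy_mz_offset_is_half_an_oxygen(self, kyamicin):
        offset = ion_mz(kyamicin.mature_formula(), 2) - ion_mz(
            kyamicin.mature_formula(False), 2
        )
        assert math.isclose(offset, MONOISOTOPIC_MASS["O"] / 2, abs_tol=1e-9)
        assert round(offset, 4) == 7.9975


class TestReduction:
    @pytest.mark.parametrize(
        "k, hill",
        [
            (0, "C76H108N20O25S3"),
            (1, "C76H110N20O25S2"),
            (2, "C76H112N20O25S"),
            (3, "C76H114N20O25"),
        ],
    )
    def test_desulfurized_formulas(self, kyamicin, k, hill):
        assert kyamicin.reduced_formula(k).hill() == hill

    def test_k_out_of_range(self, kyamicin):
        with pytest.raises(ValueError):
            kyamicin.reduced_formula(4)
        with pytest.raises(ValueError):
            kyamicin.reduced_formula(-1)

    def test_series_monotone_and_evenly_spaced(self, kyamicin):
        series = kyamicin.reduction_series(charge=2)
        assert [k for k, _ in series] == [0, 1, 2, 3]
        mzs = [ion.mz for _, ion in series]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))
        expected_gap = (
            MONOISOTOPIC_MASS["S"] - 2 * MONOISOTOPIC_MASS["H"]
        ) / 2
        for a, b in zip(mzs, mzs[1:]):
            assert math.isclose(a - b, expected_gap, abs_tol=1e-9)

    def test_series_without_bridges_is_a_single_ion(self):
        s = LanthipeptideStructure("linear", "GAVLK")
        assert len(s.reduction_series()) == 1


class TestStructureInvariants:
    def test_dehydration_requires_ser_or_thr(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure("bad", "GAVLK", dehydrations=[1])

    def test_hydroxylation_requires_asp(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure("bad", "GAVLK", hydroxylations=[1])

    def test_bridge_needs_exactly_one_cys(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure(
                "bad", "CCSTK", dehydrations=[3], thioether_bridges=[(1, 2)]
            )
        with pytest.raises(StructureError):
            LanthipeptideStructure(
                "bad", "ASTGK", dehydrations=[2, 3], thioether_bridges=[(2, 3)]
            )

    def test_bridge_partner_must_be_dehydrated(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure("bad", "CSTGK", thioether_bridges=[(1, 2)])

    def test_no_position_in_two_bridges(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure(
                "bad",
                "CSCTK",
                dehydrations=[2, 4],
                thioether_bridges=[(1, 2), (3, 2)],
            )

    def test_lysinoalanine_needs_dehydrated_ser_and_lys(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure("bad", "ASGKT", lysinoalanine=(2, 4))  # not dehydrated
        with pytest.raises(StructureError):
            LanthipeptideStructure(
                "bad", "ASGAT", dehydrations=[2], lysinoalanine=(2, 4)
            )  # no Lys

    def test_positions_must_be_in_range(self):
        with pytest.raises(StructureError):
            LanthipeptideStructure("bad", "GAS", dehydrations=[7])


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, kyamicin, tmp_path):
        path = tmp_path / "ky.yaml"
        kyamicin.to_yaml(path)
        assert LanthipeptideStructure.from_yaml(path) == kyamicin

    def test_yaml_text_round_trip(self, duramycin):
        assert LanthipeptideStructure.from_yaml(duramycin.to_yaml()) == duramycin

    def test_packaged_structures_present(self):
        assert {"kyamicin", "cinnamycin", "duramycin"} <= set(packaged_structures())

    def test_load_structure_unknown_name(self):
        with pytest.raises(FileNotFoundError):
            load_structure("nonexistent-peptide")


class TestExtractCore:
    def test_c_terminal_cut(self, kyamicin):
        # synthetic 78-residue precursor: 59-residue leader + the core
        leader = "M" + "A" * 58
        precursor = leader + kyamicin.core_sequence
        assert len(precursor) == 78
        assert extract_core(precursor, 19) == kyamicin.core_sequence

    def test_full_length_is_identity(self):
        assert extract_core("GAVLK", 5) == "GAVLK"

    def test_too_long_core_is_an_error(self):
        with pytest.raises(ValueError):
            extract_core("ABC", 4)

    def test_fasta_precursors(self, tmp_path, kyamicin):
        fasta = tmp_path / "precursors.fasta"
        fasta.write_text(
            ">kyaA synthetic precursor\n"
            + "M" + "A" * 58 + kyamicin.core_sequence + "\n"
        )
        records = read_precursors(fasta)
        assert extract_core(records["kyaA"]) == kyamicin.core_sequence

    def test_empty_fasta_is_an_error(self, tmp_path):
        empty = tmp_path / "empty.fasta"
        empty.write_text("")
        with pytest.raises(ValueError):
            read_precursors(empty)


class TestSpeciesVariant:
    def test_labels(self, kyamicin):
        assert kyamicin.variant().label == "kyamicin"
        assert kyamicin.variant(hydroxylated=False).label == "deoxykyamicin"
        assert kyamicin.variant(reduced_bridges=3).label == "reduced kyamicin"
        assert "partially reduced" in kyamicin.variant(reduced_bridges=1).label

    def test_variant_formula_matches_structure_derivation(self, kyamicin):
        v = kyamicin.variant(hydroxylated=False, reduced_bridges=2)
        assert v.formula == kyamicin.reduced_formula(2, hydroxylated=False)

    def test_invalid_reduction_count(self, kyamicin):
        with pytest.raises(ValueError):
            kyamicin.variant(reduced_bridges=5)
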