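"""Genetic-code primitives: neighborhoods, classification, translation."""

from itertools import product

import pytest
from Bio.Seq import Seq

from onesnpaway import appio
from onesnpaway.seqcore import (
    STOP,
    CodingSequence,
    GeneticCode,
    PointSubstitution,
    all_substitutions,
    apply_substitution,
    classify_substitution,
    codon_neighbors,
    standard_code,
    stop_adjacent_sense_codons,
    translate,
)

ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]


class TestGeneticCode:
    def test_standard_code_structure(self, code):
        assert len(code.table) == 64
        assert code.stop_codons == {"TAA", "TAG", "TGA"}
        assert len(code.sense_codons) == 61
        assert code.amino_acid("TGG") == "W"
        assert code.is_stop("TGA")

    def test_alternative_code_differs(self):
        mito = GeneticCode.from_ncbi_table(2)  # vertebrate mitochondrial
        assert mito.amino_acid("TGA") == "W"
        assert mito.is_stop("AGA")

    def test_rejects_short_table(self):
        with pytest.raises(ValueError, match="64"):
            GeneticCode(table={"ATG": "M"})


class TestCodingSequence:
    def test_rejects_length_not_multiple_of_three(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            CodingSequence(id="x", nt="ATGTGGTAAG", includes_terminal_stop=True)

    def test_rejects_ambiguity_codes(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            CodingSequence(id="x", nt="ATGNNNTAA")

    def test_rejects_internal_stop(self):
        with pytest.raises(ValueError, match="internal stop.*codon 2"):
            CodingSequence(id="x", nt="ATGTAATGGTAA")

    def test_codon_indexing_is_one_based(self):
        cds = CodingSequence(id="x", nt="ATGTGGTAA")
        assert cds.codon(1) == "ATG"
        assert cds.codon(2) == "TGG"
        assert cds.codon(3) == "TAA"
        assert cds.sense_codon_count == 2
        with pytest.raises(IndexError):
            cds.codon(4)


class TestTranslate:
    @pytest.mark.parametrize(
        "nt, protein",
        [("ATGTAA", "M"), ("ATGTGGTAA", "MW")],
    )
    def test_terminal_stop_not_emitted(self, nt, protein):
        assert translate(CodingSequence(id="x", nt=nt)) == protein

    def test_lambda_rz_protein(self, lambda_rz):
        protein = translate(lambda_rz)
        assert len(protein) == 153
        assert protein.endswith("R")  # only the C-terminal Arg153 is dispensable
        assert protein[98] == "C" and protein[151] == "C"  # the two Cys of Rz


class TestCodonNeighbors:
    def test_tgg_neighborhood(self):
        assert codon_neighbors("TGG") == {
            "AGG", "CGG", "GGG", "TAG", "TCG", "TTG", "TGA", "TGC", "TGT",
        }

    def test_every_codon_has_nine_distinct_neighbors(self):
        for codon in ALL_CODONS:
            nbrs = codon_neighbors(codon)
            assert len(nbrs) == 9
            assert codon not in nbrs
            for n in nbrs:
                assert sum(a != b for a, b in zip(codon, n)) == 1

    def test_invalid_codon_rejected(self):
        with pytest.raises(ValueError):
            codon_neighbors("AT")
        with pytest.raises(ValueError):
            codon_neighbors("ATN")

    def test_stop_adjacent_census_is_eighteen(self, code):
        # independent brute force: translate every neighbor with Biopython
        brute = {
            c
            for c in ALL_CODONS
            if str(Seq(c).translate()) != "*"
            and any(str(Seq(n).translate()) == "*" for n in codon_neighbors(c))
        }
        assert len(brute) == 18
        assert stop_adjacent_sense_codons(code) == brute


class TestClassifySubstitution:
    @pytest.mark.parametrize(
        "ref, alt, kind",
        [("A", "G", "transition"), ("C", "A", "transversion"), ("T", "C", "transition")],
    )
    def test_examples(self, ref, alt, kind):
        assert classify_substitution(ref, alt) == kind

    def test_partition_over_ordered_pairs(self):
        kinds = [
            classify_substitution(a, b) for a in "ACGT" for b in "ACGT" if a != b
        ]
        assert kinds.count("transition") == 4
        assert kinds.count("transversion") == 8

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestApplySubstitution:
    def test_tryptophan_to_amber(self):
        cds = CodingSequence(id="x", nt="ATGTGGTAA")
        eff = apply_substitution(cds, PointSubstitution(2, 2, "G", "A"))
        assert (eff.ref_codon, eff.alt_codon) == ("TGG", "TAG")
        assert (eff.ref_aa, eff.alt_aa) == ("W", STOP)
        assert eff.effect_class == "nonsense"
        assert eff.stop_name == "amber"
        assert eff.mutation_type == "transition"

    def test_leucine_to_proline_missense(self):
        cds = CodingSequence(id="x", nt="ATGCTGTAA")
        eff = apply_substitution(cds, PointSubstitution(2, 2, "T", "C"))
        assert eff.alt_codon == "CCG"
        assert (eff.ref_aa, eff.alt_aa) == ("L", "P")
        assert eff.effect_class == "missense"
        assert eff.mutation_type == "transition"

    def test_synonymous_leucine(self):
        cds = CodingSequence(id="x", nt="ATGCTGTAA")
        eff = apply_substitution(cds, PointSubstitution(2, 3, "G", "A"))
        assert eff.alt_codon == "CTA"
        assert eff.effect_class == "synonymous"

    def test_start_loss_counts_as_missense(self):
        cds = CodingSequence(id="x", nt="ATGTGGTAA")
        eff = apply_substitution(cds, PointSubstitution(1, 2, "T", "A"))
        assert eff.alt_aa == "K"  # Met1Lys
        assert eff.effect_class == "start_loss"
        assert eff.counts_as_missense

    def test_ref_mismatch_names_expected_base(self):
        cds = CodingSequence(id="x", nt="ATGTGGTAA")
        with pytest.raises(ValueError, match="sequence has G, substitution expects C"):
            apply_substitution(cds, PointSubstitution(2, 2, "C", "A"))

    def test_out_of_range_index(self):
        cds = CodingSequence(id="x", nt="ATGTGGTAA")
        with pytest.raises(IndexError):
            apply_substitution(cds, PointSubstitution(9, 1, "A", "C"))


@pytest.mark.parametrize("seed", range(5))
def test_effects_match_brute_force_retranslation(seed, code):
    """Every one of the 9L substitutions classifies exactly as re-translating
    the mutated sequence with Biopython does."""
    cds = appio.generate_cds(seed, n_codons=1 + seed * 10 + 9)
    for sub in all_substitutions(cds):
        eff = apply_substitution(cds, sub, code)
        mutant = cds.mutate_nt(sub)
        i = sub.codon_index
        ref_aa = str(Seq(cds.nt[3 * (i - 1) : 3 * i]).translate())
        alt_aa = str(Seq(mutant[3 * (i - 1) : 3 * i]).translate())
        assert eff.ref_aa == ref_aa and eff.alt_aa == alt_aa
        if alt_aa == "*":
            assert eff.effect_class == "nonsense"
        elif i == 1 and eff.alt_codon not in code.start_codons:
            assert eff.effect_class == "start_loss"
        elif alt_aa == ref_aa:
            assert eff.effect_class == "synonymous"
        else:
            assert eff.effect_class == "missense"


def test_translate_reports_internal_stop_with_index():
    # AGA is sense in the standard code but a stop in the vertebrate
    # mitochondrial code, so translation under that code must name codon 2
    cds = CodingSequence(id="x", nt="ATGAGATGGTAA")
    with pytest.raises(ValueError, match="codon 2"):
        translate(cds, GeneticCode.from_ncbi_table(2))


def test_internal_stop_rejected_at_construction():
    with pytest.raises(ValueError, match="internal stop codon TAA at codon 3"):
        CodingSequence(id="x", nt="ATGTGGTAACCC", includes_terminal_stop=False)


def test_substitution_literal_round_trip():
    sub = PointSubstitution.parse("100:1:C>T")
    assert sub == PointSubstitution(100, 1, "C", "T")
    assert str(sub) == "100:1:C>T"
    with pytest.raises(ValueError, match="malformed"):
        PointSubstitution.parse("100-1-C-T")
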