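"""Mutant-table parsing, summaries, saturation model, heptads, maps."""

import io
import random

import pytest

from onesnpaway import appio
from onesnpaway.mutmap import (
    DomainMap,
    HeptadAssignment,
    MutationRecord,
    SaturationSummary,
    distinct_missense_positions,
    heptad_positions,
    parse_mutation_table,
    recompute_change_types,
    render_mutation_map,
    saturation_summary,
    span_estimate,
    summarize_mutations,
)
from onesnpaway.seqcore import STOP, translate

HEADER = "gene\tcodon_position\tref_aa\talt\tisolates\tlysis\tsource\n"


def table(*rows):
    return io.StringIO(HEADER + "".join("\t".join(map(str, r)) + "\n" for r in rows))


class TestParse:
    def test_missense_row(self):
        recs = parse_mutation_table(table(("Rz", 64, "L", "P", 3, "defective", "random")))
        (r,) = recs
        assert r.is_missense and not r.is_nonsense
        assert (r.codon_position, r.ref_aa, r.alt, r.isolates) == (64, "L", "P", 3)

    def test_nonsense_row_carries_stop_name(self):
        (r,) = parse_mutation_table(
            table(("Rz1", 54, "I", "X(Ochre)", 0, "defective", "site_directed"))
        )
        assert r.is_nonsense and r.alt == STOP and r.stop_name == "ochre"

    def test_replacement_row(self):
        (r,) = parse_mutation_table(
            table(("Rz", 4, "V", "artificial-TMD(4-24)", 0, "functional", "site_directed"))
        )
        assert r.is_replacement and r.replacement_label == "artificial-TMD(4-24)"

    @pytest.mark.parametrize(
        "row, message",
        [
            (("Rz", 64, "L", "P", -1, "defective", "random"), "negative"),
            (("Rz", 64, "B", "P", 1, "defective", "random"), "unknown amino-acid"),
            (("Rz", 64, "L", "X(Umber)", 1, "defective", "random"), "stop type"),
            (("Rz", 64, "L", "X(Ochre", 0, "defective", "site_directed"), "malformed"),
            (("Rz", 64, "L", "P", 0, "defective", "random"), "site-directed"),
        ],
    )
    def test_bad_rows_rejected_with_row_number(self, row, message):
        with pytest.raises(ValueError, match=f"row 1.*{message}|{message}"):
            parse_mutation_table(table(row))

    def test_packaged_table_loads(self, rz_records, rz1_records):
        assert len(rz_records) + len(rz1_records) == 78
        assert all(r.gene == "Rz" for r in rz_records)


class TestSummaries:
    def test_empty_record_list_gives_zero_summary(self):
        s = summarize_mutations([], DomainMap.rz_default())
        assert s.missense_isolate_sum == 0 and s.nonsense_positions == 0

    def test_rz_random_missense_isolates_sum_to_49(self, rz_records):
        s = summarize_mutations(rz_records, DomainMap.rz_default())
        assert s.missense_isolate_sum == 49

    def test_rz1_periplasmic_missense_positions(self, rz1_records):
        # mature protein minus the lipoylated Cys20 anchor: residues >= 21
        assert len(distinct_missense_positions(rz1_records, min_position=21)) == 11

    def test_replacements_and_site_directed_excluded(self, rz_records):
        s = summarize_mutations(rz_records, DomainMap.rz_default())
        # E150R/E150G (site-directed) and the engineered linkers never count
        assert 150 not in distinct_missense_positions(rz_records)
        assert s.per_domain["NTMD"].missense_positions == 3  # M1K, C14R, L19P

    def test_order_invariance(self, rz_records):
        shuffled = list(rz_records)
        random.Random(0).shuffle(shuffled)
        assert summarize_mutations(shuffled, DomainMap.rz_default()) == summarize_mutations(
            rz_records, DomainMap.rz_default()
        )

    def test_gene_mismatch_rejected(self, rz1_records):
        with pytest.raises(ValueError, match="domain map"):
            summarize_mutations(rz1_records, DomainMap.rz_default())

    def test_ts_tv_recomputed_from_codons(self, rz_records, lambda_rz):
        s = summarize_mutations(rz_records, DomainMap.rz_default(), cds=lambda_rz)
        assert s.n_classified > 0
        assert s.ts_fraction + s.tv_fraction == pytest.approx(1.0)

    def test_printed_arrow_glyphs_cross_check(self, rz_records, rz1_records, lambda_rz, lambda_rz1):
        """Recomputed ts/tv agrees with the printed arrows except for a frozen
        erratum set (the table prints a transition arrow for several changes
        that are chemically transversions, e.g. Met->Lys and the Xaa->Pro
        site-directed rows)."""
        errata = {
            ("Rz", 1, "K"), ("Rz", 36, "P"), ("Rz", 50, "P"), ("Rz", 62, "P"),
            ("Rz", 107, "P"), ("Rz", 125, "P"), ("Rz", 151, "P"), ("Rz1", 1, "K"),
        }
        for records, cds in ((rz_records, lambda_rz), (rz1_records, lambda_rz1)):
            kinds = recompute_change_types(records, cds)
            for i, r in enumerate(records):
                if r.change_type and kinds[i] is not None:
                    key = (r.gene, r.codon_position, r.alt)
                    if kinds[i] != r.change_type:
                        assert key in errata, f"unexpected ts/tv mismatch at {key}"
                    else:
                        assert key not in errata


class TestSaturation:
    def test_fraction(self):
        s = saturation_summary(range(34), range(45))
        assert s.fraction == pytest.approx(34 / 45)

    def test_full_coverage(self):
        assert saturation_summary([1, 2], [1, 2]).fraction == 1.0

    def test_stray_observed_positions_listed(self):
        with pytest.raises(ValueError, match=r"\[7, 9\]"):
            saturation_summary([1, 7, 9], [1, 2, 3])

    def test_expected_coverage_closed_form(self):
        s = SaturationSummary(accessible=45, observed=34)
        assert s.expected_coverage(82) == pytest.approx(37.873, abs=0.001)
        assert s.expected_coverage(0) == 0.0

    @pytest.mark.parametrize("m, n", [(5, 10), (5, 82), (45, 10), (45, 82)])
    def test_closed_form_within_monte_carlo_error(self, m, n):
        s = SaturationSummary(accessible=m, observed=m)
        mean, se = s.simulate_coverage(n, n_reps=20000, seed=m * 1000 + n)
        # the 1e-6 floor covers the saturated regime (m=5, n=82) where every
        # replicate hits all positions and the simulation variance is zero
        assert abs(s.expected_coverage(n) - mean) <= 3 * se + 1e-6


class TestHeptad:
    def test_published_register_gives_eight_a_d_positions(self):
        # anchor 'a' at Asp65 (the unusual a-position Asp of CC1)
        a = HeptadAssignment(start=60, end=86, anchor=65)
        positions = heptad_positions(a, {"a", "d"})
        assert positions == [61, 65, 68, 72, 75, 79, 82, 86]

    def test_any_seven_residue_window_has_two_a_d(self):
        for start in range(1, 15):
            a = HeptadAssignment(start=start, end=start + 6, anchor=5)
            assert len(heptad_positions(a, {"a", "d"})) == 2

    def test_all_letters_cover_range(self):
        a = HeptadAssignment(start=10, end=39, anchor=3)
        assert heptad_positions(a, set("abcdefg")) == list(range(10, 40))

    def test_period_seven(self):
        a = HeptadAssignment(start=1, end=30, anchor=8)
        for i in range(1, 24):
            assert a.letter(i) == a.letter(i + 7)
        assert a.letter(8) == "a"

    def test_empty_letter_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            heptad_positions(HeptadAssignment(1, 7, 1), set())


class TestSpan:
    def test_periplasm_span(self):
        # 130 Rz + 40 Rz1 residues at the alpha-helical rise
        assert 130 + 40 == 170
        assert span_estimate(170) == pytest.approx(25.5)

    def test_zero(self):
        assert span_estimate(0) == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            span_estimate(-1)


class TestRender:
    def test_empty_records_render_sequence_and_domains(self, lambda_rz):
        protein = translate(lambda_rz)
        text, tsv = render_mutation_map([], protein, DomainMap.rz_default())
        assert protein[:60] in text
        assert "NNNN" in text  # NTMD domain line
        assert tsv.count("\n") == len(protein) + 1  # header + one row per residue

    def test_single_record_glyph_above_position_one(self):
        rec = MutationRecord("Rz", 1, "M", "K", 1, "defective", "random")
        text, _ = render_mutation_map([rec], "MSRV", DomainMap(gene="Rz", intervals={"N": (1, 4)}))
        lines = text.splitlines()
        assert lines[0][0] == "K"
        assert lines[1].startswith("MSRV")

    def test_every_table_position_carries_a_glyph(self, rz_records, lambda_rz):
        protein = translate(lambda_rz)
        _, tsv = render_mutation_map(rz_records, protein, DomainMap.rz_default())
        counts = {}
        for line in tsv.splitlines()[1:]:
            pos, _aa, _dom, n, *_ = line.split("\t")
            counts[int(pos)] = int(n)
        for r in rz_records:
            if not r.is_replacement:
                assert counts[r.codon_position] >= 1

    def test_record_beyond_protein_rejected(self):
        rec = MutationRecord("Rz", 10, "M", "K", 1, "defective", "random")
        with pytest.raises(ValueError, match="beyond"):
            render_mutation_map([rec], "MSRV", DomainMap(gene="Rz", intervals={"N": (1, 4)}))
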