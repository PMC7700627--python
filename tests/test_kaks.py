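import itertools

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from genefam.kaks import (CodonAlignment, KaKsSummary, aggregate,
                          call_indels, call_substitutions,
                          classify_substitution, codon_align,
                          compare_cds_pair, indels_from_gapped_pair,
                          summarize)
from genefam.seqio import SequenceRecord
from genefam.simulate import SENSE_CODONS, DivergencePlan, \
    simulate_divergent_cds_pair

# the published SNP table: gene -> (synonymous, non-synonymous, total, ratio)
HSP70_ROWS = {
    "HSPA4L": (18, 6, 24, 0.33), "HSPA4": (13, 3, 16, 0.23),
    "HSPA13": (24, 9, 33, 0.38), "HSPA14": (8, 2, 10, 0.25),
    "HSP70": (39, 23, 62, 0.59), "HSPA8": (72, 8, 80, 0.11),
    "HSP70.1": (17, 1, 18, 0.06), "HSPA1L": (22, 3, 25, 0.14),
    "HSPA6": (19, 4, 23, 0.21),
}
HSP90_ROWS = {
    "TRP1": (111, 17, 128, 0.15), "HSP90AA1": (23, 1, 24, 0.04),
    "HSP90B1": (19, 0, 19, 0.00), "HSP90AB1": (22, 1, 23, 0.05),
}


class TestClassifySubstitution:
    def test_synonymous_third_position(self):
        assert classify_substitution("GAA", 3, "G") == "synonymous"

    def test_nonsynonymous_second_position(self):
        assert classify_substitution("GAA", 2, "T") == "non-synonymous"

    def test_stop_gain_is_nonsynonymous(self):
        assert classify_substitution("TAC", 3, "A") == "non-synonymous"  # Tyr->stop

    def test_matches_translate_oracle_for_all_576_mutations(self):
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            for offset in (1, 2, 3):
                for base in "ACGT":
                    if base == codon[offset - 1]:
                        continue
                    mutant = codon[:offset - 1] + base + codon[offset:]
                    expected = ("synonymous"
                                if str(Seq(codon).translate())
                                == str(Seq(mutant).translate())
                                else "non-synonymous")
                    assert classify_substitution(codon, offset, base) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_substitution("GA-", 1, "T")
        with pytest.raises(ValueError):
            classify_substitution("GAA", 1, "G")


class TestCodonAlign:
    def _cds(self, codons, name="g"):
        return SequenceRecord(name, "".join(codons), "dna")

    def test_identical_cds_no_gaps(self):
        rng_codons = [SENSE_CODONS[i % 61] for i in range(50)]
        ca = codon_align(self._cds(rng_codons, "a"), self._cds(rng_codons, "b"))
        assert "---" not in ca.ref_codons and "---" not in ca.alt_codons

    def test_deleted_codon_block_yields_one_gap_run(self):
        ref, alt, _ = simulate_divergent_cds_pair(
            300, DivergencePlan(indels=[(260, 5, "deletion")], seed=2))
        ca = codon_align(ref, alt)
        runs = [len(list(g)) for k, g in
                itertools.groupby(ca.alt_codons, key=lambda c: c == "---") if k]
        assert runs == [5]

    def test_gap_runs_multiple_of_three_nt(self):
        ref, alt, _ = simulate_divergent_cds_pair(
            120, DivergencePlan(n_syn=3, indels=[(30, 2, "deletion"),
                                                 (70, 1, "insertion")], seed=9))
        ca = codon_align(ref, alt)
        for row in ("".join(ca.ref_codons), "".join(ca.alt_codons)):
            for key, grp in itertools.groupby(row, key=lambda ch: ch == "-"):
                if key:
                    assert len(list(grp)) % 3 == 0

    def test_split_gap_codon_rejected(self):
        with pytest.raises(ValueError, match="whole codons"):
            CodonAlignment("g", ["A--"], ["AAA"])


class TestCallSubstitutions:
    def test_single_difference_in_codon_three(self):
        ca = CodonAlignment("g", ["ATG", "GGT", "GAA"], ["ATG", "GGT", "GAG"])
        records = call_substitutions(ca)
        assert len(records) == 1
        assert records[0].codon_index == 3
        assert records[0].cds_position == 9
        assert records[0].effect == "synonymous"

    def test_two_differences_two_records(self):
        ca = CodonAlignment("g", ["GAA"], ["GTC"])
        records = call_substitutions(ca)
        assert len(records) == 2
        assert [r.cds_position for r in records] == [2, 3]

    def test_identical_alignment_empty(self):
        assert call_substitutions(CodonAlignment("g", ["ATG"], ["ATG"])) == []

    def test_positions_skip_gap_codons(self):
        ca = CodonAlignment("g", ["ATG", "GAA", "CCC"],
                            ["ATG", "---", "CCG"])
        (rec,) = call_substitutions(ca)
        assert rec.codon_index == 3 and rec.cds_position == 9


class TestCallIndels:
    def test_published_15nt_indel_at_777_791(self):
        ref = "A" * 1000
        alt = ref[:776] + "-" * 15 + ref[791:]
        (rec,) = indels_from_gapped_pair(ref, alt)
        assert (rec.start, rec.end, rec.length_nt, rec.kind) == \
               (777, 791, 15, "deletion")

    def test_published_3nt_indel_at_1703_1705(self):
        ref = "C" * 2000
        alt = ref[:1702] + "-" * 3 + ref[1705:]
        (rec,) = indels_from_gapped_pair(ref, alt)
        assert (rec.start, rec.end, rec.length_nt) == (1703, 1705, 3)

    def test_gap_free_alignment_empty(self):
        assert call_indels(CodonAlignment("g", ["ATG"], ["ATG"])) == []

    def test_insertion_coordinates(self):
        # 6 inserted bases after reference position 3
        recs = indels_from_gapped_pair("AAA------TTT", "AAACCCGGGTTT")
        assert len(recs) == 1
        r = recs[0]
        assert (r.start, r.end, r.length_nt, r.kind) == (4, 9, 6, "insertion")

    def test_adjacent_runs_merge(self):
        recs = indels_from_gapped_pair("AAATTT", "A---TT".replace(" ", ""))
        assert len(recs) == 1 and recs[0].length_nt == 3

    def test_length_identity_always(self):
        ref, alt, _ = simulate_divergent_cds_pair(
            100, DivergencePlan(indels=[(10, 1, "deletion"),
                                        (50, 3, "insertion")], seed=5))
        for rec in compare_cds_pair(ref, alt)[2]:
            assert rec.length_nt == rec.end - rec.start + 1


class TestSummaries:
    @pytest.mark.parametrize("gene,row", list(HSP70_ROWS.items())
                             + list(HSP90_ROWS.items()))
    def test_published_rows_reproduced(self, gene, row):
        syn, nonsyn, total, ratio = row
        s = KaKsSummary(gene, syn, nonsyn)
        assert s.total == total
        assert s.ratio == pytest.approx(ratio)

    def test_half_away_from_zero_rounding(self):
        assert KaKsSummary("g", 24, 9).ratio == 0.38  # 0.375 rounds up

    def test_zero_nonsyn_gives_zero_ratio(self):
        assert KaKsSummary("g", 19, 0).ratio == 0.0

    def test_zero_syn_gives_na(self):
        assert KaKsSummary("g", 0, 3).ratio is None

    def test_family_totals(self):
        hsp70 = [KaKsSummary(g, s, n) for g, (s, n, _, _) in HSP70_ROWS.items()]
        total = aggregate(hsp70)
        assert (total.syn_count, total.nonsyn_count, total.total) == (232, 59, 291)
        assert total.ratio == pytest.approx(0.25)
        hsp90 = [KaKsSummary(g, s, n) for g, (s, n, _, _) in HSP90_ROWS.items()]
        total90 = aggregate(hsp90)
        assert (total90.syn_count, total90.nonsyn_count, total90.total) == \
               (175, 19, 194)
        assert total90.ratio == pytest.approx(0.11)

    def test_single_summary_identity(self):
        s = KaKsSummary("g", 5, 2)
        agg = aggregate([s])
        assert (agg.syn_count, agg.nonsyn_count, agg.ratio) == (5, 2, s.ratio)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 200), st.integers(0, 200)),
                    min_size=1, max_size=10))
    def test_total_invariant(self, counts):
        summaries = [KaKsSummary(f"g{i}", s, n)
                     for i, (s, n) in enumerate(counts)]
        agg = aggregate(summaries)
        assert agg.total == sum(s.total for s in summaries)
        assert agg.syn_count == sum(s.syn_count for s in summaries)


class TestRoundTrip:
    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 12), st.integers(0, 8))
    def test_planted_counts_recovered_exactly(self, seed, n_syn, n_nonsyn):
        ref, alt, _ = simulate_divergent_cds_pair(
            150, DivergencePlan(n_syn=n_syn, n_nonsyn=n_nonsyn, seed=seed))
        summary, _, indels = compare_cds_pair(ref, alt)
        assert (summary.syn_count, summary.nonsyn_count, summary.total) == \
               (n_syn, n_nonsyn, n_syn + n_nonsyn)
        assert indels == []

    def test_planted_deletion_recovered_with_length_15(self):
        ref, alt, _ = simulate_divergent_cds_pair(
            300, DivergencePlan(indels=[(260, 5, "deletion")], seed=2))
        _, _, indels = compare_cds_pair(ref, alt)
        assert len(indels) == 1
        assert indels[0].length_nt == 15 and indels[0].kind == "deletion"
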